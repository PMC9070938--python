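"""Synthetic study-condition generator with known ground truth.

Everything the pipeline consumes can be simulated here:

* **Monthly index series** — zero-mean, unit-variance AR(1) latent series
  per index (MOCI-like), with a common cross-index correlation on the
  innovations.  SST-named series are emitted as ``offset + scale × (−z)``
  so that, as in the real ocean, warm water lines up with the low-nutrient
  phase of the latent index.
* **Regional kelp truth** — per region and year, extent
  ``E_y = max(0, α + β·x_y + ε_y)`` where ``x_y`` is the region's driver
  index averaged over the linked season (winter by default) and
  ``ε ~ N(0, σ)``.  When σ is not given it is derived from a target R² via
  ``σ = |β|·sd(x)·sqrt((1−R²)/R²)``.  Default links use the strongest
  published-scale relationships: north α = 3.04 km², β = −0.77 km² per
  MOCI unit, R² ≈ 0.87; south α = 5.52, β = −0.19, R² ≈ 0.57.
* **Pixel rasterisation** — the annual regional extent is spread over 0.1°
  latitude bands with a fixed unimodal weight profile (kelp beds are
  patchy, not uniform) and, within a band, equally over pixels capped at
  the physical 900 m² per 30 × 30 m pixel.  Cloud dropout removes a
  configured fraction of a band-year's pixels with a configured
  probability, producing the missing-data structure the QC stage exists
  for.
* **Collapse scenario** — from a split year onward every observed pixel
  area is multiplied by a suppression factor while the environment is left
  untouched, emulating a biotic regime (urchin herbivory) that decouples
  canopy from ocean conditions.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .canopy_qc import BandConfig
from .seasonal import SEASONS, predictor_series, seasonal_table

__all__ = [
    "RegionLink",
    "ScenarioConfig",
    "ScenarioTruth",
    "seasonal_mean_sd",
    "noise_sd_for_r2",
    "phi_for_adjacent_season_corr",
    "gen_monthly_indices",
    "gen_regional_truth",
    "gen_canopy_pixels",
    "apply_collapse_scenario",
]

MAX_PIXEL_AREA_M2 = 900.0


@dataclass(frozen=True)
class RegionLink:
    """Linear link from one seasonal index to one region's kelp extent."""

    index_name: str
    season: str = "winter"
    alpha: float = 3.04  # km², extent at index 0
    beta: float = -0.77  # km² per index unit; negative: warm phase suppresses kelp
    target_r2: float = 0.87  # used to derive the noise sd when none is given


def _default_links() -> dict[str, RegionLink]:
    return {
        "north": RegionLink("MOCI_south", alpha=3.04, beta=-0.77, target_r2=0.87),
        "south": RegionLink("MOCI_north", alpha=5.52, beta=-0.19, target_r2=0.57),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Defaults reproduce the published study layout: kelp years 1991–2020
    with the 2014 split, eight monthly indices with moderate month-to-month
    persistence (φ = 0.6) and cross-index correlation 0.6, ten 0.1° bands
    per region on the 38–40°N domain, and cloud dropout tuned to flag a
    band-year about 8% of the time (≈ 5 missing region-years out of 30, as
    in the real record).
    """

    years: tuple[int, int] = (1991, 2020)
    split_year: int = 2014
    index_names: tuple[str, ...] = (
        "MOCI_north", "MOCI_central", "MOCI_south",
        "SST_N13", "SST_N14",
        "BEUTI_37N", "BEUTI_39N", "BEUTI_41N",
    )
    phi: float = 0.6                 # monthly AR(1) coefficient, |φ| < 1
    cross_correlation: float = 0.6   # innovation correlation between indices
    sst_offset: float = 11.5         # °C, winter-mean level of the SST-like series
    sst_scale: float = 1.0           # °C per latent index unit
    links: dict[str, RegionLink] = field(default_factory=_default_links)
    noise_sd: dict[str, float] | None = None  # km²; None → derived from target_r2
    n_bands_per_region: int = 10
    pixels_per_band: int | None = None        # None → derived from peak band load
    dropout_prob: float = 0.08       # per band-year probability of a cloud event
    dropout_fraction: float = 0.3    # fraction of the band's pixels removed
    suppression_factor: float = 1.0  # post-split observed-kelp multiplier
    band_config: BandConfig = field(default_factory=BandConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.years
        if lo > hi:
            raise ValueError(f"year range {self.years} is empty")
        if not abs(self.phi) < 1:
            raise ValueError(f"AR(1) coefficient must satisfy |phi| < 1, got {self.phi}")
        k = len(self.index_names)
        if k > 1 and not -1.0 / (k - 1) < self.cross_correlation < 1.0:
            raise ValueError(
                f"cross_correlation {self.cross_correlation} makes the "
                f"{k}×{k} equicorrelation matrix non-positive-definite"
            )
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError(f"dropout_prob must lie in [0, 1], got {self.dropout_prob}")
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError(
                f"dropout_fraction must lie in [0, 1], got {self.dropout_fraction}"
            )
        if not 0 < self.suppression_factor <= 1:
            raise ValueError(
                f"suppression_factor must lie in (0, 1], got {self.suppression_factor}"
            )
        if self.pixels_per_band is not None and self.pixels_per_band < 1:
            raise ValueError("pixels_per_band must be at least 1")
        for region, link in self.links.items():
            if link.index_name not in self.index_names:
                raise ValueError(
                    f"link for region {region!r} references unknown index "
                    f"{link.index_name!r}"
                )
            if link.season not in SEASONS:
                raise ValueError(f"unknown season {link.season!r} in link for {region!r}")

    @property
    def kelp_years(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def region_noise_sd(self, region: str) -> float:
        """Noise sd for a region: configured, or derived from the target R²."""
        if self.noise_sd is not None and region in self.noise_sd:
            return self.noise_sd[region]
        link = self.links[region]
        return noise_sd_for_r2(link.beta, seasonal_mean_sd(self.phi), link.target_r2)


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth of one realisation.

    ``regional`` columns: region, year, x (seasonal driver value), epsilon,
    extent_km2, alpha, beta.  ``dropout`` columns: band_id, year, n_dropped.
    """

    regional: pd.DataFrame
    dropout: pd.DataFrame


def seasonal_mean_sd(phi: float) -> float:
    """Sd of a 3-month mean of a unit-variance AR(1) series."""
    return math.sqrt((3 + 4 * phi + 2 * phi**2) / 9.0)


def noise_sd_for_r2(beta: float, sigma_x: float, r2: float) -> float:
    """Noise sd making the population R² of y = α + βx + ε equal ``r2``."""
    if not 0 < r2 < 1:
        raise ValueError(f"target R² must lie in (0, 1), got {r2}")
    return abs(beta) * sigma_x * math.sqrt((1 - r2) / r2)


def _adjacent_season_corr(phi: float) -> float:
    """Correlation between consecutive 3-month means of a unit-variance AR(1)."""
    cov = (phi + 2 * phi**2 + 3 * phi**3 + 2 * phi**4 + phi**5) / 9.0
    var = (3 + 4 * phi + 2 * phi**2) / 9.0
    return cov / var

def phi_for_adjacent_season_corr(target: float) -> float:
    """Monthly AR(1) coefficient giving a desired adjacent-season correlation.

    Winter→spring persistence of real ocean indices is high; this inverts
    the seasonal-mean correlation implied by the monthly model.
    """
    if not 0 <= target < 1:
        raise ValueError(f"target seasonal correlation must lie in [0, 1), got {target}")
    if target == 0:
        return 0.0
    return float(optimize.brentq(lambda p: _adjacent_season_corr(p) - target, 0.0, 0.999999))


def _rng(config: ScenarioConfig, stream: int, seed: int | None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base), stream])


def gen_monthly_indices(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate all monthly index series.

    Covers January of the year before the first kelp year (the lagged fall
    season needs it) through December of the last kelp year.

    Returns
    -------
    Long DataFrame index_name, year, month, value.
    """
    rng = _rng(config, 1, seed)
    k = len(config.index_names)
    first, last = config.years[0] - 1, config.years[1]
    n_months = 12 * (last - first + 1)

    corr = np.full((k, k), config.cross_correlation)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)

    innov_sd = math.sqrt(1 - config.phi**2)  # unit marginal variance
    shocks = rng.standard_normal((n_months, k)) @ chol.T * innov_sd
    z = np.empty((n_months, k))
    z[0] = rng.standard_normal(k) @ chol.T  # stationary start
    for t in range(1, n_months):
        z[t] = config.phi * z[t - 1] + shocks[t]

    years = np.repeat(np.arange(first, last + 1), 12)
    months = np.tile(np.arange(1, 13), last - first + 1)
    frames = []
    for j, name in enumerate(config.index_names):
        values = z[:, j]
        if name.startswith("SST"):
            values = config.sst_offset + config.sst_scale * (-values)
        frames.append(
            pd.DataFrame(
                {"index_name": name, "year": years, "month": months, "value": values}
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_regional_truth(
    config: ScenarioConfig, indices: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Latent annual kelp extent per region from the linked seasonal driver.

    Returns a frame region, year, x, epsilon, extent_km2, alpha, beta where
    ``extent_km2 = max(0, alpha + beta·x + epsilon)``.
    """
    rng = _rng(config, 2, seed)
    table = seasonal_table(indices, config.kelp_years)
    rows = []
    for region in sorted(config.links):
        link = config.links[region]
        x = predictor_series(table, link.index_name, link.season).reindex(
            config.kelp_years
        )
        if x.isna().any():
            missing = [int(y) for y in x.index[x.isna()]]
            raise ValueError(
                f"driver {link.index_name}/{link.season} incomplete for years {missing}"
            )
        eps = rng.normal(0.0, config.region_noise_sd(region), len(x))
        extent = np.maximum(0.0, link.alpha + link.beta * x.to_numpy() + eps)
        rows.append(
            pd.DataFrame(
                {
                    "region": region,
                    "year": x.index.astype(int),
                    "x": x.to_numpy(),
                    "epsilon": eps,
                    "extent_km2": extent,
                    "alpha": link.alpha,
                    "beta": link.beta,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _band_weights(n: int) -> np.ndarray:
    """Fixed unimodal (Gaussian-profile) allocation weights across a region's bands."""
    centers = np.arange(n) - (n - 1) / 2.0
    w = np.exp(-0.5 * (centers / (n / 4.0)) ** 2)
    return w / w.sum()


def gen_canopy_pixels(
    config: ScenarioConfig,
    indices: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ScenarioTruth]:
    """Rasterise the regional truth into summer-quarter pixel records.

    The regional extent of each year is split across the region's bands by
    the fixed unimodal weight profile, then equally across a band's pixels;
    cloud dropout then blanks (sets to missing) a fraction of some
    band-years' pixels.  Only Q3 records are emitted — the quarter the
    analysis consumes.

    Returns
    -------
    (pixels, truth):
        pixels has the canopy CSV columns; truth carries the regional
        latent series and the realised dropout counts.
    """
    truth_regional = gen_regional_truth(config, indices, seed)
    rng = _rng(config, 3, seed)
    bc = config.band_config
    nb = config.n_bands_per_region
    years = np.array(config.kelp_years)
    ny = len(years)
    weights = _band_weights(nb)

    # south bands hug the split from below, north bands sit on/above it
    split_band = int(round((bc.split_latitude - bc.origin) / bc.width))
    region_bands = {
        "south": np.arange(split_band - nb, split_band),
        "north": np.arange(split_band, split_band + nb),
    }
    if region_bands["south"][0] < 0 or bc.band_lower_edge(
        region_bands["north"][-1]
    ) + bc.width > bc.upper + 1e-9:
        raise ValueError(
            f"{nb} bands per region do not fit the domain "
            f"[{bc.origin}, {bc.upper}) around the {bc.split_latitude} split"
        )

    # peak per-pixel load determines the pixel count needed per band
    peak_band_area = 0.0
    for region in region_bands:
        e = truth_regional.loc[truth_regional["region"] == region, "extent_km2"]
        peak_band_area = max(peak_band_area, float(e.max()) * 1e6 * weights.max())
    ppb = config.pixels_per_band
    if ppb is None:
        ppb = max(1, math.ceil(1.1 * peak_band_area / MAX_PIXEL_AREA_M2))
    if peak_band_area / ppb > MAX_PIXEL_AREA_M2:
        raise ValueError(
            f"peak band load {peak_band_area:.0f} m² over {ppb} pixels exceeds "
            f"the {MAX_PIXEL_AREA_M2:.0f} m² pixel capacity: increase pixels_per_band"
        )

    frames = []
    dropout_rows = []
    for region, bands in region_bands.items():
        extent = (
            truth_regional.loc[truth_regional["region"] == region]
            .set_index("year")["extent_km2"]
            .reindex(years)
            .to_numpy()
        )
        band_area = np.outer(extent * 1e6, weights)       # (ny, nb)
        pixel_area = np.repeat(band_area / ppb, ppb, axis=1)  # (ny, nb*ppb)

        lower = bc.band_lower_edge(bands)
        lat_one_year = np.repeat(lower, ppb) + np.tile(
            (np.arange(ppb) + 0.5) / ppb * bc.width, nb
        )
        cloud = rng.random((ny, nb)) < config.dropout_prob
        n_drop = int(round(config.dropout_fraction * ppb))
        mask = np.zeros((ny, nb * ppb), dtype=bool)
        for yi, bi in zip(*np.nonzero(cloud)):
            dropped = rng.choice(ppb, size=n_drop, replace=False)
            mask[yi, bi * ppb + dropped] = True
            dropout_rows.append(
                {"band_id": int(bands[bi]), "year": int(years[yi]), "n_dropped": n_drop}
            )
        area = pixel_area.copy()
        area[mask] = np.nan

        frames.append(
            pd.DataFrame(
                {
                    "latitude": np.tile(lat_one_year, ny),
                    "longitude": -123.8,
                    "year": np.repeat(years, nb * ppb),
                    "quarter": 3,
                    "canopy_area_m2": area.ravel(),
                }
            )
        )
    pixels = pd.concat(frames, ignore_index=True)
    dropout = pd.DataFrame(dropout_rows, columns=["band_id", "year", "n_dropped"])
    return pixels, ScenarioTruth(regional=truth_regional, dropout=dropout)


def apply_collapse_scenario(
    pixels: pd.DataFrame, split_year: int, suppression_factor: float
) -> pd.DataFrame:
    """Suppress observed canopy from the split year on; environment untouched.

    Every pixel's canopy area in years ≥ split_year is multiplied by the
    factor, modelling a biotic limit (grazing) the ocean indices cannot see.
    """
    if not 0 < suppression_factor <= 1:
        raise ValueError(
            f"suppression_factor must lie in (0, 1], got {suppression_factor}"
        )
    out = pixels.copy()
    post = out["year"] >= split_year
    out.loc[post, "canopy_area_m2"] = out.loc[post, "canopy_area_m2"] * suppression_factor
    return out
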