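"""Quality control and regional aggregation of satellite kelp-canopy pixels.

The canopy product reports kelp canopy area (m², 0–900) per 30 × 30 m
Landsat pixel per quarter.  A pixel with no value is *missing* — the sensor
cannot distinguish cloud-obscured water from water with zero kelp, so an
absent observation must never be counted as zero canopy.  The aggregation
therefore works band-by-band:

1. the study domain (default 38–40°N) is cut into half-open 0.1° latitude
   bands;
2. summer (Q3) pixel areas are summed per band and year, counting only
   pixels that carry an observation (an observed 0 m² counts as data);
3. a band-year whose data-pixel count falls below a fraction (default 90%)
   of that band's median count across years is flagged missing;
4. a region-year (north / south of the split latitude, default 39°N) is
   itself missing when more than a tolerance fraction (default 10%) of the
   region's active bands are flagged; otherwise the regional extent is the
   sum over unflagged bands, converted to km².

Flagged bands inside an accepted year are simply excluded (no infilling or
rescaling), which slightly underestimates the true extent; this is the
simplest defensible reading of a sum over available data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BandConfig",
    "assign_latitude_band",
    "summarize_band_years",
    "flag_band_years",
    "aggregate_regional_series",
    "aggregate_canopy",
    "read_canopy_csv",
    "write_regional_csv",
]

#: m² per km².
M2_PER_KM2 = 1e6

#: Relative snap applied before flooring so decimal band edges (38.1, 39.0)
#: land in the upper half-open band despite binary float rounding.
_EDGE_SNAP = 1e-9

CANOPY_COLUMNS = ["latitude", "longitude", "year", "quarter", "canopy_area_m2"]


@dataclass(frozen=True)
class BandConfig:
    """Spatial configuration of the banding scheme.

    Attributes
    ----------
    origin, upper:
        Half-open latitude domain [origin, upper) in decimal degrees N.
    width:
        Band width in degrees (0.1° matches the canopy product analysis).
    split_latitude:
        North/south boundary; a band whose lower edge is at or above it
        belongs to the north region.
    """

    origin: float = 38.0
    upper: float = 40.0
    width: float = 0.1
    split_latitude: float = 39.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if not self.origin < self.split_latitude < self.upper:
            raise ValueError(
                "split latitude must lie strictly inside the domain: "
                f"{self.origin} < {self.split_latitude} < {self.upper} fails"
            )

    def band_lower_edge(self, band_id: np.ndarray | int) -> np.ndarray | float:
        return self.origin + np.asarray(band_id) * self.width

    def band_region(self, band_id: np.ndarray | int) -> np.ndarray:
        """Region label per band: 'north' iff the band's lower edge ≥ split."""
        edges = np.atleast_1d(self.band_lower_edge(band_id))
        return np.where(edges >= self.split_latitude - _EDGE_SNAP, "north", "south")


def assign_latitude_band(
    latitude,
    origin: float = 38.0,
    width: float = 0.1,
    upper: float = 40.0,
):
    """Map latitude(s) to half-open band indices [origin + k·w, origin + (k+1)·w).

    Parameters
    ----------
    latitude:
        Scalar or array of decimal degrees N; must satisfy origin ≤ lat < upper.

    Returns
    -------
    int or ndarray of int
        ``floor((latitude - origin) / width)``, with a tiny upward snap so
        exact decimal boundaries resolve to the band they open.
    """
    if width <= 0:
        raise ValueError(f"band width must be positive, got {width}")
    lat = np.asarray(latitude, dtype=float)
    out_of_domain = (lat < origin) | (lat >= upper) | ~np.isfinite(lat)
    if np.any(out_of_domain):
        bad = np.atleast_1d(lat)[np.atleast_1d(out_of_domain)][0]
        raise ValueError(
            f"latitude {bad} outside the study domain [{origin}, {upper})"
        )
    band = np.floor((lat - origin) / width + _EDGE_SNAP).astype(int)
    return int(band) if np.isscalar(latitude) else band


def summarize_band_years(
    pixels: pd.DataFrame,
    quarter: int = 3,
    config: BandConfig | None = None,
) -> pd.DataFrame:
    """Sum observed canopy per (band, year) for one quarter.

    Parameters
    ----------
    pixels:
        Frame with columns latitude, longitude, year, quarter,
        canopy_area_m2 (NaN = missing observation).
    quarter:
        Calendar quarter to keep (3 = July–September, the summer canopy peak).

    Returns
    -------
    DataFrame with columns band_id, year, n_data_pixels, area_sum — one row
    per (band, year) that has at least one observed pixel.  Observed zeros
    count as data; missing pixels count toward neither field.
    """
    config = config or BandConfig()
    if pixels.empty:
        return pd.DataFrame(
            columns=["band_id", "year", "n_data_pixels", "area_sum"]
        ).astype({"band_id": int, "year": int, "n_data_pixels": int, "area_sum": float})

    sel = pixels.loc[pixels["quarter"] == quarter].copy()
    sel = sel.loc[sel["canopy_area_m2"].notna()]
    if sel.empty:
        return summarize_band_years(pd.DataFrame(columns=pixels.columns), quarter, config)

    area = sel["canopy_area_m2"].to_numpy(dtype=float)
    if (area < 0).any() or (area > 900).any():
        raise ValueError("canopy_area_m2 must lie in [0, 900] m² per pixel")

    sel["band_id"] = assign_latitude_band(
        sel["latitude"].to_numpy(), config.origin, config.width, config.upper
    )
    grouped = (
        sel.groupby(["band_id", "year"], as_index=False)
        .agg(n_data_pixels=("canopy_area_m2", "size"), area_sum=("canopy_area_m2", "sum"))
        .sort_values(["band_id", "year"], ignore_index=True)
    )
    return grouped


def flag_band_years(
    summaries: pd.DataFrame,
    qc_fraction: float = 0.90,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Flag band-years whose data-pixel count is below a fraction of the band median.

    For each band the median of ``n_data_pixels`` is taken across the years
    that have a summary (even count → mean of the middle two).  A band-year
    is flagged missing iff its count is *strictly* below
    ``qc_fraction × median``; band-years with no summary at all are flagged.

    Parameters
    ----------
    years:
        Year universe for the full band × year grid; defaults to every year
        appearing in ``summaries``.

    Returns
    -------
    DataFrame with columns band_id, year, n_data_pixels (0 when absent),
    median_pixels, flagged (bool), over the full band × year grid.
    """
    if not 0 < qc_fraction <= 1:
        raise ValueError(f"qc_fraction must lie in (0, 1], got {qc_fraction}")
    if summaries.empty:
        return pd.DataFrame(
            columns=["band_id", "year", "n_data_pixels", "median_pixels", "flagged"]
        )

    if years is None:
        years = sorted(summaries["year"].unique())
    bands = sorted(summaries["band_id"].unique())

    grid = pd.MultiIndex.from_product([bands, years], names=["band_id", "year"])
    full = (
        summaries.set_index(["band_id", "year"])
        .reindex(grid)
        .reset_index()
    )
    observed = full["n_data_pixels"].notna()
    medians = summaries.groupby("band_id")["n_data_pixels"].median()
    full["median_pixels"] = full["band_id"].map(medians)
    full["flagged"] = ~observed | (
        full["n_data_pixels"] < qc_fraction * full["median_pixels"]
    )
    full["n_data_pixels"] = full["n_data_pixels"].fillna(0).astype(int)
    return full[["band_id", "year", "n_data_pixels", "median_pixels", "flagged"]]


def aggregate_regional_series(
    summaries: pd.DataFrame,
    flags: pd.DataFrame,
    config: BandConfig | None = None,
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Combine flagged band-years into annual regional canopy extents.

    A region-year whose flagged-band fraction exceeds ``tolerance`` is
    missing (extent NaN); otherwise the extent is the sum of ``area_sum``
    over unflagged band-years, in km².  The flagged-band fraction uses as
    denominator the number of *active* bands in the region — bands with a
    summary in at least one year.

    Returns
    -------
    DataFrame with columns region, year, extent_km2 (NaN = missing),
    missing_band_fraction, flagged_bands (';'-joined band ids).
    """
    config = config or BandConfig()
    if not 0 <= tolerance < 1:
        raise ValueError(f"tolerance must lie in [0, 1), got {tolerance}")

    flags = flags.merge(
        summaries[["band_id", "year", "area_sum"]], on=["band_id", "year"], how="left"
    )
    flags["area_sum"] = flags["area_sum"].fillna(0.0)
    flags["region"] = config.band_region(flags["band_id"].to_numpy())
    active = flags.drop_duplicates("band_id").groupby("region")["band_id"].size()
    for region in ("north", "south"):
        if region not in active.index or active[region] == 0:
            raise ValueError(f"no active bands in region '{region}'")

    rows = []
    for (region, year), grp in flags.groupby(["region", "year"]):
        flagged = grp.loc[grp["flagged"], "band_id"].tolist()
        fraction = len(flagged) / active[region]
        if fraction > tolerance:
            extent = np.nan
        else:
            extent = grp.loc[~grp["flagged"], "area_sum"].sum() / M2_PER_KM2
        rows.append(
            {
                "region": region,
                "year": int(year),
                "extent_km2": extent,
                "missing_band_fraction": fraction,
                "flagged_bands": ";".join(str(b) for b in sorted(flagged)),
            }
        )
    out = pd.DataFrame(rows).sort_values(["region", "year"], ignore_index=True)
    return out


def aggregate_canopy(
    pixels: pd.DataFrame,
    quarter: int = 3,
    config: BandConfig | None = None,
    qc_fraction: float = 0.90,
    tolerance: float = 0.10,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Full QC chain: pixels → band summaries → flags → regional series."""
    config = config or BandConfig()
    summaries = summarize_band_years(pixels, quarter=quarter, config=config)
    if summaries.empty:
        raise ValueError("no observed canopy pixels for the requested quarter")
    flags = flag_band_years(summaries, qc_fraction=qc_fraction, years=years)
    return aggregate_regional_series(summaries, flags, config=config, tolerance=tolerance)


def regional_extent_series(regional: pd.DataFrame, region: str) -> pd.Series:
    """Extract one region's year → extent_km2 series (NaN = missing year)."""
    sel = regional.loc[regional["region"] == region]
    if sel.empty:
        raise ValueError(f"region '{region}' absent from the aggregated table")
    return sel.set_index("year")["extent_km2"].sort_index()


def read_canopy_csv(path) -> pd.DataFrame:
    """Read the pixel CSV contract: latitude,longitude,year,quarter,canopy_area_m2.

    Empty canopy_area_m2 fields are missing observations (NaN), distinct
    from an observed 0 (zero kelp seen through clear sky).
    """
    df = pd.read_csv(path)
    missing = [c for c in CANOPY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"canopy CSV is missing columns: {missing}")
    df["year"] = df["year"].astype(int)
    df["quarter"] = df["quarter"].astype(int)
    if not df["quarter"].isin([1, 2, 3, 4]).all():
        raise ValueError("quarter must be an integer 1–4")
    return df[CANOPY_COLUMNS]


def write_regional_csv(regional: pd.DataFrame, path) -> None:
    regional.to_csv(path, index=False, float_format="%.9g")
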