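"""Replicated simulation studies that characterise the pipeline's statistics.

These are the package's own calibration experiments: parameter recovery at
published scale, the type-I error of the regression screen under a null
ocean, detectability of an environment–kelp decoupling regime, and the
exactness of the pixel → region round trip.  Each study is a pure function
of its seed and returns plain numbers/frames so it can back both the test
suite and reproduction scripts.

Problem sizes are chosen to keep each study in the tens of seconds on one
core: statistical stages run at the published scale (23 training years,
slope −0.77, R² ≈ 0.87), while studies that exercise the pixel rasteriser
use extents scaled down ~50× so a 0.1° band stays within the 900 m²/pixel
capacity at modest pixel counts (the QC arithmetic is scale-free).
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .canopy_qc import aggregate_canopy, regional_extent_series
from .forecast import forecast_years
from .pipeline import PipelineConfig, run_full_analysis
from .regression import fit_ols, screen_models
from .seasonal import build_pairs, predictor_series, seasonal_table
from .simulate import (
    RegionLink,
    ScenarioConfig,
    apply_collapse_scenario,
    gen_canopy_pixels,
    gen_monthly_indices,
    gen_regional_truth,
)
from .validation import loo_cross_validate

__all__ = [
    "scaled_scenario",
    "rep_seed",
    "slope_recovery_study",
    "screen_type1_study",
    "decoupling_study",
    "roundtrip_study",
]

#: published-scale north link: extent 3.04 km² at neutral winter index,
#: −0.77 km² per index unit, explaining ~87% of variance
NORTH_LINK = RegionLink("MOCI_south", season="winter", alpha=3.04, beta=-0.77,
                        target_r2=0.87)
SOUTH_LINK = RegionLink("MOCI_north", season="winter", alpha=5.52, beta=-0.19,
                        target_r2=0.57)

#: linear down-scaling applied to (alpha, beta) for pixel-level studies
PIXEL_SCALE = 0.02


def scaled_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The default two-region scenario with extents scaled by PIXEL_SCALE."""
    s = PIXEL_SCALE
    defaults = dict(
        index_names=("MOCI_north", "MOCI_south"),
        links={
            "north": RegionLink("MOCI_south", alpha=NORTH_LINK.alpha * s,
                                beta=NORTH_LINK.beta * s, target_r2=0.87),
            "south": RegionLink("MOCI_north", alpha=SOUTH_LINK.alpha * s,
                                beta=SOUTH_LINK.beta * s, target_r2=0.57),
        },
        seed=seed,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def rep_seed(base: int, rep: int) -> int:
    """Derive a replicate seed below 2³¹ from a base seed."""
    return (int(base) * 1_000_003 + rep) % (2**31)


def slope_recovery_study(n_reps: int = 500, seed: int = 0) -> pd.DataFrame:
    """Fit the winter model on replicated 23-year synthetic records.

    Each replicate draws a fresh monthly MOCI-like series and a kelp record
    from the published-scale link (α = 3.04, β = −0.77, noise tuned to
    R² ≈ 0.87), runs the seasonal and regression stages, and records the
    fitted slope with its 95% t-interval.

    Returns a frame with columns slope, r_squared, ci_low, ci_high, covered.
    """
    rows = []
    for rep in range(n_reps):
        s = rep_seed(seed, rep)
        cfg = ScenarioConfig(
            years=(1991, 2013),
            index_names=("MOCI_south",),
            links={"north": NORTH_LINK},
            seed=s,
        )
        indices = gen_monthly_indices(cfg)
        truth = gen_regional_truth(cfg, indices)
        kelp = truth.set_index("year")["extent_km2"].rename_axis("kelp_year")
        table = seasonal_table(indices, cfg.kelp_years)
        pred = predictor_series(table, "MOCI_south", "winter")
        fit = fit_ols(build_pairs(kelp, pred, cfg.years))
        lo, hi = fit.slope_ci(0.95)
        rows.append(
            {
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "ci_low": lo,
                "ci_high": hi,
                "covered": lo <= NORTH_LINK.beta <= hi,
            }
        )
    return pd.DataFrame(rows)


def screen_type1_study(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05
) -> tuple[int, int]:
    """Count significant screen cells when no predictor drives the kelp.

    The null ocean uses independent white-noise monthly indices (φ = 0, no
    cross-correlation) so every cell of the screen is an independent test
    and the rejection count has an exact binomial reference.  Kelp is pure
    noise around the published north intercept.

    Returns (n_unmasked_cells, n_total_cells).
    """
    null_link = RegionLink("MOCI_north", alpha=3.04, beta=0.0, target_r2=0.5)
    unmasked = total = 0
    for rep in range(n_reps):
        s = rep_seed(seed, rep)
        cfg = ScenarioConfig(
            years=(1991, 2013),
            index_names=("MOCI_north", "MOCI_south", "BEUTI_39N", "SST_N14"),
            phi=0.0,
            cross_correlation=0.0,
            links={"north": null_link},
            noise_sd={"north": 0.8},
            seed=s,
        )
        indices = gen_monthly_indices(cfg)
        truth = gen_regional_truth(cfg, indices)
        kelp = truth.set_index("year")["extent_km2"].rename_axis("kelp_year")
        table = seasonal_table(indices, cfg.kelp_years)
        screen = screen_models({"north": kelp}, table, alpha=alpha,
                               year_range=cfg.years)
        unmasked += int((~screen["masked"]).sum())
        total += len(screen)
    return unmasked, total


@dataclass(frozen=True)
class DecouplingResult:
    per_rep: pd.DataFrame  # pre_loo_mean_error, post_mean_error, detected
    detection_rate: float


def decoupling_study(
    n_reps: int = 200,
    seed: int = 0,
    suppression_factor: float = 0.1,
    detection_multiple: float = 3.0,
) -> DecouplingResult:
    """Forecast-error behaviour when post-split kelp is biotically suppressed.

    Each replicate runs the full pixel pipeline: simulate indices and
    canopy, suppress observed canopy from 2014 on, aggregate with QC,
    select the north winter model on 1991–2013, cross-validate it
    leave-one-out, and forecast 2014–2020.  A replicate *detects* the
    regime shift when its mean post-split forecast error exceeds
    ``detection_multiple`` × the pre-split LOO mean error.
    """
    rows = []
    for rep in range(n_reps):
        s = rep_seed(seed, rep)
        cfg = scaled_scenario(seed=s)
        indices = gen_monthly_indices(cfg)
        pixels, _ = gen_canopy_pixels(cfg, indices)
        if suppression_factor < 1.0:
            pixels = apply_collapse_scenario(pixels, cfg.split_year,
                                             suppression_factor)
        regional = aggregate_canopy(pixels, config=cfg.band_config)
        kelp = regional_extent_series(regional, "north")
        table = seasonal_table(indices, cfg.kelp_years)
        pred = predictor_series(table, "MOCI_south", "winter")
        pre_pairs = build_pairs(kelp, pred, (cfg.years[0], cfg.split_year - 1))
        if len(pre_pairs) < 4:
            continue  # QC left too few complete pre-split years
        fit = fit_ols(pre_pairs)
        loo = loo_cross_validate(pre_pairs)
        fc = forecast_years(fit, pred, kelp, split_year=cfg.split_year)
        post_errors = fc["error_pct"].dropna()
        if post_errors.empty or not np.isfinite(loo.mean_error_pct):
            continue
        pre = loo.mean_error_pct
        post = float(post_errors.mean())
        rows.append(
            {
                "pre_loo_mean_error": pre,
                "post_mean_error": post,
                "detected": post > detection_multiple * pre,
            }
        )
    per_rep = pd.DataFrame(rows)
    return DecouplingResult(
        per_rep=per_rep, detection_rate=float(per_rep["detected"].mean())
    )


def roundtrip_study(seed: int = 0) -> dict[str, float | bool]:
    """Noiseless, cloud-free scenario: aggregation must reproduce the truth.

    Runs the full pipeline twice on identical inputs and reports the
    maximum |aggregated − generated| extent and whether the two report
    bundles are byte-identical.
    """
    cfg = scaled_scenario(
        seed=seed, noise_sd={"north": 0.0, "south": 0.0}, dropout_prob=0.0
    )
    indices = gen_monthly_indices(cfg)
    pixels, truth = gen_canopy_pixels(cfg, indices)
    regional = aggregate_canopy(pixels, config=cfg.band_config)
    merged = regional.merge(
        truth.regional, on=["region", "year"], suffixes=("_agg", "_truth")
    )
    max_abs_err = float(
        np.max(np.abs(merged["extent_km2_agg"] - merged["extent_km2_truth"]))
    )

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        canopy_csv, index_csv = tmp / "canopy.csv", tmp / "indices.csv"
        pixels.to_csv(canopy_csv, index=False, float_format="%.9g")
        indices.to_csv(index_csv, index=False, float_format="%.9g")
        byte_identical = True
        outputs: dict[str, bytes] = {}
        for run in ("a", "b"):
            out_dir = tmp / run
            run_full_analysis(
                PipelineConfig(
                    canopy_csv=str(canopy_csv), index_csv=str(index_csv),
                    out_dir=str(out_dir), log_level="WARNING",
                )
            )
            for path in sorted(out_dir.glob("*.csv")):
                if run == "a":
                    outputs[path.name] = path.read_bytes()
                elif outputs[path.name] != path.read_bytes():
                    byte_identical = False
    return {"max_abs_extent_error_km2": max_abs_err, "byte_identical": byte_identical}
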