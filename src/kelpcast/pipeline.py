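"""End-to-end analysis: pixels + monthly indices → screen, selection, LOO, forecast.

The pipeline mirrors the published workflow: aggregate summer canopy into
two regional annual series, build seasonal predictors (with the lagged
fall), screen all univariate models over the pre-collapse years, select the
best per region by AIC among significant fits, cross-validate it
leave-one-out, and forecast the post-split years from the pre-split model.

All interchange is CSV — the underlying tables are small annual/monthly
records, and diffable text keeps every stage inspectable.  A failed stage
aborts the run, names itself in the error, and removes any partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import canopy_qc, forecast, regression, seasonal, validation
from .canopy_qc import BandConfig

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis"]

log = logging.getLogger("kelpcast")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    canopy_csv: str
    index_csv: str
    out_dir: str
    split_latitude: float = 39.0
    domain: tuple[float, float] = (38.0, 40.0)
    band_width: float = 0.1
    quarter: int = 3
    qc_fraction: float = 0.90
    tolerance: float = 0.10
    alpha: float = 0.05
    pre_years: tuple[int, int] = (1991, 2013)
    split_year: int = 2014
    regions: tuple[str, ...] = ("north", "south")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("domain", "pre_years", "regions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def band_config(self) -> BandConfig:
        return BandConfig(
            origin=self.domain[0],
            upper=self.domain[1],
            width=self.band_width,
            split_latitude=self.split_latitude,
        )


def run_full_analysis(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Outputs: regional_extent.csv, seasonal_predictors.csv,
    screen_table.csv, selected_models.csv, loo_validation.csv,
    forecast.csv and run_log.json (config echo + per-stage row counts).

    Returns the tables as DataFrames keyed by output name.  Deterministic:
    identical inputs and config give byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.9g")
        written.append(path)
        counts[name] = len(frame)
        tables[name] = frame
        log.info("%s: %d rows", name, len(frame))

    stage = "aggregate"
    try:
        pixels = canopy_qc.read_canopy_csv(config.canopy_csv)
        if pixels.empty:
            raise ValueError(f"canopy CSV {config.canopy_csv} contains no records")
        regional = canopy_qc.aggregate_canopy(
            pixels,
            quarter=config.quarter,
            config=config.band_config(),
            qc_fraction=config.qc_fraction,
            tolerance=config.tolerance,
        )
        emit("regional_extent", regional)

        stage = "seasons"
        monthly = seasonal.read_index_csv(config.index_csv)
        kelp_years = sorted(regional["year"].unique())
        season_table = seasonal.seasonal_table(monthly, kelp_years)
        emit("seasonal_predictors", season_table)

        stage = "screen"
        kelp_by_region = {
            r: canopy_qc.regional_extent_series(regional, r) for r in config.regions
        }
        screen = regression.screen_models(
            kelp_by_region, season_table, alpha=config.alpha,
            year_range=config.pre_years,
        )
        emit("screen_table", screen)

        stage = "fit"
        selected = {}
        model_rows = []
        for region in config.regions:
            sel = regression.select_model(
                screen, kelp_by_region[region], season_table, region,
                year_range=config.pre_years,
            )
            selected[region] = sel
            if sel.selected:
                model_rows.append(
                    {
                        "region": region,
                        "index_name": sel.index_name,
                        "season": sel.season,
                        "equation": sel.fit.equation(
                            f"{region}_kelp", f"{sel.season} {sel.index_name}"
                        ),
                        "r_squared": sel.fit.r_squared,
                        "p": sel.fit.p_slope,
                        "aic": sel.fit.aic,
                        "n": sel.fit.n,
                    }
                )
            else:
                log.warning("no significant model for region %s", region)
        emit("selected_models", pd.DataFrame(model_rows))

        stage = "validate"
        loo_rows = []
        for region, sel in selected.items():
            if not sel.selected:
                continue
            pred = seasonal.predictor_series(season_table, sel.index_name, sel.season)
            pairs = seasonal.build_pairs(
                kelp_by_region[region], pred, config.pre_years
            )
            report = validation.loo_cross_validate(pairs)
            rows = report.rows.copy()
            rows.insert(0, "region", region)
            loo_rows.append(rows)
            log.info(
                "%s LOO: mean refit R²=%.3f mean error=%.1f%% (sd %.1f)",
                region, report.mean_refit_r_squared,
                report.mean_error_pct, report.sd_error_pct,
            )
        emit(
            "loo_validation",
            pd.concat(loo_rows, ignore_index=True) if loo_rows
            else pd.DataFrame(columns=["region", "kelp_year", "predicted_km2",
                                       "error_pct", "refit_r2"]),
        )

        stage = "forecast"
        fc_rows = []
        for region, sel in selected.items():
            if not sel.selected:
                continue
            pred = seasonal.predictor_series(season_table, sel.index_name, sel.season)
            fc = forecast.forecast_years(
                sel.fit, pred, kelp_by_region[region],
                split_year=config.split_year, region=region,
                index_name=sel.index_name, season=sel.season,
            )
            fc_rows.append(fc)
        emit(
            "forecast",
            pd.concat(fc_rows, ignore_index=True) if fc_rows
            else pd.DataFrame(columns=["region", "index_name", "season", "year",
                                       "predicted_km2", "predicted_km2_clipped",
                                       "observed_km2", "error_pct"]),
        )

        stage = "report"
        run_log = {
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in asdict(config).items()},
            "row_counts": counts,
        }
        log_path = out_dir / "run_log.json"
        log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
        written.append(log_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    return tables
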