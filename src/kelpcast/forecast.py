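"""Out-of-period forecasting from a model trained on the pre-collapse years.

A model fitted strictly to years before the split (default 2014) is applied
to the seasonal predictor values of later years and compared with the
observed canopy extent.  Raw predictions may be negative — the linear model
knows nothing of the physical floor — so the table carries both the raw
value (used for the percent error, which is otherwise not reproducible) and
a zero-clipped value for reporting.

A leakage guard refuses to forecast any year the model was trained on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regression import OlsFit

__all__ = ["forecast_years"]


def forecast_years(
    fit: OlsFit,
    predictors: pd.Series,
    observed: pd.Series,
    split_year: int = 2014,
    region: str = "",
    index_name: str = "",
    season: str = "",
) -> pd.DataFrame:
    """Predict canopy extent for every year ≥ split_year with a predictor value.

    Parameters
    ----------
    fit:
        Model trained on pre-split pairs only (its ``years`` are checked).
    predictors:
        kelp_year → seasonal predictor value (NaN rows are skipped).
    observed:
        kelp_year → observed extent km²; NaN or absent years get a blank
        error column.

    Returns
    -------
    DataFrame region, index_name, season, year, predicted_km2,
    predicted_km2_clipped, observed_km2, error_pct — error_pct is computed
    from the *raw* prediction and is NaN where the observation is missing
    or exactly zero.
    """
    trained = set(fit.years)
    leaking = sorted(y for y in trained if y >= split_year)
    if leaking:
        raise ValueError(
            f"model was trained on year(s) {leaking} at or after the "
            f"forecast split {split_year}: refusing to forecast"
        )
    target_years = sorted(
        int(y) for y in predictors.dropna().index if int(y) >= split_year
    )
    overlap = sorted(set(target_years) & trained)
    if overlap:  # unreachable when the guard above holds, kept for clarity
        raise ValueError(f"forecast year(s) {overlap} were used in training")

    rows = []
    for year in target_years:
        x = float(predictors.loc[year])
        raw = float(fit.predict(x))
        obs = float(observed.get(year, np.nan))
        if np.isnan(obs) or obs == 0:
            error_pct = np.nan
        else:
            error_pct = abs(obs - raw) / abs(obs) * 100.0
        rows.append(
            {
                "region": region,
                "index_name": index_name,
                "season": season,
                "year": year,
                "predicted_km2": raw,
                "predicted_km2_clipped": max(0.0, raw),
                "observed_km2": obs,
                "error_pct": error_pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "index_name", "season", "year", "predicted_km2",
            "predicted_km2_clipped", "observed_km2", "error_pct",
        ],
    )
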