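"""Leave-one-out cross-validation of the selected kelp–environment model.

Two statistics come out of the leave-one-out loop:

* *precision* — the mean of the in-sample R² of each refit (drop one year,
  refit on the rest).  For a stable model these track the full-period R²
  closely; large swings indicate single influential years.
* *predictability error* — for each left-out year, the absolute relative
  prediction error |y − ŷ| / |y| expressed as a percentage.  Denominators
  are kept raw (no floor): a small observed extent legitimately produces a
  triple-digit percentage.  Only an observed extent of exactly zero leaves
  the error undefined; such years are flagged and excluded from the
  aggregate mean/sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import fit_ols

__all__ = ["LooReport", "loo_cross_validate"]


@dataclass(frozen=True)
class LooReport:
    """Per-year leave-one-out results plus aggregates.

    ``rows`` has columns kelp_year, predicted_km2, error_pct (NaN when the
    observed extent is exactly 0), refit_r2.
    """

    rows: pd.DataFrame
    mean_refit_r_squared: float
    mean_error_pct: float
    sd_error_pct: float


def loo_cross_validate(pairs: pd.DataFrame) -> LooReport:
    """Refit the model once per year with that year held out.

    Parameters
    ----------
    pairs:
        Complete-case frame kelp_year, x, y with at least 4 rows (each
        refit needs 3).

    Returns
    -------
    LooReport with one row per held-out year, in year order.
    """
    n = len(pairs)
    if n < 4:
        raise ValueError(f"leave-one-out needs at least 4 pairs, got {n}")
    rows = []
    zero_years = []
    for i in range(n):
        held = pairs.iloc[i]
        refit = fit_ols(pairs.drop(pairs.index[i]))
        predicted = float(refit.predict(held["x"]))
        y = float(held["y"])
        if y == 0:
            error_pct = np.nan
            zero_years.append(int(held["kelp_year"]))
        else:
            error_pct = abs(y - predicted) / abs(y) * 100.0
        rows.append(
            {
                "kelp_year": int(held["kelp_year"]),
                "predicted_km2": predicted,
                "error_pct": error_pct,
                "refit_r2": refit.r_squared,
            }
        )
    if zero_years:
        warnings.warn(
            f"observed extent is 0 in year(s) {zero_years}: percent error "
            "undefined there, excluded from aggregates",
            stacklevel=2,
        )
    frame = pd.DataFrame(rows).sort_values("kelp_year", ignore_index=True)
    errors = frame["error_pct"].dropna()
    return LooReport(
        rows=frame,
        mean_refit_r_squared=float(frame["refit_r2"].mean()),
        mean_error_pct=float(errors.mean()) if len(errors) else float("nan"),
        sd_error_pct=float(errors.std(ddof=1)) if len(errors) > 1 else float("nan"),
    )
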