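"""Univariate regression screening, AIC model selection and auxiliary statistics.

Each candidate model regresses annual summer kelp canopy extent (km²) on a
single seasonal environmental predictor by ordinary least squares.  The
screen fits every (index, season) combination per region, masks cells whose
slope is not significant at level α (default 0.05), and the best model per
region is the significant candidate with the lowest AIC.

Inference assumes independent Gaussian errors; no autocorrelation
correction or multiple-testing adjustment is applied across the screen —
each cell is reported at its own per-test p-value, which is a caveat when
reading the table as a whole.

AIC uses the full Gaussian maximum-likelihood form

    AIC = n·ln(2π·SSE/n) + n + 2k,   k = 2 (slope, intercept),

so only differences between models fitted to the same n are meaningful.  A
perfect fit (SSE = 0) maps to −inf, which sorts first by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seasonal import SEASON_ORDER, build_pairs, predictor_series

__all__ = [
    "OlsFit",
    "fit_ols",
    "gaussian_aic",
    "screen_models",
    "select_model",
    "pearson_correlation",
    "linear_trend_test",
]

#: number of mean parameters in the univariate linear model
K_PARAMS = 2


@dataclass(frozen=True)
class OlsFit:
    """A fitted univariate OLS model y = intercept + slope·x.

    ``stderr_slope`` is the usual OLS standard error of the slope and
    ``years`` records the kelp years the fit was trained on (used by the
    forecasting leakage guard).
    """

    slope: float
    intercept: float
    n: int
    r_squared: float
    p_slope: float
    sse: float
    aic: float
    stderr_slope: float
    years: tuple[int, ...] = field(default=())

    def predict(self, x) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        tcrit = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (self.slope - tcrit * self.stderr_slope,
                self.slope + tcrit * self.stderr_slope)

    def equation(self, y_name: str = "kelp", x_name: str = "x") -> str:
        sign = "-" if self.slope < 0 else "+"
        return f"{y_name} = {self.intercept:.2f} {sign} {abs(self.slope):.2f} * {x_name}"


def gaussian_aic(n: int, sse: float, k: int = K_PARAMS) -> float:
    """Gaussian maximum-likelihood AIC; −inf for a perfect (SSE = 0) fit."""
    if sse < 0:
        raise ValueError(f"sse must be nonnegative, got {sse}")
    if sse == 0:
        return float("-inf")
    return n * math.log(2 * math.pi * sse / n) + n + 2 * k


def fit_ols(pairs: pd.DataFrame) -> OlsFit:
    """Fit y on x by ordinary least squares.

    Parameters
    ----------
    pairs:
        Complete-case frame with columns kelp_year, x, y (see
        :func:`kelpcast.seasonal.build_pairs`).

    Raises
    ------
    ValueError
        If fewer than 3 pairs are given or the predictor is constant.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs to fit, got {n}")
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope is not identifiable")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sse = float(resid @ resid)
    return OlsFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        sse=sse,
        aic=gaussian_aic(n, sse),
        stderr_slope=float(res.stderr),
        years=tuple(int(v) for v in pairs["kelp_year"]),
    )


def screen_models(
    kelp_by_region: dict[str, pd.Series],
    seasonal: pd.DataFrame,
    alpha: float = 0.05,
    year_range: tuple[int, int] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Fit every (region, index, season) combination and mask insignificant cells.

    Parameters
    ----------
    kelp_by_region:
        region name → kelp_year → extent_km2 series (NaN for missing years).
    seasonal:
        Long seasonal predictor table (index_name, season, kelp_year, value).
    alpha:
        Two-sided significance level for the slope; cells with
        p_slope ≥ alpha are masked.  Combinations with fewer than
        ``min_pairs`` complete pairs are masked with NaN statistics rather
        than failing the screen.

    Returns
    -------
    DataFrame region, index_name, season, n, slope, intercept, r_squared,
    p, aic, masked.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    names = sorted(seasonal["index_name"].unique())
    rows = []
    for region, kelp in kelp_by_region.items():
        for name in names:
            for season in SEASON_ORDER:
                try:
                    pred = predictor_series(seasonal, name, season)
                except ValueError:  # season absent from the predictor table
                    pred = pd.Series(dtype=float)
                pairs = build_pairs(kelp, pred, year_range)
                row = {
                    "region": region,
                    "index_name": name,
                    "season": season,
                    "n": len(pairs),
                }
                try:
                    fit = fit_ols(pairs)
                except ValueError:
                    row.update(
                        slope=np.nan, intercept=np.nan, r_squared=np.nan,
                        p=np.nan, aic=np.nan, masked=True,
                    )
                else:
                    row.update(
                        slope=fit.slope,
                        intercept=fit.intercept,
                        r_squared=fit.r_squared,
                        p=fit.p_slope,
                        aic=fit.aic,
                        masked=bool(fit.p_slope >= alpha),
                    )
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SelectedModel:
    """Outcome of AIC selection for one region; ``fit`` is None when no
    candidate was significant."""

    region: str
    index_name: str | None
    season: str | None
    fit: OlsFit | None

    @property
    def selected(self) -> bool:
        return self.fit is not None


def select_model(
    candidates: pd.DataFrame,
    kelp: pd.Series,
    seasonal: pd.DataFrame,
    region: str,
    year_range: tuple[int, int] | None = None,
) -> SelectedModel:
    """Pick the best significant model for one region by lowest AIC.

    Ties on AIC break toward higher R², then lexicographically smaller
    index name, so the choice is deterministic and independent of candidate
    order.  Returns a ``SelectedModel`` with ``fit=None`` when no candidate
    is significant.
    """
    cand = candidates.loc[
        (candidates["region"] == region) & (~candidates["masked"])
    ].copy()
    if cand.empty:
        return SelectedModel(region=region, index_name=None, season=None, fit=None)
    cand = cand.sort_values(
        ["aic", "r_squared", "index_name", "season"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = cand.iloc[0]
    pred = predictor_series(seasonal, best["index_name"], best["season"])
    fit = fit_ols(build_pairs(kelp, pred, year_range))
    return SelectedModel(
        region=region, index_name=best["index_name"], season=best["season"], fit=fit
    )


def pearson_correlation(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Pearson correlation on complete cases, p-value from t with n−2 df.

    Used both for the between-region kelp covariability check and for
    season-to-season correlation of environmental indices.
    """
    joined = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(joined) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(joined)}")
    if np.ptp(joined["x"]) == 0 or np.ptp(joined["y"]) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(joined["x"], joined["y"])
    return float(res.statistic), float(res.pvalue)


def linear_trend_test(series: pd.Series) -> tuple[float, float]:
    """Slope per year and its p-value for a year-indexed series (OLS on year)."""
    clean = series.dropna()
    pairs = pd.DataFrame(
        {"kelp_year": clean.index.astype(int), "x": clean.index.astype(float),
         "y": clean.to_numpy(dtype=float)}
    )
    fit = fit_ols(pairs)
    return fit.slope, fit.p_slope
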