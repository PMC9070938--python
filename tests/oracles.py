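"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive: explicit loops, the normal
equations written out, medians recomputed from sorted lists.  None of it
imports the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def ols_normal_equations(x, y):
    """Closed-form univariate least squares: slope, intercept, r_squared, sse."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    syy = float(((y - ybar) ** 2).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    sse = float(((y - intercept - slope * x) ** 2).sum())
    r_squared = sxy**2 / (sxx * syy) if syy > 0 else float("nan")
    return slope, intercept, r_squared, sse


def pearson_bruteforce(x, y):
    """Covariance over product of standard deviations, written out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cov = float(((x - x.mean()) * (y - y.mean())).sum()) / n
    sx = math.sqrt(float(((x - x.mean()) ** 2).sum()) / n)
    sy = math.sqrt(float(((y - y.mean()) ** 2).sum()) / n)
    return cov / (sx * sy)


def loo_bruteforce(years, x, y):
    """Exhaustive leave-one-out refits via the normal equations.

    Returns a list of dicts with year, predicted, error_pct (None when the
    held-out y is 0), refit_r2.
    """
    years = list(years)
    x = list(map(float, x))
    y = list(map(float, y))
    out = []
    for i in range(len(x)):
        xs = x[:i] + x[i + 1 :]
        ys = y[:i] + y[i + 1 :]
        slope, intercept, r2, _ = ols_normal_equations(xs, ys)
        pred = intercept + slope * x[i]
        err = None if y[i] == 0 else abs(y[i] - pred) / abs(y[i]) * 100.0
        out.append(
            {"year": years[i], "predicted": pred, "error_pct": err, "refit_r2": r2}
        )
    return out


def median_of(values):
    """Median with the even-count mean-of-middle-two convention."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def flags_bruteforce(counts: dict[tuple[int, int], int], qc_fraction: float,
                     bands, years):
    """Recompute band-year missing flags from a {(band, year): count} map.

    A band-year with no entry, or with count strictly below
    qc_fraction × (the band's median count over its observed years), is
    flagged.
    """
    flags = {}
    for b in bands:
        observed = [counts[(b, yr)] for yr in years if (b, yr) in counts]
        med = median_of(observed)
        for yr in years:
            if (b, yr) not in counts:
                flags[(b, yr)] = True
            else:
                flags[(b, yr)] = counts[(b, yr)] < qc_fraction * med
    return flags
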