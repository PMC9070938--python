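"""Seasonal environmental predictors aligned to kelp years.

Monthly ocean-index series (MOCI, buoy SST, BEUTI) are averaged over
three-month seasons and attached to the *kelp year* — the calendar year of
the summer canopy observation they are meant to predict:

* ``fall_prev``  — Oct–Dec of the year **before** the kelp year (the fall
  that precedes the overwintering gametophyte stage);
* ``winter``     — Jan–Mar of the kelp year;
* ``spring``     — Apr–Jun of the kelp year;
* ``summer``     — Jul–Sep of the kelp year (concurrent with the canopy
  observation).

A seasonal mean is only defined when all three months are present; a
partial mean over a 3-month window would be badly biased and there is no
principled fill rule, so any absent month makes the season missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "SEASON_ORDER",
    "seasonal_average",
    "seasonal_table",
    "predictor_series",
    "build_pairs",
    "read_index_csv",
    "write_seasonal_csv",
]

#: season name -> (kelp-year offset, calendar months)
SEASONS: dict[str, tuple[int, tuple[int, int, int]]] = {
    "fall_prev": (-1, (10, 11, 12)),
    "winter": (0, (1, 2, 3)),
    "spring": (0, (4, 5, 6)),
    "summer": (0, (7, 8, 9)),
}

SEASON_ORDER = ("fall_prev", "winter", "spring", "summer")

INDEX_COLUMNS = ["index_name", "year", "month", "value"]


def _monthly_lookup(monthly: pd.DataFrame) -> pd.Series:
    """(index_name, year, month) -> value, validating uniqueness."""
    keyed = monthly.set_index(["index_name", "year", "month"])["value"]
    if keyed.index.has_duplicates:
        dup = keyed.index[keyed.index.duplicated()][0]
        raise ValueError(f"duplicate monthly record for {dup}")
    return keyed


def seasonal_average(
    monthly: pd.DataFrame, index_name: str, season: str, kelp_year: int
) -> float:
    """Mean of one index over one season of one kelp year; NaN if any month absent."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASON_ORDER}")
    offset, months = SEASONS[season]
    keyed = _monthly_lookup(monthly)
    values = []
    for m in months:
        try:
            values.append(keyed.loc[(index_name, kelp_year + offset, m)])
        except KeyError:
            return float("nan")
    return float(np.mean(values))


def seasonal_table(
    monthly: pd.DataFrame, kelp_years: list[int] | range | None = None
) -> pd.DataFrame:
    """All seasonal predictors for every index and kelp year.

    Parameters
    ----------
    monthly:
        Long frame index_name, year, month, value.
    kelp_years:
        Kelp years to produce; defaults to every calendar year present.

    Returns
    -------
    DataFrame index_name, season, kelp_year, value (NaN for incomplete
    seasons), ordered by index, season, year.
    """
    keyed = _monthly_lookup(monthly)
    names = sorted(monthly["index_name"].unique())
    if kelp_years is None:
        kelp_years = sorted(monthly["year"].unique())
    kelp_years = [int(y) for y in kelp_years]

    wide = keyed.unstack("month")
    frames = []
    for season in SEASON_ORDER:
        offset, months = SEASONS[season]
        cols = [m for m in months if m in wide.columns]
        if len(cols) == len(months):
            vals = wide[list(months)].mean(axis=1, skipna=False)
        else:  # a whole month column absent from the input
            vals = pd.Series(np.nan, index=wide.index)
        source = pd.MultiIndex.from_product(
            [names, [y + offset for y in kelp_years]], names=["index_name", "year"]
        )
        frames.append(
            pd.DataFrame(
                {
                    "index_name": np.repeat(names, len(kelp_years)),
                    "season": season,
                    "kelp_year": np.tile(kelp_years, len(names)),
                    "value": vals.reindex(source).to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    order = {s: i for i, s in enumerate(SEASON_ORDER)}
    out = out.sort_values(
        ["index_name", "season", "kelp_year"],
        key=lambda c: c.map(order) if c.name == "season" else c,
        ignore_index=True,
    )
    return out


def predictor_series(
    seasonal: pd.DataFrame, index_name: str, season: str
) -> pd.Series:
    """One (index, season) predictor as a kelp_year → value series."""
    sel = seasonal.loc[
        (seasonal["index_name"] == index_name) & (seasonal["season"] == season)
    ]
    if sel.empty:
        raise ValueError(f"no seasonal values for ({index_name}, {season})")
    return sel.set_index("kelp_year")["value"].sort_index()


def build_pairs(
    kelp: pd.Series,
    predictor: pd.Series,
    year_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Complete-case (x, y) pairs of predictor and kelp extent by kelp year.

    Years where either side is missing (NaN or absent) are dropped; the
    result is ascending in year.  ``year_range`` is an inclusive (first,
    last) filter.
    """
    joined = pd.DataFrame({"y": kelp, "x": predictor}).dropna()
    if year_range is not None:
        lo, hi = year_range
        joined = joined.loc[(joined.index >= lo) & (joined.index <= hi)]
    joined = joined.sort_index()
    out = joined.reset_index()
    out.columns = ["kelp_year", "y", "x"]
    return out[["kelp_year", "x", "y"]]


def read_index_csv(path) -> pd.DataFrame:
    """Read the monthly index CSV contract: index_name,year,month,value."""
    df = pd.read_csv(path)
    missing = [c for c in INDEX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"index CSV is missing columns: {missing}")
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    if not df["month"].between(1, 12).all():
        raise ValueError("month must be 1–12")
    if not np.isfinite(df["value"]).all():
        raise ValueError("monthly index values must be finite")
    return df[INDEX_COLUMNS]


def write_seasonal_csv(seasonal: pd.DataFrame, path) -> None:
    seasonal.to_csv(path, index=False, float_format="%.9g")
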