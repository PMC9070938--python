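from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kelpcast import BandConfig, ScenarioConfig
from kelpcast.experiments import scaled_scenario


def small_scale_config(**overrides) -> ScenarioConfig:
    """Published-scale scenario shape scaled down ~50x so bands stay within
    pixel capacity at modest pixel counts."""
    seed = overrides.pop("seed", 0)
    return scaled_scenario(seed=seed, **overrides)


def make_pixels(spec: dict[tuple[int, int], tuple[int, float]],
                config: BandConfig | None = None,
                quarter: int = 3,
                missing: dict[tuple[int, int], int] | None = None) -> pd.DataFrame:
    """Build a pixel frame from {(band, year): (n_pixels, area_per_pixel)}.

    ``missing`` optionally adds {(band, year): k} pixels with no
    observation (NaN canopy) on top of the observed ones.
    """
    config = config or BandConfig()
    rows = []
    for (band, year), (n, area) in spec.items():
        lower = config.origin + band * config.width
        for j in range(n):
            rows.append(
                {
                    "latitude": lower + (j + 0.5) / n * config.width,
                    "longitude": -123.8,
                    "year": year,
                    "quarter": quarter,
                    "canopy_area_m2": area,
                }
            )
    for (band, year), k in (missing or {}).items():
        lower = config.origin + band * config.width
        for j in range(k):
            rows.append(
                {
                    "latitude": lower + (j + 0.25) / max(k, 1) * config.width,
                    "longitude": -123.8,
                    "year": year,
                    "quarter": quarter,
                    "canopy_area_m2": np.nan,
                }
            )
    return pd.DataFrame(rows)


def make_monthly(series: dict[str, dict[tuple[int, int], float]]) -> pd.DataFrame:
    """Build a monthly index frame from {name: {(year, month): value}}."""
    rows = [
        {"index_name": name, "year": y, "month": m, "value": v}
        for name, vals in series.items()
        for (y, m), v in vals.items()
    ]
    return pd.DataFrame(rows)


def make_pairs(years, x, y) -> pd.DataFrame:
    return pd.DataFrame({"kelp_year": list(years), "x": list(x), "y": list(y)})


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def qc_fixture():
    """5 bands × 10 years with hand-known flag structure.

    Band 0 carries the strict-inequality boundary: counts of 100 in eight
    years, 89 in 2003 (flagged: 89 < 0.9 × 100) and 90 in 2004 (not
    flagged: 90 is not < 90).  Band 3 has no summary in 2007 (flagged).
    Band 4 has a single observed year (its own median: never flagged).
    """
    years = list(range(2000, 2010))
    spec = {}
    for yr in years:
        spec[(0, yr)] = (100, 5.0)
        spec[(1, yr)] = (40, 2.0)
        spec[(2, yr)] = (60, 1.0)
        if yr != 2007:
            spec[(3, yr)] = (30, 4.0)
    spec[(0, 2003)] = (89, 5.0)
    spec[(0, 2004)] = (90, 5.0)
    spec[(4, 2005)] = (5, 3.0)
    expected_flags = {
        (b, yr): False for b in range(5) for yr in years
    }
    expected_flags[(0, 2003)] = True
    expected_flags[(3, 2007)] = True
    for yr in years:
        if yr != 2005:
            expected_flags[(4, yr)] = True  # no summary those years
    return spec, expected_flags, years
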