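"""Band assignment, band-year QC flags and regional aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kelpcast import (
    BandConfig,
    aggregate_canopy,
    aggregate_regional_series,
    assign_latitude_band,
    flag_band_years,
    summarize_band_years,
)
from conftest import make_pixels
from oracles import flags_bruteforce


class TestAssignLatitudeBand:
    @pytest.mark.parametrize(
        "lat,expected",
        [
            (38.00, 0),    # lower domain boundary opens band 0
            (39.00, 10),   # split boundary belongs to the band it opens
            (38.15, 1),
            (38.10, 1),    # decimal band edge despite binary float rounding
            (39.95, 19),
        ],
    )
    def test_examples(self, lat, expected):
        assert assign_latitude_band(lat) == expected

    @pytest.mark.parametrize("lat", [37.99, 40.0, 41.2, float("nan")])
    def test_outside_domain_rejected(self, lat):
        with pytest.raises(ValueError, match="domain"):
            assign_latitude_band(lat)

    def test_vectorized(self):
        lats = np.array([38.0, 38.55, 39.0, 39.99])
        assert assign_latitude_band(lats).tolist() == [0, 5, 10, 19]

    @given(
        band=st.integers(min_value=0, max_value=19),
        frac=st.floats(min_value=0.0, max_value=0.99),
    )
    @settings(derandomize=True, max_examples=200)
    def test_halfopen_floor_property(self, band, frac):
        lat = 38.0 + (band + frac) * 0.1
        assert assign_latitude_band(lat) == band


class TestSummarizeBandYears:
    def test_zero_counts_as_data_missing_does_not(self):
        pixels = make_pixels({(0, 2000): (1, 900.0)}, missing={(0, 2000): 1})
        pixels = pd.concat(
            [pixels, make_pixels({(0, 2000): (1, 0.0)})], ignore_index=True
        )
        out = summarize_band_years(pixels)
        assert len(out) == 1
        assert out.loc[0, "n_data_pixels"] == 2
        assert out.loc[0, "area_sum"] == 900.0

    def test_two_bands_two_years_bruteforce(self):
        spec = {(b, yr): (4, 10.0) for b in (0, 1) for yr in (2000, 2001)}
        out = summarize_band_years(make_pixels(spec))
        assert len(out) == 4
        assert (out["n_data_pixels"] == 4).all()
        assert (out["area_sum"] == 40.0).all()

    def test_all_missing_band_year_emits_nothing(self):
        pixels = make_pixels({}, missing={(2, 2000): 5})
        assert summarize_band_years(pixels).empty

    def test_empty_input_gives_empty_output(self):
        assert summarize_band_years(pd.DataFrame(
            columns=["latitude", "longitude", "year", "quarter", "canopy_area_m2"]
        )).empty

    def test_other_quarters_ignored(self):
        q1 = make_pixels({(0, 2000): (3, 10.0)}, quarter=1)
        q3 = make_pixels({(0, 2000): (2, 20.0)}, quarter=3)
        out = summarize_band_years(pd.concat([q1, q3], ignore_index=True), quarter=3)
        assert out.loc[0, "n_data_pixels"] == 2

    def test_area_out_of_range_rejected(self):
        pixels = make_pixels({(0, 2000): (1, 901.0)})
        with pytest.raises(ValueError, match="900"):
            summarize_band_years(pixels)


def _summaries_from_counts(counts: dict[tuple[int, int], int]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"band_id": b, "year": yr, "n_data_pixels": n, "area_sum": float(n)}
            for (b, yr), n in counts.items()
        ]
    )


class TestFlagBandYears:
    def test_strict_inequality_boundary(self):
        counts = {(0, y): c for y, c in zip(range(4), [100, 100, 100, 89])}
        flags = flag_band_years(_summaries_from_counts(counts)).set_index(
            ["band_id", "year"]
        )["flagged"]
        assert flags.loc[(0, 3)]          # 89 < 0.9 * 100
        assert not flags.loc[(0, 0)]

        counts = {(0, y): c for y, c in zip(range(3), [100, 100, 90])}
        flags = flag_band_years(_summaries_from_counts(counts)).set_index(
            ["band_id", "year"]
        )["flagged"]
        assert not flags.loc[(0, 2)]      # 90 is not < 90

    def test_single_year_band_never_flagged(self):
        flags = flag_band_years(_summaries_from_counts({(0, 2000): 5}))
        assert not flags["flagged"].any()

    def test_even_year_count_median_is_mean_of_middle_two(self):
        # counts {10, 20, 30, 40}: median 25, threshold 22.5 → 10 and 20 flagged
        counts = {(0, y): c for y, c in zip(range(4), [10, 20, 30, 40])}
        flags = flag_band_years(_summaries_from_counts(counts)).set_index(
            ["band_id", "year"]
        )["flagged"]
        assert flags.loc[(0, 0)] and flags.loc[(0, 1)]
        assert not flags.loc[(0, 2)] and not flags.loc[(0, 3)]

    @pytest.mark.parametrize("qc_fraction", [0.0, -0.1, 1.5])
    def test_bad_fraction_rejected(self, qc_fraction):
        with pytest.raises(ValueError, match="qc_fraction"):
            flag_band_years(_summaries_from_counts({(0, 2000): 5}), qc_fraction)

    def test_fixture_matches_hand_derivation(self, qc_fixture):
        spec, expected, years = qc_fixture
        summaries = summarize_band_years(make_pixels(spec))
        flags = flag_band_years(summaries, years=years).set_index(
            ["band_id", "year"]
        )["flagged"]
        for key, want in expected.items():
            assert flags.loc[key] == want, f"flag mismatch at {key}"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_fixtures_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        bands = list(range(rng.integers(1, 6)))
        years = list(range(2000, 2000 + int(rng.integers(2, 11))))
        counts = {}
        for b in bands:
            for yr in years:
                if rng.random() < 0.85:
                    counts[(b, yr)] = int(rng.integers(1, 120))
        if not counts:
            counts[(bands[0], years[0])] = 10
        qc = float(rng.uniform(0.5, 1.0))
        got = flag_band_years(_summaries_from_counts(counts), qc, years=years)
        got = got.set_index(["band_id", "year"])["flagged"]
        want = flags_bruteforce(counts, qc, sorted({b for b, _ in counts}), years)
        for key, flag in want.items():
            assert got.loc[key] == flag, f"seed {seed}: mismatch at {key}"


class TestAggregateRegionalSeries:
    def _flags_and_summaries(self, counts, areas=None, qc=0.9, years=None):
        summaries = _summaries_from_counts(counts)
        if areas is not None:
            summaries["area_sum"] = summaries.apply(
                lambda r: areas.get((r["band_id"], r["year"]), r["area_sum"]), axis=1
            )
        return summaries, flag_band_years(summaries, qc, years=years)

    def test_two_of_ten_bands_flagged_makes_year_missing(self):
        # 10 north bands (ids 10–19), two starved in 1996
        counts = {}
        for b in range(10, 20):
            for yr in (1995, 1996):
                counts[(b, yr)] = 100
        counts[(10, 1996)] = 10
        counts[(11, 1996)] = 10
        # give the south one healthy band so the region partition is valid
        for yr in (1995, 1996):
            counts[(0, yr)] = 50
        summaries, flags = self._flags_and_summaries(counts)
        out = aggregate_regional_series(summaries, flags).set_index(["region", "year"])
        assert np.isnan(out.loc[("north", 1996), "extent_km2"])
        assert out.loc[("north", 1996), "missing_band_fraction"] == pytest.approx(0.2)
        assert out.loc[("north", 1996), "flagged_bands"] == "10;11"
        assert not np.isnan(out.loc[("north", 1995), "extent_km2"])

    def test_extent_unit_conversion(self):
        # 10 unflagged bands, each 1e5 m² → 1.0 km²
        counts = {(b, 2000): 10 for b in range(10, 20)}
        counts[(0, 2000)] = 10
        areas = {(b, 2000): 1e5 for b in range(10, 20)}
        summaries, flags = self._flags_and_summaries(counts, areas)
        out = aggregate_regional_series(summaries, flags).set_index(["region", "year"])
        assert out.loc[("north", 2000), "extent_km2"] == pytest.approx(1.0, abs=1e-12)

    def test_conservation_when_fully_observed(self, rng):
        spec = {}
        for b in range(20):
            for yr in range(2000, 2006):
                spec[(b, yr)] = (30, float(rng.uniform(0, 900)))
        pixels = make_pixels(spec)
        regional = aggregate_canopy(pixels)
        config = BandConfig()
        for region in ("north", "south"):
            sel = pixels["latitude"] >= 39.0 if region == "north" else pixels["latitude"] < 39.0
            for yr in range(2000, 2006):
                brute = pixels.loc[sel & (pixels["year"] == yr), "canopy_area_m2"].sum() / 1e6
                got = regional.set_index(["region", "year"]).loc[(region, yr), "extent_km2"]
                assert got == pytest.approx(brute, abs=1e-9)

    def test_monotonicity_in_thresholds(self, rng):
        spec = {}
        for b in range(20):
            for yr in range(2000, 2008):
                n = int(rng.integers(5, 60))
                spec[(b, yr)] = (n, 10.0)
        pixels = make_pixels(spec)
        base = aggregate_canopy(pixels, qc_fraction=0.9, tolerance=0.10)
        easier_qc = aggregate_canopy(pixels, qc_fraction=0.6, tolerance=0.10)
        easier_tol = aggregate_canopy(pixels, qc_fraction=0.9, tolerance=0.5)
        for easier in (easier_qc, easier_tol):
            present_base = base["extent_km2"].notna()
            present_easier = easier["extent_km2"].notna()
            assert (present_easier | ~present_base).all(), (
                "relaxing a threshold must never turn a present year missing"
            )

    def test_split_move_conserves_total(self, rng):
        spec = {
            (b, 2000): (20, float(rng.uniform(10, 800))) for b in range(20)
        }
        pixels = make_pixels(spec)
        totals = []
        for split in (38.9, 39.0, 39.1):
            cfg = BandConfig(split_latitude=split)
            reg = aggregate_canopy(pixels, config=cfg).set_index(["region", "year"])
            north = reg.loc[("north", 2000), "extent_km2"]
            south = reg.loc[("south", 2000), "extent_km2"]
            totals.append(north + south)
        assert totals[0] == pytest.approx(totals[1], abs=1e-9)
        assert totals[1] == pytest.approx(totals[2], abs=1e-9)
        # and the boundary band actually moved
        cfg_lo = BandConfig(split_latitude=38.9)
        cfg_hi = BandConfig(split_latitude=39.0)
        north_lo = aggregate_canopy(pixels, config=cfg_lo).set_index(["region", "year"]).loc[("north", 2000), "extent_km2"]
        north_hi = aggregate_canopy(pixels, config=cfg_hi).set_index(["region", "year"]).loc[("north", 2000), "extent_km2"]
        assert north_lo > north_hi

    def test_region_without_bands_raises(self):
        counts = {(b, 2000): 10 for b in range(10, 13)}  # north only
        summaries, flags = self._flags_and_summaries(counts)
        with pytest.raises(ValueError, match="south"):
            aggregate_regional_series(summaries, flags)

    @pytest.mark.parametrize("tolerance", [-0.1, 1.0, 1.5])
    def test_bad_tolerance_rejected(self, tolerance):
        counts = {(0, 2000): 10, (10, 2000): 10}
        summaries, flags = self._flags_and_summaries(counts)
        with pytest.raises(ValueError, match="tolerance"):
            aggregate_regional_series(summaries, flags, tolerance=tolerance)
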