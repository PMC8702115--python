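"""Zone masks, zonal descriptive statistics and the feature table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corneasym import (
    FEATURE_NAMES,
    build_zone_mask,
    cumulative_within_range,
    extract_zone_values,
    featurize_case,
    featurize_cohort,
    summarize_zone,
    zone_column,
)
from corneasym.grid import GRID_SIZE
from corneasym.zones import EmptyZoneError, read_feature_table, signed_mean_abs, write_arff, write_feature_table

from conftest import make_diff
from oracles import extract_zone_brute, summarize_brute, zone_lattice_count

ZONE_COUNTS = {2.0: 317, 3.0: 709, 4.0: 1257, 5.0: 1961, 6.0: 2821}


class TestZoneMask:
    @pytest.mark.parametrize("diameter,count", sorted(ZONE_COUNTS.items()))
    def test_published_point_counts(self, diameter, count):
        assert build_zone_mask(diameter).point_count == count

    def test_tiny_zone_boundary_inclusive(self):
        # r = 0.05 mm reaches no neighbor; only the apex cell qualifies
        assert build_zone_mask(0.1).point_count == 1
        # r = 0.1 mm includes the four axis neighbors exactly on the boundary
        assert build_zone_mask(0.2).point_count == 5

    @pytest.mark.parametrize("diameter", [0.3, 0.7, 1.35, 2.05, 4.999, 6.0, 9.8, 13.95])
    def test_counts_match_brute_force_enumeration(self, diameter):
        assert build_zone_mask(diameter).point_count == zone_lattice_count(diameter)

    def test_invalid_diameters_rejected(self):
        for bad in (0.0, -1.0, 14.1):
            with pytest.raises(ValueError):
                build_zone_mask(bad)

    def test_masks_are_nested(self):
        prev = build_zone_mask(2.0).mask
        for d in (3.0, 4.0, 5.0, 6.0):
            cur = build_zone_mask(d).mask
            assert (prev <= cur).all()
            prev = cur


class TestExtractZoneValues:
    def test_zero_map_yields_zone_count_zeros(self):
        values, n_valid, n_missing = extract_zone_values(
            make_diff(np.zeros((GRID_SIZE, GRID_SIZE))), build_zone_mask(2.0)
        )
        assert len(values) == 317 and n_valid == 317 and n_missing == 0
        assert (values == 0).all()

    def test_all_missing_zone(self, rng):
        grid = rng.normal(size=(GRID_SIZE, GRID_SIZE))
        mask = build_zone_mask(3.0)
        grid[mask.mask] = np.nan
        values, n_valid, n_missing = extract_zone_values(make_diff(grid), mask)
        assert len(values) == 0 and n_valid == 0 and n_missing == mask.point_count

    def test_matches_double_loop_oracle(self, rng):
        grid = rng.normal(0.0, 20.0, (GRID_SIZE, GRID_SIZE))
        grid[rng.random(grid.shape) < 0.07] = np.nan
        for d in (2.0, 4.0, 6.0):
            values, n_valid, n_missing = extract_zone_values(make_diff(grid), build_zone_mask(d))
            expected, exp_missing = extract_zone_brute(grid, d)
            assert n_missing == exp_missing
            np.testing.assert_array_equal(values, expected)


class TestSummarizeZone:
    def test_constant_zeros(self):
        s = summarize_zone(np.zeros(317))
        for feat in FEATURE_NAMES:
            assert s[feat] == 0.0, feat

    def test_symmetric_two_point_mass(self):
        values = np.array([-1.0] * 100 + [1.0] * 100)
        s = summarize_zone(values)
        assert s["mean"] == 0.0
        assert s["abs_mean"] == 1.0
        assert s["neg_volume"] == pytest.approx(1.0)
        assert s["pos_volume"] == pytest.approx(1.0)
        assert s["total_volume"] == pytest.approx(2.0)
        assert s["volume_diff"] == pytest.approx(0.0)
        assert s["abs_max"] == 1.0 and s["range"] == 2.0

    def test_matches_independent_oracle_on_seeded_normals(self, rng):
        values = rng.standard_normal(1000)
        s = summarize_zone(values)
        expected = summarize_brute(values.tolist())
        for feat in FEATURE_NAMES:
            assert s[feat] == pytest.approx(expected[feat], rel=1e-9, abs=1e-12), feat

    def test_empty_and_singleton(self):
        with pytest.raises(EmptyZoneError):
            summarize_zone([])
        with pytest.warns(UserWarning):
            s = summarize_zone([4.2])
        assert s["sd"] == 0.0 and s["mean"] == 4.2

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 400))
    def test_oracle_property(self, seed, n):
        values = np.random.default_rng(seed).normal(0.0, 15.0, n)
        s = summarize_zone(values)
        expected = summarize_brute(values.tolist())
        for feat in FEATURE_NAMES:
            assert s[feat] == pytest.approx(expected[feat], rel=1e-9, abs=1e-9), feat

    def test_sign_flip_symmetries(self, rng):
        v = rng.normal(1.0, 5.0, 500)
        a, b = summarize_zone(v), summarize_zone(-v)
        assert b["mean"] == pytest.approx(-a["mean"])
        assert b["median"] == pytest.approx(-a["median"])
        assert b["min"] == pytest.approx(-a["max"])
        assert b["max"] == pytest.approx(-a["min"])
        assert b["skew"] == pytest.approx(-a["skew"], rel=1e-12)
        for inv in ("abs_mean", "abs_max", "range", "central95_range", "sd",
                    "kurtosis", "total_volume", "abs_skew", "abs_median"):
            assert b[inv] == pytest.approx(a[inv], rel=1e-12), inv
        assert b["neg_volume"] == pytest.approx(a["pos_volume"])
        assert b["pos_volume"] == pytest.approx(a["neg_volume"])

    def test_constant_shift_invariances(self, rng):
        v = rng.normal(0.0, 3.0, 400)
        c = 7.25
        a, b = summarize_zone(v), summarize_zone(v + c)
        for shifted in ("mean", "median", "min", "max"):
            assert b[shifted] == pytest.approx(a[shifted] + c, rel=1e-12)
        for inv in ("sd", "range", "central95_range", "skew", "kurtosis"):
            assert b[inv] == pytest.approx(a[inv], rel=1e-9), inv

    def test_signed_mean_abs_alternative_reading(self, rng):
        v = rng.normal(2.0, 1.0, 100)
        assert signed_mean_abs(v) == pytest.approx(abs(v.mean()))


class TestFeaturizeCase:
    def test_zero_map_all_zero_features(self):
        row = featurize_case(make_diff(np.zeros((GRID_SIZE, GRID_SIZE))))
        feature_cols = [k for k in row if not k.endswith("n_valid")]
        assert len(feature_cols) == 5 * len(FEATURE_NAMES)
        assert all(row[k] == 0.0 for k in feature_cols)

    def test_positive_map_one_sided_volumes(self, rng):
        grid = np.abs(rng.normal(5.0, 1.0, (GRID_SIZE, GRID_SIZE))) + 0.1
        row = featurize_case(make_diff(grid))
        for d in (2.0, 3.0, 4.0, 5.0, 6.0):
            assert row[zone_column(d, "neg_volume")] == 0.0
            assert row[zone_column(d, "volume_diff")] == pytest.approx(
                row[zone_column(d, "total_volume")]
            )

    def test_nested_zone_range_monotonicity(self, rng):
        for _ in range(3):
            grid = rng.normal(0.0, 10.0, (GRID_SIZE, GRID_SIZE))
            row = featurize_case(make_diff(grid))
            ranges = [row[zone_column(d, "range")] for d in (2.0, 3.0, 4.0, 5.0, 6.0)]
            assert all(a <= b + 1e-12 for a, b in zip(ranges, ranges[1:]))

    def test_cohort_table_shape_and_roundtrip(self, rng, tmp_path):
        diffs = [make_diff(rng.normal(size=(GRID_SIZE, GRID_SIZE)), f"C{i}") for i in range(4)]
        table = featurize_cohort(diffs)
        assert table.shape == (4, 5 * (len(FEATURE_NAMES) + 1))
        assert table.index.is_unique
        path = write_feature_table(table, tmp_path / "features.csv")
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_arff_export_structure(self, rng, tmp_path):
        table = featurize_cohort([make_diff(rng.normal(size=(GRID_SIZE, GRID_SIZE)), "C0")])
        text = write_arff(table, tmp_path / "t.arff").read_text()
        assert text.startswith("@RELATION")
        assert text.count("@ATTRIBUTE") == table.shape[1] + 1
        assert "@DATA" in text


class TestCumulativeWithinRange:
    def test_all_zero_cases(self):
        fracs = cumulative_within_range({f"c{i}": np.zeros(10) for i in range(10)}, [1.0])
        assert fracs == [1.0]

    def test_single_case_threshold_crossing(self):
        fracs = cumulative_within_range({"c": np.array([7.0])}, [5.0, 10.0])
        assert fracs == [0.0, 1.0]

    def test_equals_cdf_of_abs_max(self, rng):
        cases = {f"c{i}": rng.normal(0, 5, 50) for i in range(200)}
        thresholds = [2.0, 5.0, 10.0, 20.0]
        fracs = cumulative_within_range(cases, thresholds)
        abs_max = np.array([np.abs(v).max() for v in cases.values()])
        expected = [(abs_max <= t).mean() for t in thresholds]
        assert fracs == pytest.approx(expected)
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            cumulative_within_range({}, [1.0])
        with pytest.raises(ValueError):
            cumulative_within_range({"c": np.zeros(3)}, [5.0, 1.0])
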