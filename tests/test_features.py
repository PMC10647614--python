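"""Windowing, TS statistics, DTW and feature assembly.

The DTW and moment-statistic implementations are checked against
independent oracles: exhaustive warping-path enumeration and direct
summation formulas.
"""

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogstage.features import (
    WindowSpec,
    _window_stats_array,
    assemble_feature_matrix,
    compute_ts_stats,
    dtw_distance,
    dtw_feature_block,
    select_scenario_features,
    sliding_windows,
)
from cogstage.measures import MEASURES, TS_STATS

from conftest import activity_frame


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def dtw_by_path_enumeration(a, b):
    """Minimal accumulated |.|-cost over all monotone warping paths,
    by recursive enumeration (independent of the DP implementation)."""

    @lru_cache(maxsize=None)
    def best(i, j):
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        candidates = []
        if i > 0:
            candidates.append(best(i - 1, j))
        if j > 0:
            candidates.append(best(i, j - 1))
        if i > 0 and j > 0:
            candidates.append(best(i - 1, j - 1))
        return cost + min(candidates)

    return best(len(a) - 1, len(b) - 1)


def moments_by_direct_summation(x):
    """Mean/SD/varcoeff/skew/kurtosis via explicit summation formulas."""
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    sd = (n / (n - 1) * m2) ** 0.5
    g1 = m3 / m2**1.5
    skew_adj = (n * (n - 1)) ** 0.5 / (n - 2) * g1
    g2 = m4 / m2**2 - 3.0
    kurt_adj = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * g2 + 6)
    return {
        "mean": mean,
        "std": sd,
        "varcoeff": sd / mean,
        "skew": skew_adj,
        "kurtosis": kurt_adj,
    }


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

class TestSlidingWindows:
    @pytest.mark.parametrize(
        "t,L,stride,expected",
        [
            (10, 10, 3, [(0, 9)]),
            (30, 10, 3, [(s, s + 9) for s in (0, 3, 6, 9, 12, 15, 18, 21)][:7]),
            (9, 10, 3, []),
            (0, 10, 3, []),
        ],
    )
    def test_examples(self, t, L, stride, expected):
        assert sliding_windows(t, WindowSpec(L, stride)) == expected

    def test_count_formula_matches_enumeration(self):
        """floor((t-L)/stride)+1 windows for every t<=100, L<=20, stride<=L."""
        for t in range(0, 101, 7):
            for L in (2, 5, 10, 20):
                for stride in {1, min(3, L), L}:
                    got = len(sliding_windows(t, WindowSpec(L, stride)))
                    want = 0 if t < L else (t - L) // stride + 1
                    assert got == want, (t, L, stride)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(1, 1)
        with pytest.raises(ValueError):
            WindowSpec(10, 11)


# ---------------------------------------------------------------------------
# TS statistics
# ---------------------------------------------------------------------------

class TestTSStats:
    def test_constant_window_conventions(self):
        st = compute_ts_stats([2.0] * 10)
        assert st == {
            "median": 2.0, "mean": 2.0, "std": 0.0,
            "varcoeff": 0.0, "skew": 0.0, "kurtosis": 0.0,
        }

    def test_symmetric_window(self):
        st = compute_ts_stats(list(range(1, 11)))
        assert st["mean"] == pytest.approx(5.5)
        assert st["median"] == pytest.approx(5.5)
        assert st["skew"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_on_random_windows(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(1, 100, size=rng.integers(4, 30)).tolist()
            st = compute_ts_stats(x)
            want = moments_by_direct_summation(x)
            for key, val in want.items():
                assert st[key] == pytest.approx(val, rel=1e-10), key

    def test_vectorized_equals_scalar_path(self):
        rng = np.random.default_rng(5)
        series = rng.uniform(0, 50, 40)
        spec = WindowSpec(10, 3)
        table = _window_stats_array(series, spec)
        for w, (s, e) in enumerate(sliding_windows(len(series), spec)):
            st = compute_ts_stats(series[s : e + 1])
            np.testing.assert_allclose(
                table[w], [st[k] for k in TS_STATS], rtol=1e-10
            )

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            compute_ts_stats([1.0, np.nan, 2.0])


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

class TestDTW:
    def test_identity_distance_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 10, rng.integers(1, 20))
            assert dtw_distance(x, x) == 0.0

    def test_single_cell(self):
        assert dtw_distance([0.0], [5.0]) == 5.0

    def test_small_example(self):
        assert dtw_distance([1, 2, 3], [1, 3]) == 1.0

    def test_matches_path_enumeration_on_short_series(self):
        series = [
            s for L in (1, 2, 3)
            for s in itertools.product((0, 1, 2), repeat=L)
        ]
        for a in series[::3]:
            for b in series[::3]:
                assert dtw_distance(a, b) == dtw_by_path_enumeration(a, b)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.uniform(0, 5, rng.integers(1, 15))
            b = rng.uniform(0, 5, rng.integers(1, 15))
            d = dtw_distance(a, b)
            assert d >= 0
            assert d == pytest.approx(dtw_distance(b, a))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    @given(
        a=st.lists(st.floats(0, 100), min_size=1, max_size=12),
        b=st.lists(st.floats(0, 100), min_size=1, max_size=12),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_metric_like_properties(self, a, b):
        d = dtw_distance(a, b)
        assert d >= 0.0
        assert d == pytest.approx(dtw_distance(b, a))
        assert dtw_distance(a, a) == 0.0


class TestDTWFeatureBlock:
    def _series(self, data):
        return {
            sid: activity_frame(sid, {"walk_count": vals})
            for sid, vals in data.items()
        }

    def test_single_subject_all_zero(self):
        series = self._series({"A": [1.0, 2.0]})
        block = dtw_feature_block("A", series, ["A"])
        assert (block == 0.0).all()
        assert len(block) == len(MEASURES)

    def test_identical_series_all_zero(self):
        series = self._series({s: [1.0, 2.0, 3.0] for s in "ABC"})
        block = dtw_feature_block("A", series, ["A", "B", "C"])
        assert (block == 0.0).all()

    def test_matches_pairwise_assembly(self):
        data = {"A": [0.0, 1.0, 2.0], "B": [2.0, 2.0], "C": [5.0, 0.0, 1.0]}
        series = self._series(data)
        block = dtw_feature_block("B", series, ["A", "B", "C"])
        for ref in "ABC":
            want = dtw_distance(data["B"], data[ref]) if ref != "B" else 0.0
            assert block[f"dtw_walk_count_{ref}"] == pytest.approx(want)

    def test_unknown_subject_rejected(self):
        with pytest.raises(KeyError):
            dtw_feature_block("Z", self._series({"A": [1.0]}), ["A"])


# ---------------------------------------------------------------------------
# Assembly and scenario selection
# ---------------------------------------------------------------------------

def _toy_matrix(n_days=40, stages=None):
    act = activity_frame("A", {"walk_count": np.linspace(10, 20, n_days)})
    if stages is None:
        stages = ["CH"] * n_days
    timeline = pd.DataFrame(
        {"subject_id": "A", "day_index": np.arange(n_days), "stage": stages}
    )
    subject = pd.Series(
        {"subject_id": "A", "age_at_baseline": 80.0, "gender": "female",
         "education_years": 16.0}
    )
    refs = ["A", "B"]
    block = pd.Series(
        {f"dtw_{m}_{r}": float(i) for i, (m, r) in
         enumerate((m, r) for m in MEASURES for r in refs)}
    )
    return assemble_feature_matrix(subject, act, timeline, block)


class TestAssembleFeatureMatrix:
    def test_shape_is_windows_by_feature_count(self):
        m = _toy_matrix(40)
        k = (40 - 10) // 3 + 1
        n_feat = 6 * len(MEASURES) + 2 * len(MEASURES) + 3
        assert m.shape == (k, n_feat + 5)  # + meta columns

    def test_all_ch_labels(self):
        assert (_toy_matrix(40)["label"] == "CH").all()

    def test_window_label_is_last_day_stage(self):
        stages = ["CH"] * 22 + ["TR"] * 18
        m = _toy_matrix(40, stages)
        # window w ends at day 3w+9; first TR-ending window has 3w+9 >= 22
        expected = ["TR" if 3 * w + 9 >= 22 else "CH" for w in range(len(m))]
        assert m["label"].tolist() == expected

    def test_si_windows_dropped(self):
        stages = ["CH"] * 30 + ["SI"] * 10
        m = _toy_matrix(40, stages)
        assert "SI" not in set(m["label"])
        assert len(m) < (40 - 10) // 3 + 1

    def test_dtw_and_demographics_constant_across_rows(self):
        m = _toy_matrix(40)
        for col in ["dtw_walk_count_B", "age", "gender", "edu"]:
            assert m[col].nunique() == 1


class TestScenarioSelection:
    def test_scenario2_sleep_only_has_33_feature_columns(self):
        m = _toy_matrix(40)
        out = select_scenario_features(m, 2, ("sleep",))
        assert len(out.columns) - 5 == 5 * 6 + 3

    def test_scenario3_all_categories_dimensionality(self):
        m = _toy_matrix(40)
        out = select_scenario_features(m, 3)
        assert len(out.columns) - 5 == 13 * 6 + 2 * 13 + 3

    def test_scenario1_all_categories_dimensionality(self):
        m = _toy_matrix(40)
        out = select_scenario_features(m, 1)
        assert len(out.columns) - 5 == 13 + 3

    def test_scenario1_values_are_window_means(self):
        m = _toy_matrix(40)
        out = select_scenario_features(m, 1)
        np.testing.assert_allclose(out["walk_count"], m["walk_count_mean"])

    def test_empty_category_set_rejected(self):
        with pytest.raises(ValueError):
            select_scenario_features(_toy_matrix(40), 2, ())

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            select_scenario_features(_toy_matrix(40), 4)
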