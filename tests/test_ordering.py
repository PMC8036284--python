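"""GDM2 synthetic variable, maximum-gradient grouping and cohort summary."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pculfdg import (
    DEFAULT_SCALES,
    FeatureRecord,
    GroupingError,
    ScaleSpec,
    classify,
    gdm2_distance,
    gdm2_pairwise,
    max_gradient_groups,
    pattern_object,
    summarize,
    synthetic_variable,
)
from pculfdg.ordering import OrderingResult, round_half_away

from oracles import best_gap_triple, gdm2_brute


def record(vals, nid="n", label="unknown"):
    return FeatureRecord(nid, *vals, label=label)


def full_grid():
    """All 4*3*3*3 = 108 possible ordinal profiles."""
    return [
        record(v, nid=f"g{i}")
        for i, v in enumerate(itertools.product(range(1, 5), *[range(1, 4)] * 3))
    ]


class TestPattern:
    def test_default_pattern_is_upper_pole_with_neutral_midpoint(self):
        assert pattern_object().values == (4, 3, 3, 2)

    def test_all_stimulant_pattern_takes_all_maxima(self):
        scales = tuple(
            ScaleSpec(s.variable, s.scale_max, s.weight, "stimulant")
            for s in DEFAULT_SCALES
        )
        assert pattern_object(scales).values == (4, 3, 3, 3)

    def test_pattern_satisfies_scale_invariants(self):
        # FeatureRecord validates scale bounds on construction
        assert pattern_object().label == "pattern"


class TestGDM2:
    def test_single_variable_three_object_context(self):
        """Hand-evaluated reference values for the ordinal context {1,2,3}."""
        X = np.array([[1.0], [2.0], [3.0]])
        d = gdm2_pairwise(X, np.array([1.0]))
        assert d[0, 1] == pytest.approx(0.5, abs=1e-15)
        assert d[0, 2] == pytest.approx(1.0, abs=1e-15)

    def test_identical_profiles_have_zero_distance(self):
        recs = [record((4, 3, 3, 2)), record((4, 3, 3, 2)), record((1, 1, 1, 1))]
        assert gdm2_distance(recs[0], recs[1], recs) == 0.0

    def test_record_must_belong_to_context(self):
        recs = [record((1, 1, 1, 1)), record((2, 2, 2, 2))]
        with pytest.raises(ValueError, match="context"):
            gdm2_distance(record((4, 3, 3, 3)), recs[0], recs)

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 4), st.integers(1, 3), st.integers(1, 3), st.integers(1, 3)
            ),
            min_size=2,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_range_and_self_distance(self, profiles):
        X = np.array(profiles, dtype=float)
        w = np.array([s.weight for s in DEFAULT_SCALES])
        d = gdm2_pairwise(X, w)
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.all((d >= 0) & (d <= 1))
        assert np.all(np.diag(d) == 0)

    def test_matches_bruteforce_on_random_cohort(self):
        rng = np.random.default_rng(7)
        X = rng.integers(1, 5, size=(9, 4)).astype(float)
        w = np.array([s.weight for s in DEFAULT_SCALES])
        d = gdm2_pairwise(X, w)
        for i in range(9):
            for k in range(9):
                assert d[i, k] == pytest.approx(gdm2_brute(X, w, i, k), abs=1e-12)


class TestSyntheticVariable:
    def test_pattern_clone_sorts_first_with_zero_distance(self):
        cohort = [record((4, 3, 3, 2), "hit"), record((1, 1, 1, 1)), record((2, 2, 2, 2))]
        res = synthetic_variable(cohort)
        assert res.distances[0] == 0.0
        assert res.sorted_ids()[0] == "hit"

    def test_exhaustive_grid_bounds_and_antipode(self):
        res = synthetic_variable(full_grid())
        assert np.all((res.distances >= 0) & (res.distances <= 1))
        worst = np.argmax(res.distances)
        assert full_grid()[worst].values[:3] == (1, 1, 1)

    def test_input_order_does_not_change_distances(self):
        cohort = full_grid()[:20]
        res = synthetic_variable(cohort)
        rev = synthetic_variable(cohort[::-1])
        assert np.allclose(res.distances, rev.distances[::-1], atol=1e-12)

    def test_pattern_exclusion_is_a_config_switch(self):
        cohort = [record((4, 3, 3, 2)), record((1, 1, 1, 1)), record((2, 1, 2, 2))]
        incl = synthetic_variable(cohort, pattern_in_context=True)
        excl = synthetic_variable(cohort, pattern_in_context=False)
        assert incl.distances[0] == excl.distances[0] == 0.0
        assert not np.allclose(incl.distances, excl.distances)


class TestMaxGradientGroups:
    def test_reference_gap_example(self):
        d = np.array([0.10, 0.12, 0.30, 0.32, 0.50, 0.52, 0.90])
        res = OrderingResult(
            nodule_ids=tuple(f"n{i}" for i in range(7)),
            distances=d,
            order=np.arange(7),
            pattern=pattern_object(),
        )
        grouped = max_gradient_groups(res)
        assert grouped.boundaries == pytest.approx((0.21, 0.41, 0.71))
        sizes = [grouped.groups.count(g) for g in ("I", "II", "III", "IV")]
        assert sizes == [2, 2, 2, 1]

    def test_tied_gaps_break_toward_earlier_index(self):
        d = np.arange(8) * 0.125  # all gaps exactly equal (0.125 is binary-exact)
        res = OrderingResult(tuple("abcdefgh"), d, np.arange(8), pattern_object())
        grouped = max_gradient_groups(res)
        # earliest three gaps selected -> singleton groups I-III
        assert [grouped.groups.count(g) for g in ("I", "II", "III", "IV")] == [1, 1, 1, 5]

    def test_matches_exhaustive_boundary_search(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            d = np.sort(rng.random(n))
            res = OrderingResult(tuple(map(str, range(n))), d, np.arange(n), pattern_object())
            grouped = max_gradient_groups(res)
            chosen_sum = sum(
                d[i + 1] - d[i]
                for i in range(n - 1)
                if grouped.groups[i] != grouped.groups[i + 1]
            )
            oracle_sum, _ = best_gap_triple(d)
            assert chosen_sum == pytest.approx(oracle_sum, abs=1e-12)

    def test_too_few_distinct_values_rejected(self):
        d = np.array([0.2, 0.2, 0.4, 0.4])
        res = OrderingResult(tuple("abcd"), d, np.arange(4), pattern_object())
        with pytest.raises(GroupingError):
            max_gradient_groups(res)

    def test_groups_partition_and_are_sorted_intervals(self):
        rng = np.random.default_rng(9)
        d = rng.random(25)
        order = np.argsort(d)
        res = OrderingResult(tuple(map(str, range(25))), d, order, pattern_object())
        grouped = max_gradient_groups(res)
        seq = [grouped.groups[i] for i in order]
        # contiguous blocks I..IV in sorted order
        blocks = [g for g, _ in itertools.groupby(seq)]
        assert blocks == sorted(set(seq), key=["I", "II", "III", "IV"].index)


class TestClassify:
    @pytest.mark.parametrize(
        "distance, expected",
        [(0.4, "malignant"), (0.0, "malignant"), (0.400001, "benign"), (1.0, "benign")],
    )
    def test_threshold_inclusive_on_malignant_side(self, distance, expected):
        res = OrderingResult(("n",), np.array([distance]), np.array([0]), pattern_object())
        assert classify(res) == [expected]


class TestSummarize:
    def test_reference_cohort_compositions(self):
        """The printed group compositions of the 69-nodule cohort."""
        stats = summarize([(33, 0), (6, 1), (1, 10), (0, 18)])
        assert stats["confident_pct"] == 73.9
        assert stats["indeterminate_pct"] == 26.1
        assert stats["accuracy_at_threshold_pct"] == 97.5
        shares = stats["group_label_shares_pct"]
        assert shares["I"]["malignant"] == 82.5
        assert shares["II"]["malignant"] == 15.0
        assert shares["II"]["benign"] == 3.4  # 1/29, one-decimal rounding
        assert shares["III"]["malignant"] == 2.5
        assert shares["III"]["benign"] == 34.5
        assert shares["IV"]["benign"] == 62.1
        assert round_half_away(shares["IV"]["benign"], 0) == 62.0

    def test_single_group_single_label(self):
        stats = summarize([(12, 0), (0, 0), (0, 0), (0, 0)])
        assert stats["confident_pct"] == 100.0
        assert stats["accuracy_at_threshold_pct"] == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize([(0, 0)] * 4)

    def test_weights_must_sum_to_one(self):
        bad = (
            ScaleSpec(1, 4, 0.5, "stimulant"),
            ScaleSpec(2, 3, 0.3, "stimulant"),
            ScaleSpec(3, 3, 0.05, "stimulant"),
            ScaleSpec(4, 3, 0.05, "neutral"),
        )
        with pytest.raises(ValueError, match="sum to 1"):
            synthetic_variable([record((1, 1, 1, 1))], scales=bad)
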