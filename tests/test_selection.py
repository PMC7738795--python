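"""Pseudolabel threshold determination and the two solvers."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfpaced.selection import (
    IGNORED,
    ClassThresholdSet,
    ProbabilityMatrix,
    determine_class_thresholds,
    predicted_class_counts,
    select_top_fraction,
    solve_class_balanced,
    solve_vanilla,
)

from oracles import brute_class_balanced, brute_thresholds, brute_vanilla


class TestProbabilityMatrix:
    def test_rejects_rows_not_summing_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            ProbabilityMatrix(np.array([[0.5, 0.4]]))

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="2 classes"):
            ProbabilityMatrix(np.array([[1.0]]))

    def test_default_sample_ids(self):
        pm = ProbabilityMatrix(np.array([[0.5, 0.5], [0.2, 0.8]]))
        assert list(pm.sample_ids) == [0, 1]


class TestPredictedClassCounts:
    @pytest.mark.parametrize(
        "P, expected",
        [
            ([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]], [2, 1]),
            ([[0.5, 0.5]], [1, 0]),  # tie -> lowest class index
        ],
    )
    def test_examples(self, P, expected):
        assert list(predicted_class_counts(np.array(P))) == expected

    def test_degenerate_one_hot(self):
        P = np.tile([1.0, 0.0, 0.0], (7, 1))
        assert list(predicted_class_counts(P)) == [7, 0, 0]

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="no predictions"):
            predicted_class_counts(np.zeros((0, 3)))


class TestDetermineClassThresholds:
    def test_rank_is_ceil_of_fraction_times_count(self):
        # class-0 probs of class-0-predicted samples: 0.9, 0.8, 0.7, 0.6
        P = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3], [0.6, 0.4], [0.1, 0.9]])
        t = determine_class_thresholds(P, 0.5)
        assert t.thresholds[0] == pytest.approx(0.8)  # rank ceil(2) = 2
        assert list(t.counts) == [4, 1]
        assert t.fraction == 0.5

    def test_full_fraction_is_class_minimum(self):
        P = np.array([[0.9, 0.1], [0.8, 0.2], [0.55, 0.45], [0.3, 0.7]])
        t = determine_class_thresholds(P, 1.0)
        assert t.thresholds[0] == pytest.approx(0.55)
        assert t.thresholds[1] == pytest.approx(0.7)

    def test_empty_class_gets_sentinel(self):
        P = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1]])
        t = determine_class_thresholds(P, 0.5)
        assert np.isnan(t.thresholds[1]) and np.isnan(t.thresholds[2])
        # and no pseudolabel may land on the sentinel classes
        out = solve_class_balanced(P, t)
        assert set(out.labels[out.selected]) <= {0}

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, p):
        with pytest.raises(ValueError, match="fraction"):
            determine_class_thresholds(np.array([[0.6, 0.4]]), p)

    def test_counts_sum_to_n(self, random_proba):
        P = random_proba(137, 5, seed=3)
        t = determine_class_thresholds(P, 0.2)
        assert t.counts.sum() == 137

    def test_matches_brute_force_sort(self, random_proba):
        for seed in range(20):
            P = random_proba(60, 4, seed=seed)
            for p in (0.05, 0.3, 1.0):
                got = determine_class_thresholds(P, p).thresholds
                want = brute_thresholds(P.tolist(), p)
                for g, w in zip(got, want):
                    assert (math.isnan(g) and math.isnan(w)) or g == pytest.approx(w)


class TestSolveClassBalanced:
    def _ts(self, thresholds, counts=None):
        thresholds = np.asarray(thresholds, dtype=float)
        if counts is None:
            counts = np.ones(len(thresholds), dtype=int)
        return ClassThresholdSet(thresholds=thresholds, counts=counts, fraction=0.5)

    def test_ratio_argmax_selects(self):
        out = solve_class_balanced(np.array([[0.7, 0.3]]), self._ts([0.6, 0.5]))
        assert out.labels[0] == 0
        assert out.confidences[0] == pytest.approx(0.7 / 0.6)

    def test_normalization_flips_raw_argmax(self):
        # raw argmax is class 0, but the rarer class 1 wins the ratio
        out = solve_class_balanced(np.array([[0.55, 0.45]]), self._ts([0.9, 0.4]))
        assert out.labels[0] == 1
        assert out.confidences[0] == pytest.approx(0.45 / 0.4)

    def test_unit_thresholds_ignore_non_degenerate_rows(self):
        P = np.array([[0.6, 0.4], [1.0, 0.0]])
        out = solve_class_balanced(P, self._ts([1.0, 1.0]))
        assert out.labels[0] == IGNORED
        assert out.labels[1] == 0  # probability exactly 1 reaches the cutoff

    def test_all_sentinels_warns_and_ignores_all(self):
        ts = ClassThresholdSet(
            thresholds=np.array([np.nan, np.nan]),
            counts=np.array([0, 0]),
            fraction=0.5,
        )
        with pytest.warns(UserWarning, match="sentinel"):
            out = solve_class_balanced(np.array([[0.6, 0.4]]), ts)
        assert out.n_selected == 0

    def test_restrict_to_argmax_mode(self):
        # same row as the flip test, but confined to its raw argmax class
        out = solve_class_balanced(
            np.array([[0.55, 0.45]]), self._ts([0.9, 0.4]), restrict_to_argmax=True
        )
        assert out.labels[0] == IGNORED  # 0.55/0.9 < 1, class 1 not considered

    def test_matches_brute_force(self, random_proba):
        for seed in range(30):
            n = 10 + 7 * seed
            P = random_proba(n, 2 + seed % 7, seed=100 + seed)
            t = determine_class_thresholds(P, 0.2)
            got = solve_class_balanced(P, t)
            want = brute_class_balanced(P.tolist(), list(t.thresholds))
            assert list(got.labels) == want


class TestSolveVanilla:
    def test_above_cutoff_selected(self):
        out = solve_vanilla(np.array([[0.8, 0.2]]), -math.log(0.7))
        assert out.labels[0] == 0

    def test_below_cutoff_ignored(self):
        out = solve_vanilla(np.array([[0.6, 0.4]]), -math.log(0.7))
        assert out.labels[0] == IGNORED

    def test_k_zero_selects_nothing(self, random_proba):
        P = random_proba(50, 3, seed=1)
        assert solve_vanilla(P, 0.0).n_selected == 0

    def test_negative_k_errors(self):
        with pytest.raises(ValueError, match="k must be"):
            solve_vanilla(np.array([[0.6, 0.4]]), -0.1)

    def test_matches_brute_force(self, random_proba):
        for seed in range(30):
            P = random_proba(80, 2 + seed % 7, seed=200 + seed)
            for k in (0.05, 0.3, 1.0):
                got = solve_vanilla(P, k)
                assert list(got.labels) == brute_vanilla(P.tolist(), k)


class TestSelectTopFraction:
    def test_full_fraction_selects_everything(self, random_proba):
        P = random_proba(120, 4, seed=5)
        out = select_top_fraction(P, 1.0, mode="class_balanced")
        assert out.n_selected == 120

    def test_count_invariant_per_class(self, random_proba):
        P = random_proba(100, 2, seed=6)
        pred = np.argmax(P, axis=1)
        t = determine_class_thresholds(P, 0.1)
        for c in range(2):
            n_c = int(np.sum(pred == c))
            passing = np.sum(P[pred == c, c] >= t.thresholds[c] * (1 - 1e-12))
            assert passing == math.ceil(0.1 * n_c)

    def test_balance_contrast(self, imbalanced_instance):
        P = imbalanced_instance
        bal = select_top_fraction(P, 0.1, mode="class_balanced")
        van = select_top_fraction(P, 0.1, mode="vanilla")
        assert van.n_selected == 10  # matched total budget
        assert van.counts_per_class(2)[1] == 0
        assert bal.counts_per_class(2)[1] == math.ceil(0.1 * 10)

    def test_vanilla_budget_and_tie_order(self):
        P = np.array([[0.8, 0.2], [0.8, 0.2], [0.7, 0.3], [0.4, 0.6]])
        out = select_top_fraction(P, 0.5, mode="vanilla")
        # budget ceil(0.5*4)=2; the two 0.8s win, earlier index first
        assert list(out.labels) == [0, 0, IGNORED, IGNORED]

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown mode"):
            select_top_fraction(np.array([[0.6, 0.4]]), 0.5, mode="soft")


class TestSelectionProperties:
    def test_monotonicity_in_fraction(self, random_proba):
        for seed in range(10):
            P = random_proba(150, 5, seed=300 + seed)
            prev = None
            for p in (0.05, 0.1, 0.2, 0.5, 1.0):
                sel = set(np.flatnonzero(
                    select_top_fraction(P, p, mode="class_balanced").selected
                ))
                if prev is not None:
                    assert prev <= sel
                prev = sel

    def test_permutation_equivariance(self, random_proba, rng):
        P = random_proba(80, 4, seed=7)
        perm = rng.permutation(80)
        base = select_top_fraction(P, 0.2, mode="class_balanced")
        permuted = select_top_fraction(P[perm], 0.2, mode="class_balanced")
        assert np.array_equal(permuted.labels, base.labels[perm])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        n=st.integers(1, 60),
        c=st.integers(2, 6),
        seed=st.integers(0, 10_000),
        p=st.floats(0.01, 1.0),
    )
    def test_solver_agrees_with_oracle_hypothesis(self, n, c, seed, p):
        P = np.random.default_rng(seed).dirichlet(np.ones(c), size=n)
        t = determine_class_thresholds(P, p)
        got = solve_class_balanced(P, t)
        assert list(got.labels) == brute_class_balanced(P.tolist(), list(t.thresholds))

    def test_assignment_serializes_to_table(self, random_proba):
        P = random_proba(10, 3, seed=9)
        out = select_top_fraction(P, 0.5, mode="class_balanced")
        df = out.to_frame(round_index=2)
        assert list(df.columns) == ["sample_id", "assigned_class", "confidence", "round"]
        assert (df["round"] == 2).all()
        assert (df["assigned_class"] == "IGNORED").sum() == 10 - out.n_selected
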