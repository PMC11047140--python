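"""Ordinal-weighted kappa, pairwise agreement, and the trial bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raterprof import (
    GroupSpec,
    InsufficientRatersError,
    ProfileDistribution,
    SimulationConfig,
    UndefinedKappaError,
    bootstrap_group_difference,
    classify_agreement,
    examiner_style,
    pairwise_agreement,
    simulate_study,
    weight_matrix,
    weighted_kappa,
)
from conftest import kappa_oracle, make_table


rating_pairs = st.integers(2, 25).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(-3, 3), min_size=n, max_size=n),
        st.lists(st.integers(-3, 3), min_size=n, max_size=n),
    )
)


class TestWeightedKappa:
    def test_identical_vectors_give_one(self):
        assert weighted_kappa([3, -2, 0, 1], [3, -2, 0, 1]) == pytest.approx(1.0)

    def test_worked_example(self):
        # hand evaluation of both double sums gives (11/12 - 9/16)/(7/16)
        assert weighted_kappa([-3, 0, 3, 3], [-3, 1, 3, 2], "linear") == pytest.approx(
            17 / 21, abs=1e-12
        )
        assert weighted_kappa([-3, 0, 3, 3], [-3, 1, 3, 2], "linear") == pytest.approx(
            0.810, abs=1e-3
        )

    def test_independent_ratings_approach_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(-3, 4, size=10_000)
        b = rng.integers(-3, 4, size=10_000)
        assert abs(weighted_kappa(a, b)) < 0.03

    def test_undefined_when_both_constant_same_category(self):
        with pytest.raises(UndefinedKappaError):
            weighted_kappa([2, 2, 2], [2, 2, 2])

    @given(rating_pairs, st.sampled_from(["linear", "quadratic"]))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_double_sum_oracle_and_symmetry(self, pair, weighting):
        a, b = pair
        expected = kappa_oracle(a, b, weighting)
        if math.isnan(expected):
            with pytest.raises(UndefinedKappaError):
                weighted_kappa(a, b, weighting)
            return
        assert weighted_kappa(a, b, weighting) == pytest.approx(expected, abs=1e-12)
        assert weighted_kappa(b, a, weighting) == pytest.approx(expected, abs=1e-12)

    @given(rating_pairs, st.randoms(use_true_random=False))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_invariant_to_trial_relabelling(self, pair, rnd):
        a, b = pair
        order = list(range(len(a)))
        rnd.shuffle(order)
        try:
            original = weighted_kappa(a, b)
        except UndefinedKappaError:
            return
        shuffled = weighted_kappa([a[i] for i in order], [b[i] for i in order])
        assert shuffled == pytest.approx(original, abs=1e-12)

    def test_two_adjacent_categories_reduce_to_unweighted_kappa(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 2, size=30)  # categories 0 and 1
            b = rng.integers(0, 2, size=30)
            try:
                ours = weighted_kappa(a, b, "linear")
            except UndefinedKappaError:
                continue
            ref = sklearn.cohen_kappa_score(a, b)
            if math.isnan(ref):
                continue
            # adjacent categories: partial credit never applies, so the
            # linear-weighted kappa equals plain Cohen's kappa
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_matches_sklearn_weighted_on_full_scale(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        labels = list(range(7))
        for weighting in ("linear", "quadratic"):
            for _ in range(25):
                a = rng.integers(-3, 4, size=40)
                b = rng.integers(-3, 4, size=40)
                ours = weighted_kappa(a, b, weighting)
                ref = sklearn.cohen_kappa_score(
                    a + 3, b + 3, labels=labels, weights=weighting
                )
                assert ours == pytest.approx(ref, abs=1e-10)


class TestPairwiseAgreement:
    def test_pair_count_formula(self):
        rows = [
            (f"r{r}", "g", f"t{t}", "same" if t == 0 else "different", (r + t) % 7 - 3, 1)
            for r in range(4)
            for t in range(3)
        ]
        aset = pairwise_agreement(make_table(rows), "g")
        assert aset.n_pairs == 6  # C(4, 2)
        assert aset.n_pairs + aset.n_undefined_pairs == 4 * 3 // 2

    def test_requires_two_raters(self):
        rows = [("r1", "g", "t1", "same", 1, 1)]
        with pytest.raises(InsufficientRatersError):
            pairwise_agreement(make_table(rows), "g")

    def test_vectorized_path_matches_scalar_kappa(self):
        cfg = SimulationConfig(groups=(GroupSpec("g", 8, examiner_style()),), seed=13)
        table, _ = simulate_study(cfg)
        aset = pairwise_agreement(table, "g")
        _, _, matrix = table.ratings_matrix("g")
        for (ra, rb), kappa in zip(aset.pairs, aset.pair_kappas):
            ids, _, _ = table.ratings_matrix("g")
            expected = weighted_kappa(matrix[ids.index(ra)], matrix[ids.index(rb)])
            assert kappa == pytest.approx(expected, abs=1e-12)

    def test_undefined_pairs_counted_not_averaged(self):
        rows = []
        for r, js in [("r1", [2, 2]), ("r2", [2, 2]), ("r3", [3, -3])]:
            for t, j in enumerate(js):
                rows.append((r, "g", f"t{t}", "same" if t == 0 else "different", j, 1))
        aset = pairwise_agreement(make_table(rows), "g")
        assert aset.n_undefined_pairs == 1  # r1-r2 both constant at +2
        assert aset.n_pairs == 3
        assert not math.isnan(aset.mean)


class TestClassifyAgreement:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (1.0, "excellent"),
            (0.75, "excellent"),
            (0.48, "fair"),
            (0.41, "fair"),
            (0.40, "poor"),
            (0.26, "poor"),
            (-1.0, "poor"),
        ],
    )
    def test_rule_of_thumb_labels(self, kappa, label):
        assert classify_agreement(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_agreement(1.5)


@pytest.fixture(scope="module")
def two_group_table():
    cfg = SimulationConfig(
        groups=(
            GroupSpec("a", 8, examiner_style()),
            GroupSpec("b", 8, examiner_style()),
        ),
        seed=31,
    )
    table, _ = simulate_study(cfg)
    return table


class TestBootstrap:
    def test_copy_group_gives_null_interval(self):
        rows = []
        judgments = {"r1": [3, 1, -2, 0], "r2": [2, 0, -3, -1]}
        for g, prefix in [("a", ""), ("b", "c_")]:
            for r, js in judgments.items():
                for t, j in enumerate(js):
                    rows.append(
                        (prefix + r, g, f"t{t}", "same" if t < 2 else "different", j, 1)
                    )
        boot = bootstrap_group_difference(make_table(rows), "a", "b", n_iterations=50, seed=0)
        assert np.all(boot.differences == 0.0)
        assert (boot.ci_lower, boot.ci_upper) == (0.0, 0.0)
        assert not boot.significant

    def test_bookkeeping_and_determinism(self, two_group_table):
        b1 = bootstrap_group_difference(two_group_table, "a", "b", n_iterations=200, seed=7)
        b2 = bootstrap_group_difference(two_group_table, "a", "b", n_iterations=200, seed=7)
        assert len(b1.differences) == 200
        np.testing.assert_array_equal(b1.differences, b2.differences)
        assert b1.ci_lower <= b1.ci_upper
        b3 = bootstrap_group_difference(two_group_table, "a", "b", n_iterations=200, seed=8)
        assert not np.array_equal(b1.differences, b3.differences)

    def test_stratified_option_runs(self, two_group_table):
        boot = bootstrap_group_difference(
            two_group_table, "a", "b", n_iterations=100, seed=3, stratified=True
        )
        assert len(boot.differences) == 100

    def test_homogeneous_group_agrees_more(self):
        tight = ProfileDistribution(threshold_jitter_sd=0.05)
        loose = ProfileDistribution(threshold_jitter_sd=0.7)
        cfg = SimulationConfig(
            groups=(GroupSpec("tight", 12, tight), GroupSpec("loose", 12, loose)),
            seed=17,
        )
        table, _ = simulate_study(cfg)
        k_tight = pairwise_agreement(table, "tight").mean
        k_loose = pairwise_agreement(table, "loose").mean
        assert k_tight > k_loose
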