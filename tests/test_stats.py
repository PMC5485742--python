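"""evaluation_stats: precision/recall, enrichment, contingency tests."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from oracles import (
    chi_square_yates_statistic,
    fisher_two_sided,
    hypergeom_pmf,
    hypergeom_sf_inclusive,
)
from trscout.stats import (
    bonferroni,
    fisher_exact_two_sided,
    fold_enrichment,
    precision_recall,
    tf_interaction_enrichment,
    welch_t_test,
    yates_chi_square,
)


class TestPrecisionRecall:
    def test_perfect_prediction(self):
        gold = {"a", "b", "c"}
        assert precision_recall(gold, gold) == (1.0, 1.0)

    def test_hand_counted_overlap(self):
        predicted = {"A", "B", "C", "D", "E"}
        gold = {"A", "B", "C", "X", "Y"}
        assert precision_recall(predicted, gold) == (0.6, 0.6)

    def test_disjoint_prediction(self):
        assert precision_recall({"a"}, {"b"}) == (0.0, 0.0)

    def test_universe_restricts_gold_for_recall(self):
        # gold members outside the eligible universe do not count against recall
        predicted, gold = {"a", "b"}, {"a", "b", "zz"}
        universe = {"a", "b", "c"}
        assert precision_recall(predicted, gold, universe) == (1.0, 1.0)

    def test_empty_prediction_flagged_nan(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            precision, recall = precision_recall(set(), {"a"})
        assert math.isnan(precision) and recall == 0.0

    def test_predicting_whole_universe_gives_full_recall(self):
        universe = {f"p{i}" for i in range(10)}
        gold = {"p1", "p5", "p9", "outside"}
        _, recall = precision_recall(universe, gold, universe)
        assert recall == 1.0


class TestFoldEnrichment:
    def test_hand_arithmetic_fold(self):
        universe = {f"f{i}" for i in range(100)}
        candidates = {f"f{i}" for i in range(10)}
        criterion = {f"f{i}" for i in range(6, 16)}  # contains f6..f9: k=4
        r = fold_enrichment(criterion, candidates, universe)
        assert (r.k, r.n, r.K, r.N) == (4, 10, 10, 100)
        assert r.fold == pytest.approx(4.0)

    def test_criterion_equal_to_universe(self):
        universe = {f"f{i}" for i in range(30)}
        candidates = {"f0", "f1"}
        r = fold_enrichment(universe, candidates, universe)
        assert r.fold == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_tail_probability_matches_enumeration(self):
        universe = {f"f{i}" for i in range(20)}
        candidates = {f"f{i}" for i in range(5)}
        criterion = {"f0", "f1", "f2", "f3", "f4", "f10"}  # k=5, n=6
        r = fold_enrichment(criterion, candidates, universe)
        assert r.p == pytest.approx(hypergeom_sf_inclusive(5, 20, 5, 6), abs=1e-12)

    def test_tested_denominator_restriction(self):
        universe = {f"f{i}" for i in range(10)}
        tested = {f"f{i}" for i in range(6)}
        candidates = {"f0", "f1", "f8"}  # f8 leaves the universe when restricted
        criterion = {"f0", "f1", "f2"}
        r = fold_enrichment(criterion, candidates, universe, tested, restrict_to_tested=True)
        assert (r.N, r.K, r.n, r.k) == (6, 2, 3, 2)

    def test_empty_criterion_flagged(self):
        with pytest.warns(UserWarning):
            r = fold_enrichment(set(), {"f0"}, {"f0", "f1"})
        assert math.isnan(r.fold)

    def test_p_monotone_in_k(self):
        # at fixed (N, K, n), a larger observed overlap is never less surprising
        ps = [hypergeom_sf_inclusive(k, 40, 8, 10) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_hypergeometric_masses_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            total = sum(
                hypergeom_pmf(k, N, K, n)
                for k in range(max(0, n + K - N), min(n, K) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestYatesChiSquare:
    def test_balanced_table_is_null(self):
        stat, p = yates_chi_square(10, 10, 10, 10)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_small_deviation_clamped_to_zero(self):
        # |ad - bc| = 5 <= N/2 = 10.5 -> statistic 0 after the clamp
        stat, _ = yates_chi_square(5, 5, 5, 6)
        assert stat == 0.0

    def test_matches_formula_oracle_and_library(self):
        stat, p = yates_chi_square(30, 70, 10, 90)
        assert stat == pytest.approx(chi_square_yates_statistic(30, 70, 10, 90), abs=1e-12)
        lib_stat, lib_p, _, _ = sps.chi2_contingency([[30, 70], [10, 90]], correction=True)
        assert stat == pytest.approx(lib_stat)
        assert p == pytest.approx(lib_p)

    def test_zero_margin_flagged(self):
        with pytest.warns(UserWarning):
            stat, p = yates_chi_square(0, 0, 5, 5)
        assert math.isnan(stat) and math.isnan(p)

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            n = a + b + c + d
            uncorrected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            stat, _ = yates_chi_square(a, b, c, d)
            assert stat <= uncorrected + 1e-12


class TestWelchAndBonferroni:
    def test_identical_samples(self):
        assert welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_zero_variance_equal_means(self):
        assert welch_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_closed_form_hand_computation(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        y = [10.0, 11.0, 12.0, 13.0, 14.0]
        t, p = welch_t_test(x, y)
        # equal variances s^2 = 2.5, n = 5: t = -10 / sqrt(2 * 2.5 / 5) = -10
        assert t == pytest.approx(-10.0)
        # Welch df reduces to 8 here; compare against the t distribution
        assert p == pytest.approx(2 * sps.t.sf(10.0, df=8), rel=1e-10)

    def test_pooled_variant_available(self):
        t_w, _ = welch_t_test([0, 1, 2], [1, 2, 3, 4, 5, 6], equal_var=False)
        t_p, _ = welch_t_test([0, 1, 2], [1, 2, 3, 4, 5, 6], equal_var=True)
        assert t_w != t_p

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_bonferroni_scales_and_clamps(self):
        assert bonferroni([0.01], m=7) == [pytest.approx(0.07)]
        assert bonferroni([0.2] * 7, m=7) == [1.0] * 7
        assert bonferroni([0.1, 0.02]) == [pytest.approx(0.2), pytest.approx(0.04)]


class TestTfInteractionEnrichment:
    def test_everyone_interacts_with_a_tf(self):
        edges = [(f"p{i}", "TF1") for i in range(6)] + [("TF1", "TF2")]
        r = tf_interaction_enrichment(edges, {"TF1", "TF2"}, {"p0", "p1"})
        assert r.rate_all == 1.0 and r.rate_candidates == 1.0
        assert r.fold == pytest.approx(1.0)

    def test_printed_rates_reproduce_published_fold(self):
        # 37% of candidates vs 22% of all proteins with interaction data
        edges = []
        tf = "TF0"
        candidates = {f"c{i}" for i in range(100)}
        for i in range(100):
            partner = tf if i < 37 else "x_nontf"
            edges.append((f"c{i}", partner))
        # background: 900 more proteins, 220 - 37 = 183 of them interact with the TF
        for i in range(900):
            partner = tf if i < 183 else "y_nontf"
            edges.append((f"b{i}", partner))
        r = tf_interaction_enrichment(edges, {tf}, candidates)
        assert r.rate_candidates == pytest.approx(0.37, abs=0.005)
        assert r.rate_all == pytest.approx(0.22, abs=0.005)
        assert round(r.fold, 1) == 1.7

    def test_fisher_p_matches_enumeration_oracle(self):
        edges = []
        tf = "TF"
        candidates = set()
        for i in range(20):
            candidates.add(f"c{i}")
            edges.append((f"c{i}", tf if i < 8 else "z"))
        for i in range(100):
            edges.append((f"b{i}", tf if i < 22 else "z"))
        r = tf_interaction_enrichment(edges, {tf}, candidates)
        # whatever 2x2 table results, the library p must match full enumeration
        assert r.fisher_p == pytest.approx(fisher_two_sided(*r.table), abs=1e-10)
        # and the enumeration oracle agrees with the library on a fixed table
        assert fisher_two_sided(8, 12, 22, 78) == pytest.approx(
            sps.fisher_exact([[8, 12], [22, 78]])[1], abs=1e-10
        )

    def test_fisher_implementation_agrees_with_scipy_battery(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            mine = fisher_exact_two_sided(a, b, c, d)
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_no_candidate_with_data_flagged(self):
        with pytest.warns(UserWarning):
            r = tf_interaction_enrichment([("a", "TF")], {"TF"}, {"ghost"})
        assert math.isnan(r.rate_candidates)
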