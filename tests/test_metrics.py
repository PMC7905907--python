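"""Cost metrics, efficiency index, weighted voting and the Wilcoxon test,
checked against hand arithmetic, exhaustive enumeration and scipy."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from costvote.dataio import ValidationError
from costvote.metrics import (ConfusionCounts, CostMatrix, auc_score,
                              compute_weights, confusion, efficiency_index,
                              metric_set, misclassification_cost, weighted_vote,
                              wilcoxon_signed_rank)

CM = CostMatrix()  # (10, 1)


class TestConfusion:
    def test_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_empty_inputs_error(self):
        with pytest.raises(ValidationError):
            confusion([], [])


class TestCostAndEfficiency:
    def test_mc_hand_value(self):
        c = ConfusionCounts(tp=8, tn=9, fp=1, fn=2)
        assert misclassification_cost(c, CM) == pytest.approx(1.05)

    def test_mc_zero_when_all_correct(self):
        assert misclassification_cost(ConfusionCounts(5, 5, 0, 0), CM) == 0.0

    def test_mc_linearity_in_error_swap(self):
        base = ConfusionCounts(tp=8, tn=9, fp=1, fn=2)
        swapped = ConfusionCounts(tp=8, tn=9, fp=2, fn=1)
        delta = misclassification_cost(base, CM) - misclassification_cost(swapped, CM)
        assert delta == pytest.approx((CM.cost_fn - CM.cost_fp) / base.total)

    @pytest.mark.parametrize("acc,mc,expected", [
        (1.0, 0.0, 1.0),
        (0.9, 0.55, 0.925),
        (0.0, 10.0, (0.0 + 1.0 - 10.0 / 11.0) / 2.0),
    ])
    def test_efficiency_hand_values(self, acc, mc, expected):
        assert efficiency_index(acc, mc, CM) == pytest.approx(expected)

    def test_e_monotone_in_accuracy_and_mc(self):
        for acc in np.linspace(0, 1, 7):
            es = [efficiency_index(acc, mc, CM) for mc in np.linspace(0, 5, 9)]
            assert all(a > b for a, b in zip(es, es[1:]))
        for mc in np.linspace(0, 5, 7):
            es = [efficiency_index(acc, mc, CM) for acc in np.linspace(0, 1, 9)]
            assert all(a < b for a, b in zip(es, es[1:]))


class TestWeights:
    def test_equal_efficiencies_give_uniform_weights(self):
        w = compute_weights([0.7] * 5).weights
        np.testing.assert_allclose(w, 0.2)

    def test_normalization_arithmetic(self):
        w = compute_weights([0.9, 0.8, 0.7, 0.6, 0.5]).weights
        np.testing.assert_allclose(
            w, [0.2571, 0.2286, 0.2, 0.1714, 0.1429], atol=5e-5)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            e = rng.uniform(0.01, 1.0, size=5)
            assert compute_weights(e).weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_sum_errors(self):
        with pytest.raises(ValidationError):
            compute_weights([0.0, 0.0])


class TestWeightedVote:
    def test_majority_with_equal_weights(self):
        label, score = weighted_vote([1, 1, 1, 0, 0], np.full(5, 0.2))
        assert label == 1 and score == pytest.approx(0.6)

    def test_dominant_member_wins(self):
        label, score = weighted_vote([0, 1, 1, 1, 1],
                                     np.array([0.6, 0.1, 0.1, 0.1, 0.1]))
        assert score == pytest.approx(0.4) and label == 0

    def test_exact_half_resolves_to_patient(self):
        label, _ = weighted_vote([1, 0], np.array([0.5, 0.5]))
        assert label == 1

    def test_equal_weights_equal_majority_exhaustively(self):
        w = np.full(5, 0.2)
        for pattern in itertools.product((0, 1), repeat=5):
            label, _ = weighted_vote(list(pattern), w)
            majority = 1 if sum(pattern) * 2 >= 5 else 0
            assert label == majority

    def test_dominant_weight_dictates_exhaustively(self):
        w = np.array([0.52, 0.12, 0.12, 0.12, 0.12])
        for pattern in itertools.product((0, 1), repeat=5):
            label, _ = weighted_vote(list(pattern), w)
            assert label == pattern[0]

    def test_member_count_mismatch_errors(self):
        with pytest.raises(ValidationError):
            weighted_vote([1, 0, 1], np.array([0.5, 0.5]))


class TestMetricSet:
    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=5, tn=5, fp=0, fn=0)
        y = [1] * 5 + [0] * 5
        scores = [1.0] * 5 + [0.0] * 5
        ms = metric_set(c, scores, y, CM)
        assert ms.precision == ms.recall == ms.specificity == ms.gmean == 100.0
        assert ms.auc == 100.0 and ms.mc == 0.0 and ms.e == 100.0

    def test_gmean_hand_value(self):
        # recall 80%, specificity 90% -> sqrt(0.72) = 84.85%
        c = ConfusionCounts(tp=8, tn=9, fp=1, fn=2)
        ms = metric_set(c, [0.5] * 20, [1] * 10 + [0] * 10, CM)
        assert ms.gmean == pytest.approx(84.85, abs=5e-3)

    def test_constant_scores_give_auc_50(self):
        c = ConfusionCounts(tp=1, tn=1, fp=1, fn=1)
        ms = metric_set(c, [0.3] * 4, [1, 1, 0, 0], CM)
        assert ms.auc == pytest.approx(50.0)

    def test_zero_denominator_conventions(self):
        c = ConfusionCounts(tp=0, tn=4, fp=0, fn=0)
        ms = metric_set(c, [0.1] * 4, [0, 0, 0, 0], CM)
        assert ms.precision == 0.0 and ms.recall == 0.0

    def test_exhaustive_small_tables_match_brute_force(self):
        """G-mean^2 = recall * specificity and MC equals a per-instance cost
        sum, for every confusion table with at most 12 instances."""
        for total in range(1, 13):
            for tp in range(total + 1):
                for tn in range(total - tp + 1):
                    for fp in range(total - tp - tn + 1):
                        fn = total - tp - tn - fp
                        c = ConfusionCounts(tp, tn, fp, fn)
                        y = [1] * tp + [0] * tn + [0] * fp + [1] * fn
                        p = [1] * tp + [0] * tn + [1] * fp + [0] * fn
                        ms = metric_set(c, [0.5] * total, y, CM)
                        # brute-force per-instance cost
                        cost = sum(10.0 if (yy == 1 and pp == 0) else
                                   1.0 if (yy == 0 and pp == 1) else 0.0
                                   for yy, pp in zip(y, p))
                        assert ms.mc == pytest.approx(100.0 * cost / total)
                        assert (ms.gmean / 100) ** 2 == pytest.approx(
                            (ms.recall / 100) * (ms.specificity / 100))
                        acc = (tp + tn) / total
                        assert ms.e == pytest.approx(
                            100 * (acc + 1 - (cost / total) / 11) / 2)


class TestAuc:
    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.integers(0, 2, size=30)
            y[0], y[1] = 0, 1
            s = rng.normal(size=30)
            assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_returns_half(self):
        assert auc_score([1, 1], [0.2, 0.9]) == 0.5


class TestWilcoxon:
    def test_ten_one_sided_distinct_pairs(self):
        """All-positive distinct differences at n=10: |Z| = 27.5/sqrt(96.25)
        = 2.803 and the exact two-sided p is 2/1024."""
        a = np.arange(1.0, 11.0)
        b = np.zeros(10)
        res = wilcoxon_signed_rank(a, b)
        assert res.w_plus == 55.0
        assert abs(res.z) == pytest.approx(27.5 / np.sqrt(96.25), abs=1e-9)
        assert round(abs(res.z), 3) == 2.803
        assert res.p_exact == pytest.approx(2 / 1024)
        assert round(res.p_exact, 3) == 0.002

    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == 0.0 and res.p == 1.0

    def test_swapping_samples_flips_z_keeps_p(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(b, a)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            res = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b, correction=False, method="approx")
            assert res.p_normal == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            res = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b, method="exact")
            assert res.p_exact == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_tail_close_to_normal_tail_for_m10(self):
        """For every achievable W+ at tie-free m=10 (hence every |Z| < 2),
        the exact tail probability from full enumeration agrees with the
        continuity-corrected normal tail within 0.01, and the implementation's
        exact p matches the brute-force enumeration."""
        # independent oracle: all 2^10 sign assignments of ranks 1..10
        tail = np.zeros(56)
        for mask in range(1024):
            w = sum(r for r in range(1, 11) if mask >> (r - 1) & 1)
            tail[: w + 1] += 1  # counts assignments with W+ >= index
        tail /= 1024.0
        sigma = np.sqrt(96.25)
        for w in range(56):
            z = (w - 27.5) / sigma
            if abs(z) >= 2:
                continue
            approx = sps.norm.sf((w - 0.5 - 27.5) / sigma)
            assert abs(tail[w] - approx) < 0.01
        # tie the implementation to the same enumeration at a few W+ values
        for keep in ([1, 2, 3], [1, 2, 3, 4, 5, 6, 7], list(range(1, 11))):
            d = np.array([float(i) if i in keep else -float(i)
                          for i in range(1, 11)])
            res = wilcoxon_signed_rank(d, np.zeros(10))
            w = sum(keep)
            lower = 1.0 - tail[w + 1] if w < 55 else 1.0
            expected = min(1.0, 2.0 * min(lower, tail[w]))
            assert res.p_exact == pytest.approx(expected, abs=1e-12)

    def test_zeros_dropped_by_default(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.0, 2.0, 0.0, 0.0, 0.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.n_used == 3

    def test_pratt_variant_matches_scipy(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        b = np.array([1.0, 2.0, 0.0, 0.5, 9.0, 2.0, 3.0, 1.0])
        res = wilcoxon_signed_rank(a, b, zero_method="pratt")
        ref = sps.wilcoxon(a, b, zero_method="pratt", correction=False,
                           method="approx")
        assert res.p_normal == pytest.approx(ref.pvalue, abs=1e-10)
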