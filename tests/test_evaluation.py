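import numpy as np
import pytest

from oracles import naive_pr_points, naive_trapezoid_auprc
from mirsite.evaluation import (ConfusionCounts, auprc, bootstrap_compare,
                                confusion, metrics, optimal_threshold,
                                pr_curve, threshold_grid)


class TestConfusion:
    def test_basic(self):
        cc = confusion([1, 0], [0.9, 0.1], 0.5)
        assert (cc.TP, cc.TN, cc.FP, cc.FN) == (1, 1, 0, 0)

    def test_threshold_zero_calls_everything_positive(self):
        labels = [1, 1, 0, 0, 0]
        cc = confusion(labels, [0.2, 0.8, 0.3, 0.0, 0.9], 0.0)
        assert cc.FN == 0 and cc.FP == 3

    def test_boundary_counts_positive(self):
        cc = confusion([1], [0.5], 0.5)
        assert cc.TP == 1

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=57)
        probs = rng.random(57)
        cc = confusion(labels, probs, 0.4)
        assert cc.n == 57


class TestMetrics:
    @pytest.mark.parametrize("precision,recall,f1", [
        (0.8725, 0.8703, 0.8714),
        (0.7659, 0.7818, 0.7738),
    ])
    def test_f1_worked_examples(self, precision, recall, f1):
        computed = 2 * precision * recall / (precision + recall)
        assert round(computed, 4) == f1

    def test_balanced_confusion_gives_half_accuracy(self):
        m = metrics(ConfusionCounts(TP=5, FP=5, TN=5, FN=5))
        assert m["accuracy"] == 0.5

    def test_formulas(self):
        cc = ConfusionCounts(TP=8, FP=2, TN=15, FN=5)
        m = metrics(cc)
        assert m["precision"] == 8 / 10
        assert m["recall"] == 8 / 13
        assert m["specificity"] == 15 / 17
        assert m["NPV"] == 15 / 20
        assert m["accuracy"] == 23 / 30
        assert m["F1"] == pytest.approx(
            2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"]))

    def test_empty_denominator_conventions(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=2))
        assert m["precision"] == 1.0
        m = metrics(ConfusionCounts(TP=3, FP=2, TN=0, FN=0))
        assert m["NPV"] == 1.0


class TestPRCurve:
    def test_grid_is_hundred_points_including_printed_thresholds(self):
        grid = threshold_grid()
        assert len(grid) == 100
        assert grid[0] == 1.0 and grid[-1] == 0.0
        # printed thresholds such as 0.2121 are k/99 grid members
        assert np.isclose(grid, 21 / 99).any()

    def test_perfect_scorer(self):
        labels = [1, 1, 0, 0]
        probs = [1.0, 1.0, 0.0, 0.0]
        curve = pr_curve(labels, probs)
        # every threshold above 0 calls exactly the positives
        assert np.all(curve.precision[curve.thresholds > 0] == 1.0)
        assert curve.recall[-1] == 1.0  # threshold 0 calls everything

    def test_recall_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=200)
        probs = rng.random(200)
        curve = pr_curve(labels, probs)
        # thresholds descend, so recall along the traversal is non-decreasing
        assert np.all(np.diff(curve.recall) >= 0)

    def test_matches_naive_per_threshold_recomputation(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=150)
        probs = rng.random(150)
        curve = pr_curve(labels, probs)
        points = naive_pr_points(labels, probs, curve.thresholds)
        for k, (p, r) in enumerate(points):
            assert curve.precision[k] == pytest.approx(p)
            assert curve.recall[k] == pytest.approx(r)


class TestAUPRC:
    def test_perfect_classifier(self):
        labels = [1] * 10 + [0] * 10
        probs = [0.9] * 10 + [0.1] * 10
        assert auprc(pr_curve(labels, probs)) == pytest.approx(1.0, abs=0.01)

    def test_constant_scorer_near_prevalence(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(1000) < 0.3).astype(int)
        probs = rng.random(1000)  # uninformative scores
        prevalence = labels.mean()
        assert auprc(pr_curve(labels, probs)) == pytest.approx(
            prevalence, abs=0.05)

    def test_agrees_with_independent_trapezoid(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(20, 300))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            probs = rng.random(n)
            curve = pr_curve(labels, probs)
            oracle = naive_trapezoid_auprc(
                naive_pr_points(labels, probs, curve.thresholds))
            assert auprc(curve) == pytest.approx(oracle, abs=1e-9)


class TestOptimalThreshold:
    def test_returned_threshold_is_grid_member(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=100)
        probs = rng.random(100)
        thr, _ = optimal_threshold(pr_curve(labels, probs))
        ks = thr * 99
        assert abs(ks - round(ks)) < 1e-9

    def test_unique_crossing_bracketed(self):
        # a well-separated scorer: P rises, R falls; the crossing threshold
        # on a dense grid must be within one grid step of the returned one
        rng = np.random.default_rng(6)
        labels = np.array([1] * 300 + [0] * 700)
        probs = np.concatenate([
            np.clip(rng.normal(0.7, 0.15, 300), 0, 1),
            np.clip(rng.normal(0.3, 0.15, 700), 0, 1)])
        curve = pr_curve(labels, probs)
        thr, at = optimal_threshold(curve)
        dense = np.linspace(0, 1, 991)
        gaps = []
        for t in dense:
            tp = np.sum((probs >= t) & (labels == 1))
            fp = np.sum((probs >= t) & (labels == 0))
            fn = np.sum((probs < t) & (labels == 1))
            p = tp / (tp + fp) if tp + fp else 1.0
            r = tp / (tp + fn)
            gaps.append(abs(p - r))
        crossing = dense[int(np.argmin(gaps))]
        assert abs(thr - crossing) <= 1 / 99 + 1e-9
        assert at["precision"] == pytest.approx(at["recall"], abs=0.05)

    def test_tie_breaks_to_smallest_threshold(self):
        # constant scores make P and R constant wherever calls exist; with
        # equal gap and F1 everywhere the smallest grid threshold wins
        labels = [1, 0, 1, 0]
        probs = [0.5, 0.5, 0.5, 0.5]
        curve = pr_curve(labels, probs)
        gap = np.abs(curve.precision - curve.recall)
        candidates = curve.thresholds[gap == gap.min()]
        thr, _ = optimal_threshold(curve)
        assert thr == candidates.min()


class TestBootstrap:
    def test_deterministic(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=80)
        a = rng.random(80)
        b = rng.random(80)
        r1 = bootstrap_compare(labels, a, b, iterations=50, seed=3)
        r2 = bootstrap_compare(labels, a, b, iterations=50, seed=3)
        assert r1 == r2

    def test_identical_scorers(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=60)
        probs = rng.random(60)
        res = bootstrap_compare(labels, probs, probs, iterations=100, seed=0)
        assert res.mean_diff == 0.0
        # every difference is exactly 0, so P(diff <= 0) = 1 by convention
        assert res.p_value == 1.0
        assert res.ci_a[1] > res.ci_a[0]

    def test_planted_better_classifier_is_significant(self):
        rng = np.random.default_rng(9)
        n = 1000
        labels = rng.integers(0, 2, size=n)
        strong = np.clip(labels * 0.6 + rng.normal(0.2, 0.15, n), 0, 1)
        weak = np.clip(labels * 0.2 + rng.normal(0.4, 0.25, n), 0, 1)
        res = bootstrap_compare(labels, strong, weak, iterations=1000, seed=1)
        assert res.auprc_a > res.auprc_b
        assert res.p_value <= 0.05

    def test_ci_bounds_ordered(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 2, size=70)
        a = rng.random(70)
        b = rng.random(70)
        res = bootstrap_compare(labels, a, b, iterations=100, seed=2)
        assert res.ci_a[0] <= res.auprc_a <= res.ci_a[1]
        assert res.ci_b[0] <= res.auprc_b <= res.ci_b[1]
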