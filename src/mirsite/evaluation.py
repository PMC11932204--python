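"""Classification metrics, precision-recall analysis, and bootstrap tests.

The precision-recall curve is evaluated on a fixed grid of 100 thresholds
evenly spaced over [0, 1] (step 1/99), traversed from 1 down to 0; printed
thresholds such as 0.2121 are grid members (21/99).  A sample is called
positive when its probability is >= the threshold.  AUPRC is the trapezoid
sum over the traversal,

    AUPRC = sum_i (R_{i+1} - R_i) * (P_{i+1} + P_i) / 2,

clipped to [0, 1]; for a random scorer it approaches the positive-class
prevalence.  When no positive calls are made, precision is defined as 1
(and symmetrically NPV when no negative calls) -- the standard PR-curve
convention at the top of the grid.

Model comparison uses paired bootstrap resampling of the test set (1000
iterations by default): the one-sided p-value is the proportion of
resamples in which method A's AUPRC minus method B's is <= 0, and 95%
percentile confidence intervals are reported per method.  Note that for two
identical score vectors every difference is 0, so this convention yields
p = 1, not 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_THRESHOLDS",
    "threshold_grid",
    "ConfusionCounts",
    "PRCurve",
    "BootstrapResult",
    "confusion",
    "metrics",
    "pr_curve",
    "auprc",
    "optimal_threshold",
    "bootstrap_compare",
]

N_THRESHOLDS = 100


def threshold_grid() -> np.ndarray:
    """The 100 grid thresholds from 1 down to 0 (step 1/99)."""
    return np.linspace(0.0, 1.0, N_THRESHOLDS)[::-1].copy()


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class PRCurve:
    """Per-threshold metrics on the fixed 100-point grid (descending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray


@dataclass
class BootstrapResult:
    mean_diff: float
    p_value: float
    ci_a: tuple
    ci_b: tuple
    auprc_a: float
    auprc_b: float
    iterations: int
    seed: int
    redraws: int = 0


def confusion(labels, probs, threshold: float) -> ConfusionCounts:
    """Confusion counts calling positive when prob >= threshold."""
    labels = np.asarray(labels).astype(bool)
    calls = np.asarray(probs) >= threshold
    return ConfusionCounts(
        TP=int(np.sum(calls & labels)),
        FP=int(np.sum(calls & ~labels)),
        TN=int(np.sum(~calls & ~labels)),
        FN=int(np.sum(~calls & labels)),
    )


def _ratio(num: int, den: int, empty: float) -> float:
    return num / den if den else empty


def metrics(cc: ConfusionCounts) -> dict:
    """Precision, recall, F1, accuracy, specificity, and NPV."""
    precision = _ratio(cc.TP, cc.TP + cc.FP, 1.0)
    recall = _ratio(cc.TP, cc.TP + cc.FN, 1.0)
    specificity = _ratio(cc.TN, cc.TN + cc.FP, 1.0)
    npv = _ratio(cc.TN, cc.TN + cc.FN, 1.0)
    accuracy = _ratio(cc.TP + cc.TN, cc.n, 1.0)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "F1": f1,
            "accuracy": accuracy, "specificity": specificity, "NPV": npv}


def pr_curve(labels, probs) -> PRCurve:
    """Precision/recall/specificity at each of the 100 grid thresholds."""
    labels = np.asarray(labels).astype(bool)
    probs = np.asarray(probs, dtype=float)
    thr = threshold_grid()
    calls = probs[None, :] >= thr[:, None]            # (100, n)
    tp = (calls & labels[None, :]).sum(axis=1)
    fp = (calls & ~labels[None, :]).sum(axis=1)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    pred_pos = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), 1.0)
        recall = tp / n_pos if n_pos else np.ones_like(tp, dtype=float)
        specificity = ((n_neg - fp) / n_neg if n_neg
                       else np.ones_like(fp, dtype=float))
    return PRCurve(thresholds=thr, precision=precision.astype(float),
                   recall=np.asarray(recall, dtype=float),
                   specificity=np.asarray(specificity, dtype=float))


def auprc(curve: PRCurve) -> float:
    """Trapezoid area over the threshold traversal, clipped to [0, 1]."""
    P, R = curve.precision, curve.recall
    area = float(np.sum((R[1:] - R[:-1]) * (P[1:] + P[:-1]) / 2.0))
    return min(max(area, 0.0), 1.0)


def optimal_threshold(curve: PRCurve):
    """Grid threshold where precision and recall intersect.

    Minimizes |P - R|; ties break toward the larger F1, then the smaller
    threshold.  Returns ``(threshold, metrics_at_threshold)``.
    """
    P, R, T = curve.precision, curve.recall, curve.thresholds
    gap = np.abs(P - R)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(P + R > 0, 2 * P * R / np.maximum(P + R, 1e-300), 0.0)
    best = None
    for i in range(len(T)):
        key = (gap[i], -f1[i], T[i])
        if best is None or key < best[0]:
            best = (key, i)
    i = best[1]
    return float(T[i]), {
        "precision": float(P[i]), "recall": float(R[i]),
        "specificity": float(curve.specificity[i]), "F1": float(f1[i]),
    }


def bootstrap_compare(labels, probs_a, probs_b, iterations: int = 1000,
                      seed: int = 0) -> BootstrapResult:
    """Paired bootstrap comparison of two scorers on one test set.

    Resamples the test set with replacement at full size; single-class
    resamples are redrawn (counted in ``redraws``).  Reports the mean AUPRC
    difference (A - B), the one-sided p-value P(diff <= 0), and 95%
    percentile CIs for each method.
    """
    labels = np.asarray(labels).astype(bool)
    probs_a = np.asarray(probs_a, dtype=float)
    probs_b = np.asarray(probs_b, dtype=float)
    n = len(labels)
    rng = np.random.default_rng(seed)
    a_scores = np.empty(iterations)
    b_scores = np.empty(iterations)
    redraws = 0
    for it in range(iterations):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
            redraws += 1
        a_scores[it] = auprc(pr_curve(lab, probs_a[idx]))
        b_scores[it] = auprc(pr_curve(lab, probs_b[idx]))
    diffs = a_scores - b_scores
    return BootstrapResult(
        mean_diff=float(diffs.mean()),
        p_value=float(np.mean(diffs <= 0.0)),
        ci_a=(float(np.percentile(a_scores, 2.5)),
              float(np.percentile(a_scores, 97.5))),
        ci_b=(float(np.percentile(b_scores, 2.5)),
              float(np.percentile(b_scores, 97.5))),
        auprc_a=float(auprc(pr_curve(labels, probs_a))),
        auprc_b=float(auprc(pr_curve(labels, probs_b))),
        iterations=iterations, seed=seed, redraws=redraws,
    )
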