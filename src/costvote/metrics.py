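"""Cost structure, efficiency index, weighted voting and evaluation metrics.

The cost matrix charges ``cost_fn`` (default 10) for missing a patient and
``cost_fp`` (default 1) for mislabeling a healthy person; correct decisions
cost 0.  Misclassification cost (MC) is the average per-instance penalty:

    MC = (FP * cost_fp + FN * cost_fn) / (TP + TN + FP + FN)

The efficiency index combines accuracy and cost on a [0, 1] scale,

    E = (accuracy + 1 - MC / (cost_fn + cost_fp)) / 2,

and member weights in the ensemble vote are the normalized efficiencies
w_i = E_i / sum(E_j).  The module also provides the reported metric family
(E, MC, G-mean, precision, recall, specificity, AUC — percent scale) and a
self-contained Wilcoxon signed-rank test with exact small-sample p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .dataio import ValidationError

__all__ = [
    "CostMatrix",
    "ConfusionCounts",
    "MetricSet",
    "EnsembleWeights",
    "WilcoxonResult",
    "confusion",
    "misclassification_cost",
    "efficiency_index",
    "compute_weights",
    "weighted_vote",
    "auc_score",
    "metric_set",
    "wilcoxon_signed_rank",
    "METRIC_NAMES",
]

METRIC_NAMES = ("E", "MC", "G-mean", "Precision", "Recall", "Specificity", "AUC")


@dataclass(frozen=True)
class CostMatrix:
    """Asymmetric misclassification costs; correct classification costs 0."""

    cost_fn: float = 10.0  # missing a patient
    cost_fp: float = 1.0   # mislabeling a healthy person

    def __post_init__(self) -> None:
        if self.cost_fn < 0 or self.cost_fp < 0:
            raise ValidationError("costs must be non-negative")
        if self.cost_fn + self.cost_fp == 0:
            raise ValidationError("cost_fn + cost_fp must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class MetricSet:
    """The seven reported metrics, on the percent scale."""

    e: float
    mc: float
    gmean: float
    precision: float
    recall: float
    specificity: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "E": self.e, "MC": self.mc, "G-mean": self.gmean,
            "Precision": self.precision, "Recall": self.recall,
            "Specificity": self.specificity, "AUC": self.auc,
        }


@dataclass(frozen=True)
class EnsembleWeights:
    efficiencies: np.ndarray
    weights: np.ndarray
    cost_matrix: CostMatrix
    source: str = "validation"


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p_exact: float | None
    p_normal: float
    p: float          # exact when available, else normal
    w_plus: float
    n_used: int       # pairs remaining after zero differences are dropped


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValidationError("empty label vectors")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{name} must contain only 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def misclassification_cost(c: ConfusionCounts, cm: CostMatrix = CostMatrix()) -> float:
    """Average per-instance penalty, as a fraction (multiply by 100 for the
    reported percent form; it may exceed 1 when cost_fn > 1)."""
    if c.total == 0:
        raise ValidationError("confusion total must be positive")
    return (c.fp * cm.cost_fp + c.fn * cm.cost_fn) / c.total


def efficiency_index(accuracy: float, mc: float, cm: CostMatrix = CostMatrix()) -> float:
    """E = (accuracy + 1 - MC/(cost_fn + cost_fp)) / 2, on [0, 1].

    ``mc`` is the per-instance cost fraction (not the percent form).
    """
    if not (0.0 <= accuracy <= 1.0):
        raise ValidationError("accuracy must be in [0, 1]")
    if mc < 0:
        raise ValidationError("MC must be non-negative")
    return (accuracy + 1.0 - mc / (cm.cost_fn + cm.cost_fp)) / 2.0


def compute_weights(e_values, cm: CostMatrix = CostMatrix(),
                    source: str = "validation") -> EnsembleWeights:
    """Normalize member efficiencies into voting weights w_i = E_i / sum E."""
    e = np.asarray(e_values, dtype=float)
    if (e < 0).any():
        raise ValidationError("efficiencies must be non-negative")
    s = e.sum()
    if s <= 0:
        raise ValidationError("sum of efficiencies must be positive")
    return EnsembleWeights(efficiencies=e, weights=e / s, cost_matrix=cm, source=source)


def weighted_vote(member_labels, weights: EnsembleWeights | np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted majority vote over member label predictions.

    ``member_labels`` has shape (n_members,) or (n_members, n_samples).
    Returns (labels, positive_score) where positive_score is the total weight
    voting 1; a score of exactly 0.5 resolves to the patient label (the costly
    error is the missed patient).
    """
    w = weights.weights if isinstance(weights, EnsembleWeights) else np.asarray(weights)
    arr = np.asarray(member_labels, dtype=float)
    single = arr.ndim == 1
    labels = arr[:, None] if single else arr
    if labels.shape[0] != len(w):
        raise ValidationError("one weight per member is required")
    score = w @ labels
    pred = (score >= 0.5).astype(int)
    if single:
        return int(pred[0]), float(score[0])
    return pred, score


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic with midrank
    tie handling, as a fraction.  Returns 0.5 if a class is absent."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)
    r_pos = ranks[y_true == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def metric_set(c: ConfusionCounts, scores, y_true,
               cm: CostMatrix = CostMatrix()) -> MetricSet:
    """The seven reported metrics on the percent scale.

    Zero-denominator precision/recall/specificity are defined as 0.
    """
    if c.total == 0:
        raise ValidationError("confusion total must be positive")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    gmean = float(np.sqrt(recall * specificity))
    mc = misclassification_cost(c, cm)
    e = efficiency_index(c.accuracy, mc, cm)
    auc = auc_score(y_true, scores)
    return MetricSet(
        e=float(100.0 * e), mc=float(100.0 * mc), gmean=float(100.0 * gmean),
        precision=float(100.0 * precision), recall=float(100.0 * recall),
        specificity=float(100.0 * specificity), auc=float(100.0 * auc),
    )


def _exact_two_sided_p(two_ranks: np.ndarray, w_plus_double: int) -> float:
    """Exact two-sided tail of W+ by dynamic programming over all 2^m sign
    assignments.  Ranks arrive doubled so midranks stay integral."""
    total = int(two_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in two_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    n_assign = counts.sum()
    w = int(w_plus_double)
    lower = counts[: w + 1].sum() / n_assign         # P(W+ <= w)
    upper = counts[w:].sum() / n_assign              # P(W+ >= w)
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(a, b, zero_method: str = "drop",
                         exact_limit: int = 25) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Differences of zero are dropped (classical convention; ``zero_method=
    "pratt"`` keeps them in the ranking but excludes them from W+).  Absolute
    differences receive midranks.  The standardized statistic is

        Z = (W+ - m(m+1)/4) / sqrt(m(m+1)(2m+1)/24 - sum(t^3 - t)/48)

    without continuity correction; the tie term vanishes for tie-free data.
    The exact two-sided p-value enumerates all 2^m sign assignments (dynamic
    programming) for m <= ``exact_limit``; the normal approximation is always
    reported alongside.  All differences zero yields the degenerate result
    Z = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired samples of equal length >= 2 required")
    if zero_method not in ("drop", "pratt"):
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    d = a - b
    if zero_method == "drop":
        d = d[d != 0]
    if len(d) == 0 or (d == 0).all():
        return WilcoxonResult(z=0.0, p_exact=1.0, p_normal=1.0, p=1.0,
                              w_plus=0.0, n_used=0)
    ranks = rankdata(np.abs(d))
    nonzero = d != 0
    m = int(nonzero.sum())
    n_all = len(d)
    n_zero = n_all - m
    w_plus = float(ranks[d > 0].sum())
    _, t = np.unique(ranks[nonzero], return_counts=True)
    tie_term = float((t.astype(float) ** 3 - t).sum()) / 48.0
    if zero_method == "pratt":
        # zeros occupy the lowest ranks; subtract their mass from mean/variance
        mu = (n_all * (n_all + 1) - n_zero * (n_zero + 1)) / 4.0
        var = (n_all * (n_all + 1) * (2 * n_all + 1)
               - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0 - tie_term
    else:
        mu = m * (m + 1) / 4.0
        # midrank tie correction; equals the closed form when ties are absent
        var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(z=0.0, p_exact=1.0, p_normal=1.0, p=1.0,
                              w_plus=w_plus, n_used=m)
    z = (w_plus - mu) / np.sqrt(var)
    p_normal = float(2.0 * norm.sf(abs(z)))
    p_exact = None
    if zero_method == "drop" and m <= exact_limit:
        two_ranks = np.rint(2 * ranks).astype(int)
        p_exact = _exact_two_sided_p(two_ranks, int(round(2 * w_plus)))
    p = p_exact if p_exact is not None else p_normal
    return WilcoxonResult(z=float(z), p_exact=p_exact, p_normal=p_normal,
                          p=float(p), w_plus=w_plus, n_used=m)
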