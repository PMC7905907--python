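"""Relief feature weighting for mixed continuous/categorical tables.

Relief scores a feature by contrasting how much it separates each instance
from its nearest neighbor of the same class (near-hit) versus its nearest
neighbor of the opposite class (near-miss).  A feature whose values track the
class boundary differs little from hits and much from misses, accumulating a
positive weight; an irrelevant feature drifts toward zero.

Per-feature differences use the classical two-class diff: 0/1 equality for
categorical features, absolute difference for continuous features (which are
assumed already z-normalized so units are comparable).  The instance distance
driving the hit/miss search is the sum of these diffs (Manhattan over diff
values).  The weight update uses squared diffs by default — the original
formulation — with a linear variant available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataio import CATEGORICAL, CONTINUOUS, Dataset, FeatureSpec, ValidationError

__all__ = [
    "ReliefConfig",
    "ReliefResult",
    "diff",
    "nearest_hit_miss",
    "relief_weights",
    "top_k",
    "ReliefSelector",
]


@dataclass(frozen=True)
class ReliefConfig:
    """Sampling plan: ``n_samples`` instances per pass ("all" = one full
    deterministic pass in index order), ``n_repeats`` averaged passes."""

    n_samples: int | str = "all"
    n_repeats: int = 1
    seed: int = 0
    squared: bool = True

    def __post_init__(self) -> None:
        if self.n_samples != "all" and (not isinstance(self.n_samples, int)
                                        or self.n_samples < 1):
            raise ValidationError('n_samples must be a positive int or "all"')
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ReliefResult:
    weights: np.ndarray
    ranking: tuple[str, ...]
    feature_names: tuple[str, ...]
    config: ReliefConfig


def diff(spec: FeatureSpec, a: float, b: float) -> float:
    """Per-feature difference: categorical 0/1 equality, continuous |a - b|."""
    if np.isnan(a) or np.isnan(b):
        raise ValidationError("diff on missing values; impute before Relief")
    if spec.kind == CATEGORICAL:
        return 0.0 if a == b else 1.0
    return abs(a - b)


def _kind_masks(kinds) -> tuple[np.ndarray, np.ndarray]:
    kinds = np.asarray(kinds)
    cont = kinds == CONTINUOUS
    cat = kinds == CATEGORICAL
    if not (cont | cat).all():
        raise ValidationError("feature kinds must be continuous/categorical")
    return cont, cat


def _pairwise_diff_distance(X: np.ndarray, kinds) -> np.ndarray:
    """n x n matrix of summed per-feature diffs."""
    cont, cat = _kind_masks(kinds)
    n = X.shape[0]
    D = np.zeros((n, n))
    if cont.any():
        Xc = X[:, cont]
        D += np.abs(Xc[:, None, :] - Xc[None, :, :]).sum(axis=2)
    if cat.any():
        Xk = X[:, cat]
        D += (Xk[:, None, :] != Xk[None, :, :]).sum(axis=2)
    return D


def _hit_miss_from_matrix(i: int, D: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    row = D[i].copy()
    same = y == y[i]
    row_hit = np.where(same, row, np.inf)
    row_hit[i] = np.inf
    row_miss = np.where(~same, row, np.inf)
    if not np.isfinite(row_hit).any() or not np.isfinite(row_miss).any():
        raise ValidationError("each class needs >= 2 instances for hit/miss search")
    # np.argmin returns the first minimum -> ties break to the smallest index
    return int(np.argmin(row_hit)), int(np.argmin(row_miss))


def nearest_hit_miss(index: int, dataset: Dataset) -> tuple[int, int]:
    """Nearest same-class (excluding self) and other-class instance indices,
    ties broken toward the smaller index."""
    if dataset.missing_mask.to_numpy().any():
        raise ValidationError("Relief requires a fully imputed dataset")
    D = _pairwise_diff_distance(dataset.X, dataset.schema.kinds)
    return _hit_miss_from_matrix(index, D, dataset.labels)


def _require_two_per_class(y: np.ndarray) -> None:
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValidationError(
                f"class {cls} has fewer than 2 instances; hit/miss search "
                "is undefined")


def _feature_diffs(X: np.ndarray, i: int, j: int, cont: np.ndarray,
                   cat: np.ndarray) -> np.ndarray:
    d = np.empty(X.shape[1])
    d[cont] = np.abs(X[i, cont] - X[j, cont])
    d[cat] = (X[i, cat] != X[j, cat]).astype(float)
    return d


def relief_weights_array(X: np.ndarray, y: np.ndarray, kinds,
                         config: ReliefConfig = ReliefConfig()) -> np.ndarray:
    """Relief weight vector on plain arrays (one weight per column)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValidationError("Relief requires a fully imputed dataset")
    _require_two_per_class(y)
    n = X.shape[0]
    cont, cat = _kind_masks(kinds)
    D = _pairwise_diff_distance(X, kinds)
    rng = np.random.default_rng(config.seed)
    power = 2 if config.squared else 1
    total = np.zeros(X.shape[1])
    for _ in range(config.n_repeats):
        if config.n_samples == "all":
            sample = np.arange(n)
        else:
            sample = rng.integers(0, n, size=config.n_samples)
        m = len(sample)
        W = np.zeros(X.shape[1])
        for i in sample:
            hit, miss = _hit_miss_from_matrix(int(i), D, y)
            dh = _feature_diffs(X, int(i), hit, cont, cat)
            dm = _feature_diffs(X, int(i), miss, cont, cat)
            W += (dm ** power - dh ** power) / m
        total += W
    return total / config.n_repeats


def relief_weights(dataset: Dataset, config: ReliefConfig = ReliefConfig()
                   ) -> ReliefResult:
    """Relief weights and the induced descending ranking (weight ties broken
    by schema order)."""
    W = relief_weights_array(dataset.X, dataset.labels, dataset.schema.kinds, config)
    names = dataset.schema.names
    order = sorted(range(len(names)), key=lambda j: (-W[j], j))
    return ReliefResult(weights=W, ranking=tuple(names[j] for j in order),
                        feature_names=names, config=config)


def top_k(result: ReliefResult, k: int) -> tuple[str, ...]:
    """First ``k`` names of the ranking."""
    if not (1 <= k <= len(result.ranking)):
        raise ValidationError(f"k={k} out of range 1..{len(result.ranking)}")
    return result.ranking[:k]


class ReliefSelector(SelectorMixin, BaseEstimator):
    """sklearn-style feature selector keeping the ``k`` top Relief features.

    Parameters
    ----------
    k : int or None
        Number of features to keep; None keeps all (ranking still computed).
    kinds : sequence of {"continuous", "categorical"} or None
        Per-column feature kind; None treats every column as continuous.
    n_samples, n_repeats, random_state, squared
        Relief sampling plan (see :class:`ReliefConfig`).
    """

    def __init__(self, k: int | None = None, kinds=None,
                 n_samples: int | str = "all", n_repeats: int = 1,
                 random_state: int = 0, squared: bool = True) -> None:
        self.k = k
        self.kinds = kinds
        self.n_samples = n_samples
        self.n_repeats = n_repeats
        self.random_state = random_state
        self.squared = squared

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        kinds = (tuple(self.kinds) if self.kinds is not None
                 else (CONTINUOUS,) * X.shape[1])
        if len(kinds) != X.shape[1]:
            raise ValidationError("kinds length must match feature count")
        cfg = ReliefConfig(n_samples=self.n_samples, n_repeats=self.n_repeats,
                           seed=self.random_state, squared=self.squared)
        self.weights_ = relief_weights_array(X, y, kinds, cfg)
        order = sorted(range(X.shape[1]), key=lambda j: (-self.weights_[j], j))
        self.ranking_ = np.array(order)
        k = X.shape[1] if self.k is None else self.k
        if not (1 <= k <= X.shape[1]):
            raise ValidationError(f"k={k} out of range 1..{X.shape[1]}")
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.ranking_[:k]] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
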