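"""Cost-sensitive weighted-vote ensemble of the five heterogeneous members.

Each trained member i is scored by its efficiency index E_i on a reference
split (training data at ``fit`` time; any held-out set via ``reweight``), and
votes with weight w_i = E_i / sum(E).  The ensemble label is the weighted
majority, with the 0.5 tie resolved to the patient class — the expensive
mistake is the missed patient.  The ensemble's ranking score for AUC is the
positive weighted vote share.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataio import ValidationError
from .learners import MEMBER_NAMES, MemberSpec, make_member, positive_scores
from .metrics import (CostMatrix, compute_weights, confusion, efficiency_index,
                      misclassification_cost, weighted_vote)

__all__ = ["CostSensitiveVotingEnsemble", "member_efficiency"]


def member_efficiency(member, X, y, cost_matrix: CostMatrix) -> float:
    """Efficiency index E of a fitted member on (X, y)."""
    c = confusion(y, member.predict(X))
    return efficiency_index(c.accuracy, misclassification_cost(c, cost_matrix),
                            cost_matrix)


def default_member_specs(seed: int = 0) -> tuple[MemberSpec, ...]:
    return tuple(MemberSpec(name=n, seed=seed + i)
                 for i, n in enumerate(MEMBER_NAMES))


class CostSensitiveVotingEnsemble(ClassifierMixin, BaseEstimator):
    """E-weighted voting over heterogeneous members.

    Parameters
    ----------
    members : sequence of (name, estimator) pairs or None
        Untrained members; None builds the default five (rf, lr, svm, elm,
        knn) seeded from ``random_state``.
    cost_fn, cost_fp : float
        Misclassification costs (missed patient / mislabeled healthy).
    random_state : int
        Seed for the default members.

    Attributes
    ----------
    members_ : list of (name, fitted estimator)
    efficiencies_, weights_ : per-member E_i and normalized w_i
    weight_source_ : which data last set the weights ("train" after fit,
        "validation" after :meth:`reweight`)
    """

    def __init__(self, members=None, cost_fn: float = 10.0, cost_fp: float = 1.0,
                 random_state: int = 0) -> None:
        self.members = members
        self.cost_fn = cost_fn
        self.cost_fp = cost_fp
        self.random_state = random_state

    @property
    def cost_matrix_(self) -> CostMatrix:
        return CostMatrix(cost_fn=self.cost_fn, cost_fp=self.cost_fp)

    def _build_members(self):
        if self.members is not None:
            return [(name, clone(est)) for name, est in self.members]
        return [(s.name, make_member(s)) for s in default_member_specs(self.random_state)]

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.array([0, 1])
        self.members_ = []
        for name, est in self._build_members():
            est.fit(X, y)
            self.members_.append((name, est))
        self._set_weights(X, y, source="train")
        return self

    def _set_weights(self, X, y, source: str) -> None:
        cm = self.cost_matrix_
        e = np.array([member_efficiency(est, X, y, cm) for _, est in self.members_])
        w = compute_weights(e, cm, source=source)
        self.efficiencies_ = w.efficiencies
        self.weights_ = w.weights
        self.weight_source_ = source

    def reweight(self, X, y, source: str = "validation"):
        """Recompute the vote weights from a held-out split."""
        check_is_fitted(self, "members_")
        X = validate_data(self, X, reset=False)
        self._set_weights(X, np.asarray(y, dtype=int), source=source)
        return self

    def member_predictions(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = validate_data(self, X, reset=False)
        return np.vstack([np.asarray(est.predict(X), dtype=int)
                          for _, est in self.members_])

    def member_scores(self, X) -> dict[str, np.ndarray]:
        check_is_fitted(self, "members_")
        X = validate_data(self, X, reset=False)
        return {name: positive_scores(est, X) for name, est in self.members_}

    def decision_function(self, X) -> np.ndarray:
        labels = self.member_predictions(X)
        _, score = weighted_vote(labels, self.weights_)
        return np.atleast_1d(score)

    def predict(self, X) -> np.ndarray:
        labels = self.member_predictions(X)
        pred, _ = weighted_vote(labels, self.weights_)
        return np.atleast_1d(pred)
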