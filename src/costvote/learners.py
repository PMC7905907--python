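"""The five ensemble members behind one fit/predict/score contract.

Random forest, logistic regression and RBF-kernel SVM are delegated to
scikit-learn with the documented defaults (50 trees; unregularized LR with a
0.5 threshold; Gaussian kernel, C = 1).  The extreme learning machine and the
heterogeneous-distance k-nearest-neighbor classifier are implemented here.

Every member exposes labels in {0, 1} (1 = patient) and a real "patient-like"
score for AUC: vote fraction (RF), sigmoid output (LR), decision-function
value (SVM), hidden-layer output H @ beta (ELM), positive-neighbor fraction
(KNN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataio import CATEGORICAL, CONTINUOUS, Dataset, DatasetSchema, ValidationError

__all__ = [
    "MEMBER_NAMES",
    "MemberSpec",
    "ElmModel",
    "KnnDistanceSpec",
    "ELMClassifier",
    "HeterogeneousKNNClassifier",
    "make_member",
    "positive_scores",
    "elm_fit",
    "elm_predict",
    "hetero_distance",
    "knn_predict",
]

MEMBER_NAMES = ("rf", "lr", "svm", "elm", "knn")


@dataclass(frozen=True)
class MemberSpec:
    """A named member and its hyperparameter overrides."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MEMBER_NAMES:
            raise ValidationError(f"unknown member {self.name!r}; expected one of "
                                  f"{MEMBER_NAMES}")

    def to_dict(self) -> dict:
        return {"name": self.name, "hyperparams": dict(self.hyperparams),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "MemberSpec":
        return cls(name=d["name"], hyperparams=dict(d.get("hyperparams", {})),
                   seed=int(d.get("seed", 0)))


# --------------------------------------------------------------------------
# Extreme learning machine
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElmModel:
    input_weights: np.ndarray   # features x hidden
    biases: np.ndarray          # hidden
    beta: np.ndarray            # hidden
    activation: str = "sigmoid"
    seed: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _hidden_matrix(X: np.ndarray, model_w: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _sigmoid(X @ model_w + b)


def elm_fit(X, y, hidden: int = 50, seed: int = 0, ridge: float = 0.0) -> ElmModel:
    """Train a single-hidden-layer network whose hidden weights stay random.

    Input weights and biases are drawn uniformly on [-1, 1] from ``seed``; the
    output weights solve the least-squares problem H beta = t in closed form
    via the Moore-Penrose pseudo-inverse (targets t in {-1, +1}), optionally
    ridge-stabilized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("X must be a non-empty 2-D array")
    if hidden < 1:
        raise ValidationError("hidden must be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], hidden))
    b = rng.uniform(-1.0, 1.0, size=hidden)
    H = _hidden_matrix(X, W, b)
    t = np.where(y == 1, 1.0, -1.0)
    if ridge > 0:
        beta = np.linalg.solve(H.T @ H + ridge * np.eye(hidden), H.T @ t)
    else:
        beta = np.linalg.pinv(H) @ t
    return ElmModel(input_weights=W, biases=b, beta=beta, seed=seed)


def elm_predict(model: ElmModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and real scores; a score of exactly 0 maps to the patient label."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    if X.shape[1] != model.input_weights.shape[0]:
        raise ValidationError("feature arity does not match the trained model")
    score = _hidden_matrix(X, model.input_weights, model.biases) @ model.beta
    return (score >= 0).astype(int), score


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper around the closed-form ELM.

    Parameters
    ----------
    n_hidden : int, default 50
        Hidden-layer width; at n_hidden >= n_samples the network interpolates
        the training labels.
    ridge : float, default 0.0
        Optional Tikhonov term on the output-weight solve.
    random_state : int, default 0
        Seed for the random hidden weights (the model is fully reproducible
        from seed and shape).
    """

    def __init__(self, n_hidden: int = 50, ridge: float = 0.0,
                 random_state: int = 0) -> None:
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.array([0, 1])
        self.model_ = elm_fit(X, y, hidden=self.n_hidden, seed=self.random_state,
                              ridge=self.ridge)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        return elm_predict(self.model_, X)[1]

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        return elm_predict(self.model_, X)[0]


# --------------------------------------------------------------------------
# Heterogeneous-distance KNN
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KnnDistanceSpec:
    """Mixed-type distance d(a, b) = sum_q w_q (a_q - b_q)^2
    + sum_c w_c L_c(a_c, b_c) — squared terms, no square root.

    ``penalties`` maps a categorical feature name to (categories, matrix)
    with a symmetric non-negative zero-diagonal matrix; the default penalty
    is 0 on the diagonal and 1 off it.
    """

    w_q: dict = field(default_factory=dict)   # name -> weight, default 1
    w_c: dict = field(default_factory=dict)
    penalties: dict = field(default_factory=dict)
    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        for name, (cats, L) in self.penalties.items():
            L = np.asarray(L, dtype=float)
            if L.shape != (len(cats), len(cats)):
                raise ValidationError(f"penalty matrix shape mismatch for {name!r}")
            if not np.allclose(L, L.T) or (np.diag(L) != 0).any() or (L < 0).any():
                raise ValidationError(
                    f"penalty matrix for {name!r} must be symmetric, non-negative, "
                    "zero-diagonal")


def _categorical_penalty(spec: KnnDistanceSpec, name: str,
                         a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if name in spec.penalties:
        cats, L = spec.penalties[name]
        L = np.asarray(L, dtype=float)
        cats = [float(c) for c in cats]
        ia = np.array([cats.index(float(v)) for v in np.atleast_1d(a)])
        ib = np.array([cats.index(float(v)) for v in np.atleast_1d(b)])
        return L[ia, ib]
    return (np.atleast_1d(a) != np.atleast_1d(b)).astype(float)


def hetero_distance(a, b, spec: KnnDistanceSpec, schema: DatasetSchema) -> float:
    """Distance between two instances laid out per ``schema``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("hetero_distance requires fully observed instances")
    d = 0.0
    for j, fs in enumerate(schema.features):
        if fs.kind == CONTINUOUS:
            d += spec.w_q.get(fs.name, 1.0) * (a[j] - b[j]) ** 2
        else:
            d += spec.w_c.get(fs.name, 1.0) * float(
                _categorical_penalty(spec, fs.name, a[j:j + 1], b[j:j + 1])[0])
    return float(d)


def _distance_matrix(query: np.ndarray, train: np.ndarray, kinds,
                     names, spec: KnnDistanceSpec) -> np.ndarray:
    nq, nt = query.shape[0], train.shape[0]
    D = np.zeros((nq, nt))
    for j, (kind, name) in enumerate(zip(kinds, names)):
        qa = query[:, j][:, None]
        tb = train[:, j][None, :]
        if kind == CONTINUOUS:
            D += spec.w_q.get(name, 1.0) * (qa - tb) ** 2
        elif name in spec.penalties:
            cats, L = spec.penalties[name]
            L = np.asarray(L, dtype=float)
            lut = {float(c): i for i, c in enumerate(cats)}
            ia = np.vectorize(lut.__getitem__)(query[:, j])
            ib = np.vectorize(lut.__getitem__)(train[:, j])
            D += spec.w_c.get(name, 1.0) * L[ia[:, None], ib[None, :]]
        else:
            D += spec.w_c.get(name, 1.0) * (qa != tb).astype(float)
    return D


def knn_predict(train: Dataset, query_rows, spec: KnnDistanceSpec = KnnDistanceSpec()
                ) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote among the k nearest training instances.

    Distance ties resolve toward the smaller training index; a split vote
    resolves to the patient label.  The score is the positive-neighbor
    fraction.
    """
    if spec.k > train.n_instances:
        raise ValidationError("k exceeds the training-set size")
    query = np.asarray(query_rows, dtype=float)
    if query.ndim == 1:
        query = query[None, :]
    D = _distance_matrix(query, train.X, train.schema.kinds, train.schema.names, spec)
    # stable sort keeps original (= smaller-index) order among equal distances
    order = np.argsort(D, axis=1, kind="stable")[:, :spec.k]
    votes = train.labels[order]
    score = votes.mean(axis=1)
    labels = (2 * votes.sum(axis=1) >= spec.k).astype(int)
    return labels, score


class HeterogeneousKNNClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style KNN under the mixed-type squared/penalty distance.

    ``kinds`` gives the per-column feature kind (default: all continuous);
    ``w_q``/``w_c``/``penalties`` follow :class:`KnnDistanceSpec` but are
    keyed by column index when fitting plain arrays.
    """

    def __init__(self, k: int = 5, kinds=None, w_q=None, w_c=None,
                 penalties=None) -> None:
        self.k = k
        self.kinds = kinds
        self.w_q = w_q
        self.w_c = w_c
        self.penalties = penalties

    def _spec_and_names(self, n_features: int) -> tuple[KnnDistanceSpec, tuple]:
        names = tuple(str(j) for j in range(n_features))
        spec = KnnDistanceSpec(
            w_q={str(k): v for k, v in (self.w_q or {}).items()},
            w_c={str(k): v for k, v in (self.w_c or {}).items()},
            penalties={str(k): v for k, v in (self.penalties or {}).items()},
            k=self.k,
        )
        return spec, names

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.k > len(y):
            raise ValidationError("k exceeds the training-set size")
        self.classes_ = np.array([0, 1])
        self.X_ = X
        self.y_ = np.asarray(y, dtype=int)
        self.kinds_ = (tuple(self.kinds) if self.kinds is not None
                       else (CONTINUOUS,) * X.shape[1])
        return self

    def _scores(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        X = validate_data(self, X, reset=False)
        spec, names = self._spec_and_names(self.X_.shape[1])
        D = _distance_matrix(X, self.X_, self.kinds_, names, spec)
        order = np.argsort(D, axis=1, kind="stable")[:, :self.k]
        return self.y_[order].mean(axis=1)

    def decision_function(self, X):
        return self._scores(X)

    def predict(self, X):
        score = self._scores(X)
        return (score >= 0.5).astype(int)


# --------------------------------------------------------------------------
# Member factory
# --------------------------------------------------------------------------

def make_member(spec: MemberSpec) -> BaseEstimator:
    """Instantiate an untrained member with the documented defaults.

    rf: 50-tree random forest; lr: unregularized logistic regression with the
    0.5 threshold; svm: RBF kernel, C = 1; elm: 50 hidden units; knn: k = 5
    under the heterogeneous distance.  ``spec.hyperparams`` overrides any
    constructor argument.
    """
    hp = dict(spec.hyperparams)
    if spec.name == "rf":
        hp.setdefault("n_estimators", 50)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.name == "lr":
        # plain (unregularized) logistic regression with the 0.5 threshold
        hp.setdefault("C", np.inf)
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(**hp)
    if spec.name == "svm":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("C", 1.0)
        hp.setdefault("gamma", "scale")
        return SVC(random_state=spec.seed, **hp)
    if spec.name == "elm":
        hp.setdefault("n_hidden", 50)
        return ELMClassifier(random_state=spec.seed, **hp)
    if spec.name == "knn":
        hp.setdefault("k", 5)
        return HeterogeneousKNNClassifier(**hp)
    raise ValidationError(f"unknown member {spec.name!r}")


def positive_scores(member: BaseEstimator, X) -> np.ndarray:
    """A real 'patient-like' score for AUC, per member type."""
    if hasattr(member, "predict_proba"):
        proba = member.predict_proba(X)
        if 1 in member.classes_:
            pos = int(np.flatnonzero(member.classes_ == 1)[0])
            return np.asarray(proba[:, pos], dtype=float)
        return np.zeros(len(proba))
    return np.asarray(member.decision_function(X), dtype=float)
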