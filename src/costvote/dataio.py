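"""Schemas, dataset container and I/O for mixed-type clinical tables.

The native container couples a pandas table of feature values (floats; missing
cells are NaN) with an explicit boolean missing mask and a binary label vector
(1 = patient, 0 = healthy).  Three on-disk dialects are supported:

``native``
    Comma-separated with a header row; missing cells are empty or ``NA``.
``statlog``
    Whitespace-separated, no header, labels {1, 2} (2 = patient), no missing
    values — the UCI Statlog ``heart.dat`` layout.
``cleveland``
    Comma-separated, no header, ``?`` marks missing, labels 0–4 with any
    positive severity meaning "patient" — the UCI ``processed.*.data`` layout
    shared by the Cleveland and Hungarian tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

__all__ = [
    "CONTINUOUS",
    "CATEGORICAL",
    "FeatureSpec",
    "DatasetSchema",
    "Dataset",
    "SplitIndices",
    "heart_schema",
    "binarize_label",
    "load_table",
    "write_native",
    "stratified_split",
    "largest_remainder_counts",
    "dataset_summary",
]


class ParseError(ValueError):
    """Malformed input row (wrong arity, unparseable field)."""


class ValidationError(ValueError):
    """Value outside the admissible set declared by the schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """One column of a clinical table: a name, a kind and, for categorical
    features, the ordered admissible codes."""

    name: str
    kind: str
    categories: tuple[float, ...] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if self.categories is None or len(self.categories) < 2:
                raise ValidationError(
                    f"categorical feature {self.name!r} needs >=2 categories"
                )
            object.__setattr__(self, "categories", tuple(float(c) for c in self.categories))
        elif self.categories is not None:
            raise ValidationError(
                f"continuous feature {self.name!r} must not declare categories"
            )


@dataclass(frozen=True)
class DatasetSchema:
    features: tuple[FeatureSpec, ...]
    label_name: str = "Num"
    missing_token: str = "?"

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        names = self.names
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names in schema")
        if self.label_name in names:
            raise ValidationError("label name collides with a feature name")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(f.kind for f in self.features)

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.kind == CONTINUOUS)

    @property
    def categorical_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.kind == CATEGORICAL)

    def spec(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "DatasetSchema":
        """Schema restricted to ``names``, preserving the original order."""
        keep = set(names)
        return DatasetSchema(
            features=tuple(f for f in self.features if f.name in keep),
            label_name=self.label_name,
            missing_token=self.missing_token,
        )


def heart_schema() -> DatasetSchema:
    """The shared 13-feature schema of the UCI heart-disease tables."""
    return DatasetSchema(
        features=(
            FeatureSpec("Age", CONTINUOUS, description="age in years"),
            FeatureSpec("Sex", CATEGORICAL, (0, 1), "1 male, 0 female"),
            FeatureSpec("Cp", CATEGORICAL, (1, 2, 3, 4), "chest pain type"),
            FeatureSpec("Trestbps", CONTINUOUS, description="resting blood pressure, mm Hg"),
            FeatureSpec("Chol", CONTINUOUS, description="serum cholesterol, mg/dl"),
            FeatureSpec("Fbs", CATEGORICAL, (0, 1), "fasting blood sugar > 120 mg/dl"),
            FeatureSpec("Restecg", CATEGORICAL, (0, 1, 2), "resting ECG result"),
            FeatureSpec("Thalach", CONTINUOUS, description="maximum heart rate achieved"),
            FeatureSpec("Exang", CATEGORICAL, (0, 1), "exercise induced angina"),
            FeatureSpec("Oldpeak", CONTINUOUS, description="exercise-induced ST depression"),
            FeatureSpec("Slope", CATEGORICAL, (1, 2, 3), "slope of peak exercise ST segment"),
            FeatureSpec("Ca", CATEGORICAL, (0, 1, 2, 3), "major vessels colored by fluoroscopy"),
            FeatureSpec("Thal", CATEGORICAL, (3, 6, 7), "thallium defect type"),
        ),
        label_name="Num",
        missing_token="?",
    )


class Dataset:
    """Instance-by-feature table with an explicit missing mask and 0/1 labels."""

    def __init__(
        self,
        schema: DatasetSchema,
        values: pd.DataFrame,
        missing_mask: pd.DataFrame | None = None,
        labels: np.ndarray | Sequence[int] | None = None,
        validate: bool = True,
    ) -> None:
        self.schema = schema
        self.values = values.reset_index(drop=True).astype(float)
        if missing_mask is None:
            missing_mask = self.values.isna()
        self.missing_mask = missing_mask.reset_index(drop=True).astype(bool)
        self.labels = np.asarray(labels, dtype=int)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if tuple(self.values.columns) != self.schema.names:
            raise ValidationError("value columns do not match schema feature names")
        if self.values.shape != self.missing_mask.shape:
            raise ValidationError("values and missing mask shapes differ")
        if len(self.labels) != len(self.values):
            raise ValidationError("label count does not match instance count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0/1 with no missing entries")
        for spec in self.schema.features:
            if spec.kind != CATEGORICAL:
                continue
            col = self.values[spec.name].to_numpy()
            observed = ~self.missing_mask[spec.name].to_numpy()
            bad = observed & ~np.isin(col, spec.categories)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"feature {spec.name!r}: value {col[i]!r} at row {i} is not "
                    f"among categories {spec.categories}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return len(self.schema.features)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def missing_fraction(self) -> pd.Series:
        return self.missing_mask.mean(axis=0)

    def take(self, rows: Sequence[int]) -> "Dataset":
        rows = np.asarray(rows, dtype=int)
        return Dataset(
            self.schema,
            self.values.iloc[rows],
            self.missing_mask.iloc[rows],
            self.labels[rows],
            validate=False,
        )

    def select_features(self, names: Sequence[str]) -> "Dataset":
        """Restrict to ``names`` (kept in schema order)."""
        sub = self.schema.subset(names)
        cols = list(sub.names)
        return Dataset(sub, self.values[cols], self.missing_mask[cols], self.labels,
                       validate=False)

    def copy(self) -> "Dataset":
        return Dataset(self.schema, self.values.copy(), self.missing_mask.copy(),
                       self.labels.copy(), validate=False)

    def equals(self, other: "Dataset") -> bool:
        """Structural equality: feature names/kinds/categories, labels, mask
        and observed values (descriptions are ignored)."""
        def shape(s: DatasetSchema):
            return (tuple((f.name, f.kind, f.categories) for f in s.features),
                    s.label_name)
        return (
            shape(self.schema) == shape(other.schema)
            and np.array_equal(self.labels, other.labels)
            and self.missing_mask.equals(other.missing_mask)
            and np.allclose(
                np.where(self.missing_mask, 0.0, self.values),
                np.where(other.missing_mask, 0.0, other.values),
                equal_nan=True,
            )
        )


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def parts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.train, self.validation, self.test


def binarize_label(raw: float, dialect: str) -> int:
    """Map a raw on-disk label to the 1 = patient convention.

    native: {0,1} pass through; statlog: 1 -> 0, 2 -> 1; cleveland: the 0-4
    severity code is positive iff > 0 (standard UCI binarization).
    """
    if not np.isfinite(raw):
        raise ValidationError(f"label {raw!r} is not finite")
    if dialect == "native":
        if raw in (0, 1):
            return int(raw)
        raise ValidationError(f"native label must be 0/1, got {raw!r}")
    if dialect == "statlog":
        if raw == 1:
            return 0
        if raw == 2:
            return 1
        raise ValidationError(f"statlog label must be 1/2, got {raw!r}")
    if dialect == "cleveland":
        if raw < 0 or raw != int(raw) or raw > 4:
            raise ValidationError(f"cleveland label must be an integer 0-4, got {raw!r}")
        return int(raw > 0)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _check_arity(path: Path, dialect: str, ncol: int) -> None:
    sep = None if dialect == "statlog" else ","
    skip = 1 if dialect == "native" else 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skip or not line.strip():
                continue
            found = len(line.split(sep))
            if found != ncol:
                raise ParseError(
                    f"{path}: line {lineno} has {found} fields, expected {ncol}"
                )


def _parse_rows(path: Path, dialect: str, schema: DatasetSchema) -> pd.DataFrame:
    ncol = len(schema.features) + 1
    columns = list(schema.names) + [schema.label_name]
    _check_arity(path, dialect, ncol)
    if dialect == "native":
        na = ["", "NA", schema.missing_token]
        frame = pd.read_csv(path, sep=",", na_values=na, keep_default_na=False,
                            skipinitialspace=True)
        if list(frame.columns) != columns:
            raise ParseError(
                f"{path}: header {list(frame.columns)} does not match schema {columns}"
            )
        return frame
    sep = r"\s+" if dialect == "statlog" else ","
    na = [schema.missing_token] if dialect == "cleveland" else []
    try:
        frame = pd.read_csv(path, sep=sep, header=None, na_values=na,
                            keep_default_na=False, skipinitialspace=True)
    except pd.errors.ParserError as exc:  # arity mismatch: pandas reports the line
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[1] != ncol:
        raise ParseError(
            f"{path}: expected {ncol} columns, found {frame.shape[1]}"
        )
    frame.columns = columns
    return frame


def load_table(path: str | Path, dialect: str = "native",
               schema: DatasetSchema | None = None) -> Dataset:
    """Read a delimited table in one of the three dialects into a Dataset."""
    if dialect not in ("native", "statlog", "cleveland"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    schema = schema or heart_schema()
    path = Path(path)
    frame = _parse_rows(path, dialect, schema)
    raw_labels = frame[schema.label_name].to_numpy(dtype=float)
    if np.isnan(raw_labels).any():
        i = int(np.flatnonzero(np.isnan(raw_labels))[0])
        raise ValidationError(f"{path}: missing label at row {i}")
    labels = np.array([binarize_label(v, dialect) for v in raw_labels])
    values = frame[list(schema.names)].astype(float)
    return Dataset(schema, values, values.isna(), labels)


def write_native(dataset: Dataset, path: str | Path) -> None:
    """Write the native comma-separated dialect (missing cells empty)."""
    frame = dataset.values.copy()
    frame = frame.mask(dataset.missing_mask)
    frame[dataset.schema.label_name] = dataset.labels
    frame.to_csv(path, index=False, na_rep="")


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer part sizes for ``n`` items by largest-remainder rounding.

    Remainder ties are broken toward the earlier part (training first).
    """
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValidationError("fractions must sum to 1")
    ideal = fractions * n
    base = np.floor(ideal).astype(int)
    short = n - base.sum()
    order = sorted(range(len(fractions)), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def stratified_split(dataset: Dataset, fractions: Sequence[float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> SplitIndices:
    """Class-stratified train/validation/test partition.

    Per-class part sizes follow largest-remainder rounding so each part's class
    composition deviates from ``fraction * class_size`` by less than one
    instance.  Deterministic for a fixed seed.
    """
    y = dataset.labels
    nparts = len(fractions)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in range(nparts)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < nparts:
            raise ValidationError(
                f"class {cls} has {len(idx)} instances; needs >= {nparts}"
            )
        idx = idx.copy()
        rng.shuffle(idx)
        counts = largest_remainder_counts(len(idx), fractions)
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(idx[start:start + c].tolist())
            start += c
    train, val, test = (np.sort(np.array(p, dtype=int)) for p in parts)
    return SplitIndices(train=train, validation=val, test=test, seed=seed)


def dataset_summary(dataset: Dataset) -> dict:
    """JSON-serializable summary: class counts and per-feature missing rates."""
    y = dataset.labels
    frac = dataset.missing_fraction()
    return {
        "n_instances": int(dataset.n_instances),
        "n_features": int(dataset.n_features),
        "n_patients": int((y == 1).sum()),
        "n_controls": int((y == 0).sum()),
        "percent_patients": round(100.0 * float((y == 1).mean()), 2),
        "missing_fraction": {k: float(v) for k, v in frac.items()},
    }


def write_summary(dataset: Dataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataset_summary(dataset), indent=2, sort_keys=True))
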