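"""Seeded generator of heart-disease-like tabular data.

Labels are Bernoulli(prevalence); continuous features are class-conditional
Gaussians whose patient-class mean is shifted by an effect size ``d`` in SD
units; categorical features are class-conditional multinomials.  Noise
features share one distribution across classes.  MCAR missingness can be
injected per cell, with per-feature overrides to fabricate heavily missing
columns for the sparse-feature filter.

The default fixture mirrors the 270-instance, 44.4%-prevalence layout of the
13-feature heart-disease schema, with three informative continuous features
(effects 1.5, 1.0, 0.7 SD) and uninformative remaining features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import (CATEGORICAL, CONTINUOUS, Dataset, DatasetSchema, FeatureSpec,
                     ValidationError, heart_schema)

__all__ = [
    "ContinuousFeature",
    "CategoricalFeature",
    "SynthConfig",
    "generate",
    "inject_missing",
    "statlog_like",
]


@dataclass(frozen=True)
class ContinuousFeature:
    """Gaussian feature: control mean/SD, patient mean shifted by d * sd."""

    name: str
    mean: float = 0.0
    sd: float = 1.0
    effect: float = 0.0  # patient-class mean shift, in SD units

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError(f"{self.name}: sd must be positive")


@dataclass(frozen=True)
class CategoricalFeature:
    """Multinomial feature with per-class category probabilities."""

    name: str
    categories: tuple[float, ...]
    probs_control: tuple[float, ...]
    probs_patient: tuple[float, ...] | None = None  # None -> same as control

    def __post_init__(self) -> None:
        pp = self.probs_patient if self.probs_patient is not None else self.probs_control
        for probs in (self.probs_control, pp):
            if len(probs) != len(self.categories):
                raise ValidationError(f"{self.name}: probability arity mismatch")
            if not np.isclose(sum(probs), 1.0):
                raise ValidationError(f"{self.name}: probabilities must sum to 1")


@dataclass(frozen=True)
class SynthConfig:
    features: tuple
    n: int = 270
    prevalence: float = 0.444
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError("n must be >= 4")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")


def _schema_from_config(config: SynthConfig) -> DatasetSchema:
    specs = []
    for f in config.features:
        if isinstance(f, ContinuousFeature):
            specs.append(FeatureSpec(f.name, CONTINUOUS, description="synthetic"))
        else:
            specs.append(FeatureSpec(f.name, CATEGORICAL, f.categories,
                                     description="synthetic"))
    return DatasetSchema(features=tuple(specs), label_name="Num", missing_token="?")


def generate(config: SynthConfig) -> Dataset:
    """Draw a complete dataset (then optionally pass to :func:`inject_missing`)."""
    rng = np.random.default_rng(config.seed)
    y = (rng.random(config.n) < config.prevalence).astype(int)
    cols = {}
    for f in config.features:
        if isinstance(f, ContinuousFeature):
            loc = f.mean + f.effect * f.sd * y
            cols[f.name] = rng.normal(loc, f.sd)
        else:
            pp = f.probs_patient if f.probs_patient is not None else f.probs_control
            cdf = np.vstack([np.cumsum(f.probs_control), np.cumsum(pp)])
            u = rng.random(config.n)
            idx = np.array([np.searchsorted(cdf[cls], ui, side="right")
                            for cls, ui in zip(y, u)])
            idx = np.clip(idx, 0, len(f.categories) - 1)
            cols[f.name] = np.asarray(f.categories, dtype=float)[idx]
    schema = _schema_from_config(config)
    values = pd.DataFrame(cols)[list(schema.names)]
    ds = Dataset(schema, values, labels=y)
    if config.missing_rate > 0:
        ds = inject_missing(ds, config.missing_rate, seed=config.seed + 1)
    return ds


def inject_missing(dataset: Dataset, rate: float, seed: int = 0,
                   per_feature: dict[str, float] | None = None) -> Dataset:
    """MCAR mask at ``rate`` per cell; ``per_feature`` overrides individual
    feature rates (labels are never masked)."""
    if not (0.0 <= rate < 1.0):
        raise ValidationError("rate must be in [0, 1)")
    if rate == 0.0 and not per_feature:
        return dataset.copy()
    rng = np.random.default_rng(seed)
    rates = np.array([
        (per_feature or {}).get(name, rate) for name in dataset.schema.names
    ])
    u = rng.random((dataset.n_instances, dataset.n_features))
    mask = u < rates[None, :]
    values = dataset.values.copy()
    arr = values.to_numpy()
    arr[mask] = np.nan
    values.iloc[:, :] = arr
    mask_frame = pd.DataFrame(mask | dataset.missing_mask.to_numpy(),
                              columns=values.columns)
    return Dataset(dataset.schema, values, mask_frame, dataset.labels)


def statlog_like(n: int = 270, seed: int = 0, missing_rate: float = 0.0,
                 prevalence: float = 0.444) -> SynthConfig:
    """Default fixture: the 13-feature heart schema, three informative
    continuous features (d = 1.5 on Thalach, 1.0 on Oldpeak, 0.7 on Age),
    remaining features noise."""
    hs = heart_schema()

    def cat(name: str, probs) -> CategoricalFeature:
        return CategoricalFeature(name, hs.spec(name).categories, tuple(probs))

    features = (
        ContinuousFeature("Age", mean=54.0, sd=9.0, effect=0.7),
        cat("Sex", (0.32, 0.68)),
        cat("Cp", (0.07, 0.15, 0.29, 0.49)),
        ContinuousFeature("Trestbps", mean=131.0, sd=17.0),
        ContinuousFeature("Chol", mean=249.0, sd=52.0),
        cat("Fbs", (0.85, 0.15)),
        cat("Restecg", (0.49, 0.01, 0.50)),
        ContinuousFeature("Thalach", mean=158.0, sd=19.0, effect=-1.5),
        cat("Exang", (0.67, 0.33)),
        ContinuousFeature("Oldpeak", mean=0.6, sd=0.8, effect=1.0),
        cat("Slope", (0.47, 0.46, 0.07)),
        cat("Ca", (0.59, 0.21, 0.12, 0.08)),
        cat("Thal", (0.55, 0.05, 0.40)),
    )
    return SynthConfig(features=features, n=n, prevalence=prevalence,
                       missing_rate=missing_rate, seed=seed)
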