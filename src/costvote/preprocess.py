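"""Missing-feature filtering, group-mean imputation and z-normalization.

The preprocessing stage mirrors common clinical-table practice: features
missing in more than half the instances are removed outright; remaining
missing cells are filled with the class-conditional mean (continuous) or mode
(categorical) — "group" imputation, which consults the instance's own label —
and continuous features are standardized to mean 0, variance 1.

Group imputation leaks label information when applied to instances whose label
should be unknown, so two modes are provided: ``group`` applies label-aware
statistics everywhere (preprocessing before splitting, matching the original
protocol), while ``strict`` fits on training data only and uses label-free
overall statistics for validation/test instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CATEGORICAL, CONTINUOUS, Dataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationStats",
    "NormalizationStats",
    "drop_sparse_features",
    "fit_imputer",
    "impute",
    "fit_normalizer",
    "apply_normalizer",
    "preprocess_report",
]


@dataclass(frozen=True)
class ImputationStats:
    """Per-feature fill values: per-class and overall mean (continuous) or
    mode (categorical; ties broken toward the smallest code)."""

    class_stats: dict  # name -> {0: value, 1: value}
    overall: dict      # name -> value
    fitted_on: int


@dataclass(frozen=True)
class NormalizationStats:
    """Per-continuous-feature mean and population (divide-by-n) SD."""

    mean: dict
    sd: dict
    fitted_on: int


def drop_sparse_features(dataset: Dataset, threshold: float = 0.5
                         ) -> tuple[Dataset, list[str]]:
    """Remove features whose missing fraction exceeds ``threshold``.

    Survivor order is preserved.  Raises if every feature would be dropped.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must be in (0, 1]")
    frac = dataset.missing_fraction()
    dropped = [n for n in dataset.schema.names if frac[n] > threshold]
    kept = [n for n in dataset.schema.names if n not in dropped]
    if not kept:
        raise ValidationError("all features exceed the missing-value threshold")
    if not dropped:
        return dataset, []
    return dataset.select_features(kept), dropped


def _mode(values: np.ndarray) -> float:
    """Most frequent value; ties broken toward the smallest code."""
    codes, counts = np.unique(values, return_counts=True)
    return float(codes[np.argmax(counts)])  # np.unique sorts, argmax takes first max


def fit_imputer(dataset: Dataset, labels_available: bool = True) -> ImputationStats:
    """Compute class-conditional and overall fill statistics.

    A feature fully missing within one class falls back to the overall
    statistic for that class (logged as a warning).
    """
    class_stats: dict = {}
    overall: dict = {}
    y = dataset.labels
    for spec in dataset.schema.features:
        col = dataset.values[spec.name].to_numpy()
        obs = ~dataset.missing_mask[spec.name].to_numpy()
        if not obs.any():
            raise ValidationError(f"feature {spec.name!r} has no observed values")
        agg = np.mean if spec.kind == CONTINUOUS else _mode
        ov = float(agg(col[obs]))
        overall[spec.name] = ov
        if labels_available:
            per_class = {}
            for cls in (0, 1):
                sel = obs & (y == cls)
                if sel.any():
                    per_class[cls] = float(agg(col[sel]))
                else:
                    logger.warning(
                        "feature %s fully missing in class %d; overall statistic used",
                        spec.name, cls,
                    )
                    per_class[cls] = ov
            class_stats[spec.name] = per_class
    return ImputationStats(class_stats=class_stats, overall=overall,
                           fitted_on=dataset.n_instances)


def impute(dataset: Dataset, stats: ImputationStats, mode: str = "group") -> Dataset:
    """Fill missing cells and clear the missing mask.

    ``group``: each cell takes the statistic of the instance's own class.
    ``strict``: label-free overall statistics (for held-out instances).
    """
    if mode not in ("group", "strict"):
        raise ValidationError(f"unknown imputation mode {mode!r}")
    missing_stats = [n for n in dataset.schema.names if n not in stats.overall]
    if missing_stats:
        raise ValidationError(f"imputation stats lack features {missing_stats}")
    if mode == "group" and not stats.class_stats:
        raise ValidationError("group-mode imputation needs class-conditional stats")
    values = dataset.values.copy()
    y = dataset.labels
    for name in dataset.schema.names:
        miss = dataset.missing_mask[name].to_numpy()
        if not miss.any():
            continue
        if mode == "group":
            fill = np.where(y == 1, stats.class_stats[name][1], stats.class_stats[name][0])
        else:
            fill = np.full(len(values), stats.overall[name])
        col = values[name].to_numpy()
        col[miss] = fill[miss]
        values[name] = col
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return Dataset(dataset.schema, values, mask, dataset.labels)


def fit_normalizer(dataset: Dataset) -> NormalizationStats:
    """Mean/SD of each continuous feature (population SD, divide by n)."""
    mean: dict = {}
    sd: dict = {}
    for name in dataset.schema.continuous_names:
        if dataset.missing_mask[name].any():
            raise ValidationError(
                f"feature {name!r} still has missing cells; impute before normalizing"
            )
        col = dataset.values[name].to_numpy()
        mean[name] = float(np.mean(col))
        sd[name] = float(np.std(col))
    return NormalizationStats(mean=mean, sd=sd, fitted_on=dataset.n_instances)


def apply_normalizer(dataset: Dataset, stats: NormalizationStats) -> Dataset:
    """z-score continuous features with fitted stats; a zero-SD feature maps
    to all zeros; categorical features are untouched."""
    values = dataset.values.copy()
    for name in dataset.schema.continuous_names:
        if name not in stats.mean:
            raise ValidationError(f"normalizer has no stats for feature {name!r}")
        sd = stats.sd[name]
        if sd == 0.0:
            values[name] = 0.0
        else:
            values[name] = (values[name] - stats.mean[name]) / sd
    return Dataset(dataset.schema, values, dataset.missing_mask, dataset.labels,
                   validate=False)


def preprocess_report(dataset_before: Dataset, dropped: list[str],
                      stats: ImputationStats) -> dict:
    """JSON-serializable record of what preprocessing did."""
    frac = dataset_before.missing_fraction()
    return {
        "dropped_features": list(dropped),
        "missing_fraction": {k: float(v) for k, v in frac.items()},
        "imputation": {
            "overall": stats.overall,
            "class_stats": {k: {str(c): v for c, v in d.items()}
                            for k, d in stats.class_stats.items()},
            "fitted_on": stats.fitted_on,
        },
    }
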