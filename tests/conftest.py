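"""Shared fixtures: tiny handcrafted tables and random mixed-type datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from costvote.dataio import (CATEGORICAL, CONTINUOUS, Dataset, DatasetSchema,
                             FeatureSpec)


def make_dataset(values: dict, labels, kinds: dict | None = None,
                 categories: dict | None = None) -> Dataset:
    """Build a Dataset from plain dicts; NaN cells become missing."""
    kinds = kinds or {}
    categories = categories or {}
    frame = pd.DataFrame(values).astype(float)
    specs = []
    for name in frame.columns:
        kind = kinds.get(name, CONTINUOUS)
        cats = categories.get(name)
        if kind == CATEGORICAL and cats is None:
            observed = frame[name].dropna().unique()
            cats = tuple(sorted(observed))
            if len(cats) < 2:
                cats = tuple(sorted(set(cats) | {-999.0}))
        specs.append(FeatureSpec(name, kind, cats if kind == CATEGORICAL else None))
    schema = DatasetSchema(features=tuple(specs))
    return Dataset(schema, frame, frame.isna(), np.asarray(labels, dtype=int))


def random_mixed_dataset(rng: np.random.Generator, n: int, p: int) -> Dataset:
    """Random dataset with a mix of continuous and categorical columns and
    both classes populated."""
    values = {}
    kinds = {}
    categories = {}
    for j in range(p):
        name = f"f{j}"
        if j % 2 == 0:
            values[name] = rng.normal(size=n)
        else:
            cats = (0.0, 1.0, 2.0)
            values[name] = rng.choice(cats, size=n)
            kinds[name] = CATEGORICAL
            categories[name] = cats
    labels = rng.integers(0, 2, size=n)
    # guarantee >= 2 instances per class for hit/miss search
    labels[:2] = 0
    labels[2:4] = 1
    return make_dataset(values, labels, kinds, categories)


def naive_relief(ds: Dataset, squared: bool = True) -> np.ndarray:
    """Brute-force Relief: explicit double loops, one full pass in index
    order, no code shared with the implementation under test."""
    X = ds.values.to_numpy(dtype=float)
    y = ds.labels
    kinds = ds.schema.kinds
    n, p = X.shape

    def d_feat(j, a, b):
        if kinds[j] == CATEGORICAL:
            return 0.0 if X[a, j] == X[b, j] else 1.0
        return abs(X[a, j] - X[b, j])

    def dist(a, b):
        return sum(d_feat(j, a, b) for j in range(p))

    W = np.zeros(p)
    for i in range(n):
        hit = miss = None
        hit_d = miss_d = float("inf")
        for other in range(n):
            if other == i:
                continue
            dd = dist(i, other)
            if y[other] == y[i]:
                if dd < hit_d:
                    hit, hit_d = other, dd
            else:
                if dd < miss_d:
                    miss, miss_d = other, dd
        for j in range(p):
            dh, dm = d_feat(j, i, hit), d_feat(j, i, miss)
            if squared:
                dh, dm = dh * dh, dm * dm
            W[j] += (dm - dh) / n
    return W


@pytest.fixture
def toy_mixed_dataset() -> Dataset:
    """Six instances, one continuous + one categorical feature."""
    return make_dataset(
        {"x": [0.0, 0.1, 0.9, 1.0, 0.5, 0.45],
         "c": [0, 0, 1, 1, 0, 1]},
        labels=[1, 1, 0, 0, 1, 0],
        kinds={"c": CATEGORICAL},
        categories={"c": (0.0, 1.0)},
    )
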