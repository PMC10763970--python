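"""Shared fixtures: toy schemas, synthetic splits, and stub learners."""

from __future__ import annotations

import numpy as np
import pytest

from selfstack import (
    BaseLearnerSpec,
    Cohort,
    FeatureSchema,
    StackConfig,
    encode_features,
    make_separable_cohort,
    split_train_test,
)
from selfstack.data_io import Column


class ConstantStub:
    """Always predicts one fixed class."""

    def __init__(self, label: int = 0):
        self.label = label

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)

    def predict_proba(self, X):
        p = np.zeros((len(X), len(self.classes_)))
        p[:, list(self.classes_).index(self.label)] = 1.0
        return p


class MemorizingStub:
    """Returns the memorized training label for rows seen at fit time and a
    fixed arbitrary class otherwise; counts lookups that hit the memory so
    out-of-fold leakage is directly observable."""

    def __init__(self, leak_counter: list | None = None, fallback: int = 0):
        self.leak_counter = leak_counter if leak_counter is not None else [0]
        self.fallback = fallback

    def fit(self, X, y):
        self.memory_ = {row.tobytes(): int(lab) for row, lab in zip(X, y)}
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(np.asarray(X)):
            key = row.tobytes()
            if key in self.memory_:
                self.leak_counter[0] += 1
                out[i] = self.memory_[key]
            else:
                out[i] = self.fallback
        return out


@pytest.fixture(scope="session")
def fast_rf_spec() -> BaseLearnerSpec:
    """A 30-tree forest: same behaviour class as the default, far cheaper."""
    return BaseLearnerSpec("RF", {"n_estimators": 30})


@pytest.fixture(scope="session")
def fast_stack_config(fast_rf_spec) -> StackConfig:
    return StackConfig(base_spec=fast_rf_spec, meta_spec=fast_rf_spec)


@pytest.fixture(scope="session")
def separable_split():
    """Encoded 80:20 split of a small well-separated 5-class cohort."""
    cohort = make_separable_cohort(n_per_class=60, n_classes=5, seed=0)
    encoded = encode_features(cohort)
    return split_train_test(encoded, ratio=0.2, seed=0, shuffle=True), encoded


def toy_schema(with_categorical: bool = False) -> FeatureSchema:
    cols = [Column("x", "continuous"), Column("flag", "binary")]
    if with_categorical:
        cols.append(Column("src", "categorical"))
    cols += [Column("target", "target"), Column("pid", "identifier")]
    return FeatureSchema(tuple(cols))


def toy_cohort(rows, with_categorical: bool = False) -> Cohort:
    return Cohort(toy_schema(with_categorical), [tuple(r) for r in rows])
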