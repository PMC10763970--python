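"""Self-stacking and self-voting ensembles of homogeneous base learners.

The self-stacking classifier (SSC) trains m random-forest base learners and
feeds their *out-of-fold* predictions — each training row is predicted by a
model fit on folds excluding that row — as meta-features to another random
forest, the meta-learner.  Using one model family throughout ("self"-stacking)
keeps the ensemble homogeneous; diversity comes only from the learners'
distinct random seeds.  The self-voting ensemble (SVEC) instead combines
the members' outputs directly, by majority label (hard) or by summed class
probabilities (soft).

Base-learner families and their default hyperparameters match the tuned
settings used throughout the evaluation protocol (random forest with 200
trees capped at depth 50, and so on); `make_model` turns a spec into a
configured scikit-learn estimator.
"""

from __future__ import annotations

import inspect
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .data_io import EncodedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BaseLearnerSpec",
    "StackConfig",
    "MetaDataset",
    "FittedStack",
    "VoteEnsemble",
    "SelfStackingClassifier",
    "SelfVotingClassifier",
    "make_model",
    "build_meta_features",
    "fit_self_stack",
    "predict_self_stack",
    "fit_self_vote",
    "vote_hard",
    "vote_soft",
]

_FAMILIES = {
    "RF": RandomForestClassifier,
    "GBM": GradientBoostingClassifier,
    "AdaBoost": AdaBoostClassifier,
    "LR": LogisticRegression,
    "SVC": SVC,
}

#: Tuned defaults per family, as used in the evaluation protocol.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "RF": {"n_estimators": 200, "max_depth": 50},
    "GBM": {
        "max_depth": 200,
        "learning_rate": 0.2,
        "n_estimators": 50,
        "random_state": 52,
    },
    "AdaBoost": {"n_estimators": 300, "random_state": 5, "learning_rate": 0.8},
    "LR": {"solver": "saga", "multi_class": "multinomial", "C": 3.0},
    "SVC": {"kernel": "linear", "C": 1.0},
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A model family plus hyperparameter overrides and a seed.

    ``seed`` (when not None) takes precedence over any ``random_state``
    hyperparameter, so ensembles can derive distinct member seeds from a
    single master seed.
    """

    family: str = "RF"
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}"
            )

    def with_seed(self, seed: int) -> "BaseLearnerSpec":
        return replace(self, seed=seed)


def make_model(spec: BaseLearnerSpec):
    """Instantiate an unfitted scikit-learn estimator per the spec.

    Unknown hyperparameter names raise.  ``multi_class='multinomial'`` is
    accepted for LR but dropped when the installed scikit-learn no longer
    takes the argument (the saga solver is multinomial natively).
    """
    cls = _FAMILIES[spec.family]
    params = dict(DEFAULT_HYPERPARAMETERS[spec.family])
    params.update(spec.hyperparameters)
    accepted = set(inspect.signature(cls).parameters)
    for name in params:
        if name not in accepted and name != "multi_class":
            raise ValueError(
                f"unknown hyperparameter {name!r} for family {spec.family!r}"
            )
    if "multi_class" in params and "multi_class" not in accepted:
        params.pop("multi_class")
    if spec.seed is not None and "random_state" in accepted:
        params["random_state"] = spec.seed
    return cls(**params)


@dataclass(frozen=True)
class StackConfig:
    """Architecture of the self-stacking classifier.

    m base learners (default 4) are each trained through k-fold
    cross-validation (default k=5) to produce out-of-fold meta-features;
    ``meta_mode`` selects label meta-features (the default: each base
    learner contributes its predicted class, one-hot encoded for the
    meta-learner) or class-probability vectors.
    """

    m: int = 4
    k: int = 5
    meta_mode: str = "label"
    base_spec: BaseLearnerSpec = field(default_factory=BaseLearnerSpec)
    meta_spec: BaseLearnerSpec = field(default_factory=BaseLearnerSpec)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.meta_mode not in ("label", "proba"):
            raise ValueError("meta_mode must be 'label' or 'proba'")


@dataclass
class MetaDataset:
    """Out-of-fold base predictions used to train the meta-learner.

    Z is n x m in label mode (integer class per learner) and n x (m*C) in
    proba mode.  Row i's entries come from models whose training folds
    excluded row i.
    """

    Z: np.ndarray
    y: np.ndarray
    fold_assignment: np.ndarray
    meta_mode: str
    n_classes: int


def _aligned_proba(model, X: np.ndarray, n_classes: int) -> np.ndarray:
    """predict_proba with columns aligned to the full class index space.

    A model fit on a fold missing some class has no probability column for
    it; absent classes are padded with probability 0.
    """
    p = model.predict_proba(X)
    out = np.zeros((len(X), n_classes))
    out[:, np.asarray(model.classes_, dtype=int)] = p
    return out


def build_meta_features(
    train: EncodedMatrix,
    config: StackConfig,
    model_factory: Callable[[int], object] | None = None,
) -> MetaDataset:
    """Construct the meta-feature matrix by k-fold out-of-fold prediction.

    For each base learner j (seeded ``master_seed + j``) and each of the k
    folds, the learner is fit on the fold's complement and predicts the
    held-out fold.  ``model_factory(j)`` may inject arbitrary estimators
    (used by stubs in tests); by default the base spec is instantiated with
    the derived seed.
    """
    n, C = train.n, train.n_classes
    if n == 0:
        raise ValueError("training set is empty")
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds n={n}")
    if model_factory is None:
        model_factory = lambda j: make_model(
            config.base_spec.with_seed(config.master_seed + j)
        )

    kf = KFold(n_splits=config.k, shuffle=True, random_state=config.master_seed)
    folds = list(kf.split(train.X))
    fold_assignment = np.empty(n, dtype=int)
    for f, (_, held) in enumerate(folds):
        fold_assignment[held] = f

    width = config.m if config.meta_mode == "label" else config.m * C
    Z = np.empty((n, width), dtype=float)
    for j in range(config.m):
        for fit_idx, held_idx in folds:
            model = model_factory(j)
            if len(np.unique(train.y[fit_idx])) < C:
                warnings.warn(
                    f"fold complement for learner {j} is missing a class",
                    stacklevel=2,
                )
            model.fit(train.X[fit_idx], train.y[fit_idx])
            if config.meta_mode == "label":
                Z[held_idx, j] = model.predict(train.X[held_idx])
            else:
                Z[held_idx, j * C:(j + 1) * C] = _aligned_proba(
                    model, train.X[held_idx], C
                )
    return MetaDataset(Z, train.y.copy(), fold_assignment, config.meta_mode, C)


def _encode_meta(Z: np.ndarray, meta_mode: str, n_classes: int) -> np.ndarray:
    """Meta-learner input encoding: one-hot labels, or probabilities as-is.

    One-hot encoding avoids inventing an ordinal structure over class
    indices that the meta-learner would otherwise be free to exploit.
    """
    if meta_mode == "proba":
        return Z
    n, m = Z.shape
    out = np.zeros((n, m * n_classes))
    for j in range(m):
        out[np.arange(n), j * n_classes + Z[:, j].astype(int)] = 1.0
    return out


@dataclass
class FittedStack:
    """A trained self-stacking classifier.

    The prediction path replays training exactly: base models predict,
    their outputs are encoded as at training time, and the meta-model maps
    the encoding to the final label.
    """

    base_models: list
    meta_model: object
    config: StackConfig
    class_map: dict[str, int]
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_self_stack(self, X)


def fit_self_stack(
    train: EncodedMatrix,
    config: StackConfig | None = None,
    model_factory: Callable[[int], object] | None = None,
    meta_factory: Callable[[], object] | None = None,
) -> FittedStack:
    """Train the self-stacking classifier.

    Builds the out-of-fold meta-dataset, fits the meta-learner on it, then
    refits every base learner on the full training set for inference.  The
    meta-learner's seed is ``master_seed + m``, next after the base seeds.
    """
    config = config or StackConfig()
    if len(np.unique(train.y)) < 2:
        raise ValueError("training data has a single class; cannot stack")
    meta = build_meta_features(train, config, model_factory=model_factory)
    if meta_factory is None:
        meta_factory = lambda: make_model(
            config.meta_spec.with_seed(config.master_seed + config.m)
        )
    meta_model = meta_factory()
    meta_model.fit(_encode_meta(meta.Z, config.meta_mode, meta.n_classes), meta.y)

    if model_factory is None:
        model_factory = lambda j: make_model(
            config.base_spec.with_seed(config.master_seed + j)
        )
    base_models = []
    for j in range(config.m):
        model = model_factory(j)
        model.fit(train.X, train.y)
        base_models.append(model)
    return FittedStack(
        base_models=base_models,
        meta_model=meta_model,
        config=config,
        class_map=dict(train.class_map),
        n_features=train.X.shape[1],
    )


def predict_self_stack(model: FittedStack, X: np.ndarray) -> np.ndarray:
    """Predict labels: base outputs -> training-time encoding -> meta model."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X must have {model.n_features} columns, got shape {X.shape}"
        )
    if len(X) == 0:
        return np.empty(0, dtype=int)
    C = len(model.class_map)
    cfg = model.config
    if cfg.meta_mode == "label":
        Z = np.column_stack([m.predict(X) for m in model.base_models])
    else:
        Z = np.column_stack(
            [_aligned_proba(m, X, C) for m in model.base_models]
        )
    return np.asarray(
        model.meta_model.predict(_encode_meta(Z, cfg.meta_mode, C)), dtype=int
    )


@dataclass
class VoteEnsemble:
    """Fitted members plus a fixed voting criterion (hard or soft)."""

    base_models: list
    criterion: str
    class_map: dict[str, int]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            return np.empty(0, dtype=int)
        C = len(self.class_map)
        if self.criterion == "hard":
            preds = np.vstack([m.predict(X) for m in self.base_models])
            return vote_hard(preds, n_classes=C)
        probas = np.stack(
            [_aligned_proba(m, X, C) for m in self.base_models]
        )
        return vote_soft(probas)


def fit_self_vote(
    train: EncodedMatrix,
    n_base: int = 3,
    spec: BaseLearnerSpec | None = None,
    criterion: str = "hard",
    master_seed: int = 0,
    model_factory: Callable[[int], object] | None = None,
) -> VoteEnsemble:
    """Fit a self-voting ensemble of ``n_base`` same-family learners whose
    seeds are derived from ``master_seed``."""
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    if criterion not in ("hard", "soft"):
        raise ValueError("criterion must be 'hard' or 'soft'")
    spec = spec or BaseLearnerSpec()
    if model_factory is None:
        model_factory = lambda j: make_model(spec.with_seed(master_seed + j))
    models = []
    for j in range(n_base):
        model = model_factory(j)
        model.fit(train.X, train.y)
        models.append(model)
    return VoteEnsemble(models, criterion, dict(train.class_map))


class SelfStackingClassifier:
    """fit/predict adapter over `fit_self_stack` for use anywhere a plain
    estimator is expected (e.g. the cross-validation harness)."""

    def __init__(self, config: StackConfig | None = None) -> None:
        self.config = config or StackConfig()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SelfStackingClassifier":
        self.fitted_ = fit_self_stack(EncodedMatrix.from_arrays(X, y), self.config)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "fitted_"):
            raise RuntimeError("classifier is not fitted")
        return self.fitted_.predict(X)


class SelfVotingClassifier:
    """fit/predict adapter over `fit_self_vote`."""

    def __init__(
        self,
        n_base: int = 3,
        spec: BaseLearnerSpec | None = None,
        criterion: str = "hard",
        master_seed: int = 0,
    ) -> None:
        self.n_base = n_base
        self.spec = spec or BaseLearnerSpec()
        self.criterion = criterion
        self.master_seed = master_seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SelfVotingClassifier":
        self.fitted_ = fit_self_vote(
            EncodedMatrix.from_arrays(X, y),
            n_base=self.n_base,
            spec=self.spec,
            criterion=self.criterion,
            master_seed=self.master_seed,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "fitted_"):
            raise RuntimeError("classifier is not fitted")
        return self.fitted_.predict(X)


def vote_hard(
    predictions: np.ndarray, n_classes: int | None = None
) -> np.ndarray:
    """Majority vote over an (n_members x n_samples) label matrix.

    Ties break to the lowest class index.  Pure function: usable without
    fitted models.
    """
    predictions = np.asarray(predictions, dtype=int)
    if predictions.ndim != 2 or predictions.size == 0:
        raise ValueError("predictions must be a non-empty 2-D label matrix")
    C = n_classes if n_classes is not None else int(predictions.max()) + 1
    counts = np.zeros((predictions.shape[1], C), dtype=int)
    for row in predictions:
        counts[np.arange(predictions.shape[1]), row] += 1
    return counts.argmax(axis=1)  # argmax takes the lowest index on ties


def vote_soft(probabilities: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Argmax of summed member probabilities.

    Input is an (n_members x n_samples x n_classes) tensor whose rows must
    each sum to 1 within ``atol``.  Ties break to the lowest class index.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.ndim != 3 or probabilities.size == 0:
        raise ValueError("probabilities must be a non-empty 3-D tensor")
    sums = probabilities.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=atol):
        worst = float(np.abs(sums - 1.0).max())
        raise ValueError(
            f"probability rows must sum to 1 (worst deviation {worst:.3g})"
        )
    return probabilities.sum(axis=0).argmax(axis=1)
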