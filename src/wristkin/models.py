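"""Regression models mapping the 7-feature vector to a 0-28 scale score.

Four algorithm families are supported, each behind the same train/predict
surface:

* ``rf``   — random forest of regression trees; feature importance is the
  normalized mean impurity (Gini/variance) decrease per feature.
* ``svr``  — epsilon-insensitive support vector regression,
  f(x) = sum_i (alpha_hat_i - alpha_i) K(x, x_i) + b, RBF kernel by default.
* ``knn``  — k-nearest-neighbour regression; prediction is the mean label
  of the K nearest training points by Euclidean distance over the
  standardized features.  Distance ties are broken by training-set order
  after a seeded shuffle.
* ``bpnn`` — feed-forward back-propagation network, layers 7-56-28-7-1,
  ReLU activations, trained by stochastic gradient descent.

Training expects standardized features (see :mod:`wristkin.preprocess`);
predictions are clipped to the valid score range [0, 28].  The estimators
themselves are scikit-learn's; this module owns the contracts around them
(standardization checks, determinism, clipping, importance normalization).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import (
    ConfigurationError,
    ContractViolationError,
    InsufficientDataError,
    WrongAlgorithmError,
)
from .features import FEATURE_NAMES, FeatureVector
from .preprocess import LabeledDataset
from .simulate import SCORE_MAX

ALGORITHMS = ("rf", "svr", "knn", "bpnn")

#: Defaults for the hyperparameters the method leaves open.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "rf": {"n_estimators": 200, "max_depth": None},
    "svr": {"kernel": "rbf", "C": 10.0, "epsilon": 0.1},
    "knn": {"n_neighbors": 5, "weights": "uniform"},
    "bpnn": {
        "hidden_layer_sizes": (56, 28, 7),
        "learning_rate_init": 0.01,
        "max_iter": 500,
        "batch_size": 16,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice, hyperparameters, and the training seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        merged = {**DEFAULT_HYPERPARAMETERS[self.algorithm], **self.hyperparameters}
        if self.algorithm == "knn" and merged["n_neighbors"] < 1:
            raise ConfigurationError("knn needs n_neighbors >= 1")
        if self.algorithm == "rf" and merged["n_estimators"] < 1:
            raise ConfigurationError("rf needs n_estimators >= 1")
        if self.algorithm == "bpnn" and any(
            h < 1 for h in merged["hidden_layer_sizes"]
        ):
            raise ConfigurationError("bpnn hidden layer sizes must be >= 1")
        object.__setattr__(self, "hyperparameters", merged)


@dataclass(frozen=True)
class FeatureImportance:
    """Per-feature importance weights, normalized to sum to 1."""

    names: tuple
    weights: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {n: float(w) for n, w in zip(self.names, self.weights)}


@dataclass
class TrainedModel:
    """A fitted model plus the normalization state its inputs must carry."""

    spec: ModelSpec
    estimator: object
    norm_stats: dict
    feature_names: tuple = FEATURE_NAMES

    def predict(self, X) -> np.ndarray:
        """Predict scores for standardized feature rows, clipped to [0, 28]."""
        X = _as_matrix(X)
        if X.shape[1] != len(self.feature_names):
            raise ContractViolationError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        raw = np.asarray(self.estimator.predict(X), dtype=float)
        return np.clip(raw, 0.0, float(SCORE_MAX))

    def predict_dataset(self, dataset: LabeledDataset) -> np.ndarray:
        """Predict for a dataset, checking it carries this model's stats."""
        if dataset.norm_stats != self.norm_stats:
            raise ContractViolationError(
                "dataset is not standardized with this model's statistics"
            )
        return self.predict(dataset.X)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Model archive: spec JSON + pickled estimator + stats JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "spec.json", "w") as fh:
            json.dump(
                {
                    "algorithm": self.spec.algorithm,
                    "hyperparameters": _jsonable(self.spec.hyperparameters),
                    "seed": self.spec.seed,
                    "feature_names": list(self.feature_names),
                },
                fh,
                indent=2,
            )
        with open(directory / "norm_stats.json", "w") as fh:
            json.dump(self.norm_stats, fh, indent=2)
        joblib.dump(self.estimator, directory / "estimator.joblib")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        with open(directory / "spec.json") as fh:
            meta = json.load(fh)
        hyper = meta["hyperparameters"]
        if "hidden_layer_sizes" in hyper:
            hyper["hidden_layer_sizes"] = tuple(hyper["hidden_layer_sizes"])
        with open(directory / "norm_stats.json") as fh:
            stats = json.load(fh)
        return cls(
            spec=ModelSpec(meta["algorithm"], hyper, meta["seed"]),
            estimator=joblib.load(directory / "estimator.joblib"),
            norm_stats=stats,
            feature_names=tuple(meta["feature_names"]),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureVector):
        X = X.as_array()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _build_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.algorithm == "rf":
        return RandomForestRegressor(random_state=spec.seed, **hp)
    if spec.algorithm == "svr":
        return SVR(**hp)
    if spec.algorithm == "knn":
        return KNeighborsRegressor(**hp)
    # The network trains on standardized targets (scores have magnitude ~14,
    # which destabilizes plain SGD with ReLU units); predictions are mapped
    # back to the score scale automatically.
    net = MLPRegressor(
        activation="relu",
        solver="sgd",
        random_state=spec.seed,
        **hp,
    )
    return TransformedTargetRegressor(regressor=net, transformer=StandardScaler())


def train_model(spec: ModelSpec, train: LabeledDataset) -> TrainedModel:
    """Fit one model on a standardized training set.

    Training is deterministic given ``spec.seed``.  For KNN the training
    rows are shuffled with the seed first so that exact distance ties
    resolve reproducibly.
    """
    if train.n == 0:
        raise InsufficientDataError("empty training set")
    if not train.is_standardized:
        raise ContractViolationError("training data must be standardized first")
    X, y = train.X, train.y.astype(float)
    if spec.algorithm == "knn":
        order = np.random.default_rng(spec.seed).permutation(len(y))
        X, y = X[order], y[order]
    estimator = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X, y)
    return TrainedModel(spec=spec, estimator=estimator, norm_stats=train.norm_stats)


def knn_distance(a, b, feature_subset: tuple | None = None) -> float:
    """Euclidean distance between two standardized feature vectors.

    By default all 7 features enter the distance; ``feature_subset`` (a
    tuple of feature names) restricts it, e.g. to a smaller kinematic
    subset.
    """
    av, bv = _as_matrix(a)[0], _as_matrix(b)[0]
    if av.shape != bv.shape:
        raise ContractViolationError("feature vectors have mismatched dimensions")
    if feature_subset is not None:
        idx = [FEATURE_NAMES.index(name) for name in feature_subset]
        av, bv = av[idx], bv[idx]
    return float(np.sqrt(np.sum((av - bv) ** 2)))


def rf_feature_importance(model: TrainedModel) -> FeatureImportance:
    """Normalized mean impurity-decrease importances of a trained forest."""
    if model.spec.algorithm != "rf":
        raise WrongAlgorithmError("feature importances require an rf model")
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = raw.sum()
    weights = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    return FeatureImportance(names=model.feature_names, weights=weights)
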