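"""Binary classifiers: Gaussian-kernel SVM and a small feedforward ANN.

Both wrap scikit-learn estimators behind a uniform train/predict surface.
The SVM standardizes features on the training split and sets the kernel
bandwidth by the median heuristic unless told otherwise. The ANN uses the
24-12-6 hidden architecture and is "accepted" only when its training-set
success rate reaches 85 %; training restarts from fresh random weights a
few times if the first attempt falls short.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateLabelsError, EmptyInputError, ShapeError

_SERIALIZATION_VERSION = 1

#: Training-set success rate at which an ANN is accepted.
ANN_ACCEPT_SR = 0.85


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters for the Gaussian-kernel SVM.

    ``gamma`` may be a float or ``"median"`` for the median pairwise-distance
    heuristic computed on the (standardized) training features.
    """

    C: float = 1.0
    gamma: float | str = "median"
    standardize: bool = True
    seed: int = 0


@dataclass(frozen=True)
class ANNConfig:
    hidden_layers: tuple[int, ...] = (24, 12, 6)
    max_epochs: int = 2000
    restarts: int = 5
    accept_sr: float = ANN_ACCEPT_SR
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class SVMModel:
    """A fitted soft-margin RBF SVM (scaler + SVC pipeline)."""

    pipeline: Pipeline
    config: SVMConfig
    classes: np.ndarray
    n_features: int

    @property
    def gamma(self) -> float:
        return float(self.pipeline.named_steps["svc"]._gamma)

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        features = _check_matrix(features, self.n_features)
        if features.shape[0] == 0:
            return np.empty(0)
        return self.pipeline.decision_function(features)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = _check_matrix(features, self.n_features)
        if features.shape[0] == 0:
            return self.classes[:0]
        return self.pipeline.predict(features)


@dataclass
class ANNModel:
    """A trained feedforward network plus its acceptance status."""

    estimator: MLPClassifier
    config: ANNConfig
    classes: np.ndarray
    n_features: int
    training_sr: float
    accepted: bool
    restarts_used: int = 0

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = _check_matrix(features, self.n_features)
        if features.shape[0] == 0:
            return self.classes[:0]
        return self.estimator.predict(features)


def _check_matrix(features: np.ndarray, n_features: int | None = None) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features.reshape(1, -1) if features.size else features.reshape(0, 0)
    if features.ndim != 2:
        raise ShapeError(f"feature matrix must be 2-D, got ndim={features.ndim}")
    if n_features is not None and features.shape[0] > 0 and features.shape[1] != n_features:
        raise ShapeError(
            f"feature dimensionality {features.shape[1]} != training dimensionality {n_features}"
        )
    return features


def _check_training_input(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    features = _check_matrix(features)
    labels = np.asarray(labels)
    if features.shape[0] == 0:
        raise EmptyInputError("no training samples")
    if labels.shape[0] != features.shape[0]:
        raise ShapeError(
            f"{features.shape[0]} samples but {labels.shape[0]} labels"
        )
    if np.unique(labels).size < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    return features, labels


def median_heuristic_gamma(features: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise Euclidean distance.

    Returns ``gamma = 1 / (2 * median^2)``; falls back to ``1/p`` when all
    points coincide.
    """
    from scipy.spatial.distance import pdist

    distances = pdist(features)
    median = float(np.median(distances)) if distances.size else 0.0
    if median <= 0:
        return 1.0 / features.shape[1]
    return 1.0 / (2.0 * median * median)


def train_svm(features: np.ndarray, labels: np.ndarray, config: SVMConfig | None = None) -> SVMModel:
    config = config or SVMConfig()
    features, labels = _check_training_input(features, labels)
    steps = []
    if config.standardize:
        steps.append(("scaler", StandardScaler()))
    gamma = config.gamma
    if gamma == "median":
        scaled = StandardScaler().fit_transform(features) if config.standardize else features
        gamma = median_heuristic_gamma(scaled)
    steps.append(("svc", SVC(C=config.C, kernel="rbf", gamma=gamma, random_state=config.seed)))
    pipeline = Pipeline(steps)
    pipeline.fit(features, labels)
    return SVMModel(
        pipeline=pipeline,
        config=config,
        classes=pipeline.named_steps["svc"].classes_,
        n_features=features.shape[1],
    )


def train_ann(features: np.ndarray, labels: np.ndarray, config: ANNConfig | None = None) -> ANNModel:
    """Train the feedforward network, restarting until it is accepted.

    A network is accepted when its training-set success rate reaches
    ``config.accept_sr``. With ``max_epochs <= 0`` the weights are left at
    (one step past) their random initialization and the model is flagged
    not-accepted regardless of its score.
    """
    config = config or ANNConfig()
    features, labels = _check_training_input(features, labels)
    epochs = max(1, config.max_epochs)
    attempts = max(1, config.restarts)
    best: tuple[float, MLPClassifier] | None = None
    restarts_used = 0
    for attempt in range(attempts):
        estimator = MLPClassifier(
            hidden_layer_sizes=config.hidden_layers,
            activation="logistic",
            solver="adam",
            learning_rate_init=config.learning_rate,
            max_iter=epochs,
            random_state=config.seed + attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            estimator.fit(features, labels)
        sr = float(np.mean(estimator.predict(features) == labels))
        if best is None or sr > best[0]:
            best = (sr, estimator)
        restarts_used = attempt
        if sr >= config.accept_sr and config.max_epochs > 0:
            break
    training_sr, estimator = best
    accepted = config.max_epochs > 0 and training_sr >= config.accept_sr
    return ANNModel(
        estimator=estimator,
        config=config,
        classes=estimator.classes_,
        n_features=features.shape[1],
        training_sr=training_sr,
        accepted=accepted,
        restarts_used=restarts_used,
    )


def predict(model: SVMModel | ANNModel, features: np.ndarray) -> np.ndarray:
    """Labels for a feature matrix (or a single feature vector)."""
    return model.predict(features)


def save_model(model: SVMModel | ANNModel, path: str | Path) -> None:
    """Persist a model with a format version and its config embedded."""
    kind = "svm" if isinstance(model, SVMModel) else "ann"
    payload = {
        "format_version": _SERIALIZATION_VERSION,
        "kind": kind,
        "config": asdict(model.config),
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> SVMModel | ANNModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model format version: {version!r}")
    return payload["model"]
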