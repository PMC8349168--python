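"""Single-hidden-layer neural classifier over the 194-dim descriptor.

The network is 194 -> hidden_units -> 1 with logistic activations, trained by
stochastic gradient descent with classical momentum minimising cross-entropy
(scikit-learn's MLPClassifier with solver='sgd'). Defaults are the tuned
values of the published predictor: 23 hidden units, learning rate 0.001,
momentum 0.7, at most 437 epochs. Features are z-scored with statistics
fitted on the training rows only; the moment features span several orders of
magnitude, so standardisation is required for SGD at this learning rate.

A fitted model is frozen into plain numpy arrays (scaler statistics plus the
two weight matrices and biases) and serialised as JSON, so prediction is an
explicit forward pass that reproduces bit-for-bit after a save/load
round-trip.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

MODEL_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier; defaults are the tuned values."""

    hidden_units: int = 23
    learning_rate: float = 0.001
    momentum: float = 0.7
    max_iter: int = 437
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")


@dataclass
class TrainedModel:
    """Frozen scaler statistics and network weights of a fitted classifier."""

    mean: np.ndarray          # (n_features,)
    scale: np.ndarray         # (n_features,)
    W1: np.ndarray            # (n_features, hidden_units)
    b1: np.ndarray            # (hidden_units,)
    W2: np.ndarray            # (hidden_units,)
    b2: float
    config: ModelConfig
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": asdict(self.config),
            "scaler": {"mean": self.mean.tolist(), "scale": self.scale.tolist()},
            "weights": {
                "W1": self.W1.tolist(),
                "b1": self.b1.tolist(),
                "W2": self.W2.tolist(),
                "b2": float(self.b2),
            },
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model file format_version {version!r} not supported "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        return cls(
            mean=np.asarray(payload["scaler"]["mean"], dtype=float),
            scale=np.asarray(payload["scaler"]["scale"], dtype=float),
            W1=np.asarray(payload["weights"]["W1"], dtype=float),
            b1=np.asarray(payload["weights"]["b1"], dtype=float),
            W2=np.asarray(payload["weights"]["W2"], dtype=float),
            b2=float(payload["weights"]["b2"]),
            config=ModelConfig(**payload["config"]),
            training_meta=payload.get("training_meta", {}),
        )


def _check_features(X, n_features: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"feature matrix has {X.shape[1]} columns, expected {n_features}")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite feature value in row {int(np.flatnonzero(bad)[0])}")
    return X


def fit_scaler(X) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and standard deviation; zero-variance columns get 1."""
    X = _check_features(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    scaler = StandardScaler().fit(X)
    return scaler.mean_.copy(), scaler.scale_.copy()


def train(X, y, config: ModelConfig | None = None) -> TrainedModel:
    """Fit the classifier; deterministic given ``config.seed``."""
    if config is None:
        config = ModelConfig()
    X = _check_features(X)
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    mean, scale = fit_scaler(X)
    Xs = (X - mean) / scale
    net = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="logistic",
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=config.learning_rate,
        momentum=config.momentum,
        nesterovs_momentum=False,
        max_iter=config.max_iter,
        shuffle=True,
        random_state=config.seed,
        # minibatches of 32: at learning rate 1e-3 the default batch of 200
        # leaves the loss nearly flat within the epoch budget; the epoch cap
        # itself is the stopping rule, so the improvement-based stop is off
        batch_size=min(32, X.shape[0]),
        n_iter_no_change=config.max_iter,
        tol=0.0,
    )
    with warnings.catch_warnings():
        # hitting the epoch cap is expected behaviour, not a defect
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        net.fit(Xs, y)
    model = TrainedModel(
        mean=mean,
        scale=scale,
        W1=np.asarray(net.coefs_[0], dtype=float),
        b1=np.asarray(net.intercepts_[0], dtype=float),
        W2=np.asarray(net.coefs_[1], dtype=float).ravel(),
        b2=float(np.asarray(net.intercepts_[1]).ravel()[0]),
        config=config,
        training_meta={
            "n_samples": int(X.shape[0]),
            "n_positive": int((y == 1).sum()),
            "n_negative": int((y == 0).sum()),
            "final_loss": float(net.loss_),
            "epochs_run": int(net.n_iter_),
        },
    )
    return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_scores(model: TrainedModel, X) -> np.ndarray:
    """Posterior scores in [0, 1], one per row (explicit forward pass)."""
    X = _check_features(X, model.n_features)
    Xs = (X - model.mean) / model.scale
    hidden = _sigmoid(Xs @ model.W1 + model.b1)
    return _sigmoid(hidden @ model.W2 + model.b2)


def predict_labels(model: TrainedModel, X) -> np.ndarray:
    """Binary labels: 1 iff score >= config.threshold (boundary inclusive)."""
    return (predict_scores(model, X) >= model.config.threshold).astype(int)
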