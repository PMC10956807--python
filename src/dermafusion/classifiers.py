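"""Classification heads: random forest and feed-forward network.

The hybrid systems classify reduced (optionally fused) deep features
with one of two heads:

* **Random forest** — bagged decision trees, per-split feature
  subsampling (default sqrt(p)), majority vote over trees; scores are
  vote fractions.
* **Feed-forward network (FFNN)** — a fully connected rectifier
  network trained by gradient descent on the mean squared error
  against one-hot targets.  The published configuration (fifteen
  hidden layers, eight output neurons, MSE loss) is the default;
  layer widths are not published and default to a geometric taper
  from the input dimension to the output count.  Depth, widths, loss
  and optimizer settings are all configurable because very deep plain
  MLPs are fragile.

Both heads standardize nothing (RF) or standardize internally with
statistics fit on the training data only (FFNN), are deterministic
given their seed, and expose ``predict`` / ``predict_scores`` through
a common :class:`TrainedModel` wrapper that can be serialized.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

from .matrix import FeatureMatrix

__all__ = [
    "RFConfig",
    "FFNNConfig",
    "TrainedModel",
    "train_rf",
    "train_ffnn",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RFConfig:
    """Random-forest head configuration (defaults: 100 trees, sqrt(p))."""

    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class FFNNConfig:
    """Feed-forward head configuration.

    ``hidden_layers`` hidden rectifier layers whose widths taper
    geometrically from the input dimension to ``output_neurons``
    unless ``widths`` overrides them.  ``loss='mse'`` trains on
    one-hot targets with mean squared error; ``loss='cross_entropy'``
    is available as a conventional alternative.
    """

    hidden_layers: int = 15
    widths: tuple[int, ...] | None = None
    output_neurons: int = 8
    loss: str = "mse"
    epochs: int = 800
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if self.output_neurons < 2:
            raise ValueError("output_neurons must be >= 2")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError("loss must be 'mse' or 'cross_entropy'")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 1 and learning_rate positive")


@dataclass
class TrainedModel:
    """Opaque predictor with training metadata.

    ``predict`` returns integer class labels; ``predict_scores`` an
    ``(n, K)`` score matrix whose row-wise argmax equals ``predict``.
    """

    kind: str
    estimator: object
    classes: np.ndarray
    n_features: int
    config: object
    seed: int
    loss_trace: list[float] = field(default_factory=list)
    scaler: StandardScaler | None = None

    def _prep(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        if Xv.ndim != 2 or (Xv.shape[0] > 0 and Xv.shape[1] != self.n_features):
            raise ValueError(
                f"expected (n, {self.n_features}) features, got {Xv.shape}"
            )
        if self.scaler is not None and Xv.shape[0] > 0:
            Xv = self.scaler.transform(Xv)
        return Xv

    def predict_scores(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        Xv = self._prep(X)
        K = len(self.classes)
        if Xv.shape[0] == 0:
            return np.zeros((0, K))
        if self.kind == "rf":
            scores = self.estimator.predict_proba(Xv)
        elif isinstance(self.estimator, MLPRegressor):
            raw = self.estimator.predict(Xv)
            scores = raw.reshape(Xv.shape[0], K)
        else:
            scores = self.estimator.predict_proba(Xv)
        if not np.all(np.isfinite(scores)):
            raise FloatingPointError("model produced non-finite scores")
        return scores

    def predict(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        if scores.shape[0] == 0:
            return np.zeros(0, dtype=self.classes.dtype)
        return self.classes[np.argmax(scores, axis=1)]


def _check_training_input(
    X: FeatureMatrix | np.ndarray, y: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    yv = np.asarray(y)
    if Xv.ndim != 2 or Xv.shape[0] != yv.shape[0]:
        raise ValueError("X must be (n, p) with one label per row")
    if not np.all(np.isfinite(Xv)):
        raise ValueError("training features contain non-finite values")
    if Xv.shape[0] < 1:
        raise ValueError("cannot train on an empty dataset")
    return Xv, yv


def train_rf(
    X: FeatureMatrix | np.ndarray, y: Sequence[int], config: RFConfig | None = None
) -> TrainedModel:
    """Train the bagged-tree head; prediction is a majority vote."""
    config = config or RFConfig()
    Xv, yv = _check_training_input(X, y)
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(Xv, yv)
    return TrainedModel(
        kind="rf",
        estimator=est,
        classes=est.classes_,
        n_features=Xv.shape[1],
        config=config,
        seed=config.seed,
    )


def _taper_widths(p: int, config: FFNNConfig) -> tuple[int, ...]:
    if config.widths is not None:
        return tuple(int(w) for w in config.widths)
    L = config.hidden_layers
    lo = max(config.output_neurons, 2)
    # Very deep, very narrow rectifier stacks collapse (dead units), so
    # the taper starts at no less than 128 and no layer drops below 16.
    hi = max(p, 128, lo + 1)
    widths = np.geomspace(hi, lo, L + 2)[1:-1]
    return tuple(int(max(round(w), lo, 16)) for w in widths)


def train_ffnn(
    X: FeatureMatrix | np.ndarray, y: Sequence[int], config: FFNNConfig | None = None
) -> TrainedModel:
    """Train the feed-forward head on standardized features.

    With ``loss='mse'`` the network is a multi-output regressor fit to
    one-hot targets (scores are the raw outputs); with
    ``loss='cross_entropy'`` it is an ordinary softmax classifier.
    The per-epoch loss trace is recorded.
    """
    config = config or FFNNConfig()
    Xv, yv = _check_training_input(X, y)
    classes = np.unique(yv)
    scaler = StandardScaler().fit(Xv)
    Xs = scaler.transform(Xv)
    widths = _taper_widths(Xv.shape[1], config)
    common = dict(
        hidden_layer_sizes=widths,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        batch_size=min(config.batch_size, Xv.shape[0]),
        random_state=config.seed,
        early_stopping=False,
        n_iter_no_change=config.epochs,  # run the full schedule
        tol=0.0,
    )
    if config.loss == "mse":
        onehot = np.zeros((Xv.shape[0], len(classes)))
        onehot[np.arange(Xv.shape[0]), np.searchsorted(classes, yv)] = 1.0
        est = MLPRegressor(**common)
        est.fit(Xs, onehot)
    else:
        est = MLPClassifier(**common)
        est.fit(Xs, yv)
    trace = [float(v) for v in getattr(est, "loss_curve_", [])]
    if trace and not np.isfinite(trace[-1]):
        bad = next(i for i, v in enumerate(trace) if not np.isfinite(v))
        raise FloatingPointError(f"training loss diverged at epoch {bad}")
    return TrainedModel(
        kind="ffnn",
        estimator=est,
        classes=classes,
        n_features=Xv.shape[1],
        config=config,
        seed=config.seed,
        loss_trace=trace,
        scaler=scaler,
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained head with its config and seed embedded."""
    payload = {"format_version": _FORMAT_VERSION, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version in {path}")
    return payload["model"]
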