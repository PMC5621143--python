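"""Single-hidden-layer autoencoder novelty detector.

The network maps the 4 input features through a sigmoidal hidden layer
(default 8 units) back to 4 linear outputs and is trained to reproduce
target-class vectors (an identity operation).  With one hidden layer the
solution is closely related to a principal-component description of the
targets.  Novelty is scored by the squared reconstruction error
||x - decode(encode(x))||^2, thresholded by the shared fraction rule so a
configured share of training targets (default 95%) is accepted.

The output layer is linear: features are standardized upstream, and a
sigmoid output could never reach standardized values outside (0, 1).
Training is plain full-batch gradient descent on the mean squared
reconstruction error — deliberately simple, deterministic given the seed,
and verifiable by finite differences.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from ocweed.errors import (
    ConfigurationError, InputError, StateError, TrainingError,
)
from ocweed.features import FeatureTable, Standardization
from ocweed.oc_som import fraction_threshold
from ocweed.scene_sim import OTHER, TARGET


@dataclasses.dataclass
class AeConfig:
    hidden_units: int = 8
    epochs: int = 2000
    learning_rate: float = 0.1
    batch_size: Optional[int] = None  # None = full batch
    fraction_targets: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not 0.0 < self.fraction_targets < 1.0:
            raise ConfigurationError("fraction_targets must lie in (0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclasses.dataclass
class AeModel:
    """Encoder/decoder weights plus the calibrated error threshold."""

    w_enc: np.ndarray  # (d, h)
    b_enc: np.ndarray  # (h,)
    w_dec: np.ndarray  # (h, d)
    b_dec: np.ndarray  # (d,)
    threshold: Optional[float] = None
    fraction_targets: float = 0.95
    loss_trace: Optional[list] = None
    standardization: Optional[Standardization] = None

    def to_dict(self) -> dict:
        return {
            "w_enc": self.w_enc.tolist(), "b_enc": self.b_enc.tolist(),
            "w_dec": self.w_dec.tolist(), "b_dec": self.b_dec.tolist(),
            "threshold": self.threshold,
            "fraction_targets": self.fraction_targets,
            "loss_trace": self.loss_trace,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AeModel":
        d = dict(d)
        for k in ("w_enc", "b_enc", "w_dec", "b_dec"):
            d[k] = np.asarray(d[k], dtype=np.float64)
        return cls(**d)


def ae_forward(model: AeModel, x: np.ndarray) -> np.ndarray:
    """decoder(sigmoid(encoder(x))); accepts a vector or an (N, d) matrix."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.w_enc.shape[0]:
        raise InputError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.w_enc.shape[0]})"
        )
    H = _sigmoid(X @ model.w_enc + model.b_enc)
    Y = H @ model.w_dec + model.b_dec
    return Y[0] if single else Y


def ae_gradients(model: AeModel, X: np.ndarray) -> dict:
    """Analytic gradients of the mean squared reconstruction error.

    Loss = mean over rows of ||y - x||^2.  Used by training and by the
    finite-difference correctness tests.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    H = _sigmoid(X @ model.w_enc + model.b_enc)
    Y = H @ model.w_dec + model.b_dec
    dY = 2.0 * (Y - X) / n
    g = {
        "w_dec": H.T @ dY,
        "b_dec": dY.sum(axis=0),
    }
    dH = dY @ model.w_dec.T
    dZ = dH * H * (1.0 - H)
    g["w_enc"] = X.T @ dZ
    g["b_enc"] = dZ.sum(axis=0)
    return g


def ae_loss(model: AeModel, X: np.ndarray) -> float:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = ae_forward(model, X)
    return float(np.mean(np.sum((Y - X) ** 2, axis=1)))


def init_ae(n_features: int, config: AeConfig) -> AeModel:
    """Seeded uniform init in [-0.5, 0.5] scaled by 1/sqrt(fan_in)."""
    rng = np.random.default_rng(config.seed)
    h = config.hidden_units
    return AeModel(
        w_enc=rng.uniform(-0.5, 0.5, (n_features, h)) / np.sqrt(n_features),
        b_enc=np.zeros(h),
        w_dec=rng.uniform(-0.5, 0.5, (h, n_features)) / np.sqrt(h),
        b_dec=np.zeros(n_features),
        fraction_targets=config.fraction_targets,
    )


def fit_ae(train_targets: FeatureTable, config: AeConfig = None) -> AeModel:
    """Gradient-descent training on target rows; threshold auto-calibrated."""
    config = config or AeConfig()
    X = np.asarray(train_targets.values, dtype=np.float64)
    if X.shape[0] < 2:
        raise InputError("autoencoder training needs at least 2 rows")
    model = init_ae(X.shape[1], config)
    model.standardization = train_targets.standardization
    rng = np.random.default_rng(config.seed + 1)
    trace = [ae_loss(model, X)]
    for _ in range(config.epochs):
        if config.batch_size is None:
            batches = [X]
        else:
            order = rng.permutation(X.shape[0])
            batches = [
                X[order[lo:lo + config.batch_size]]
                for lo in range(0, X.shape[0], config.batch_size)
            ]
        for B in batches:
            g = ae_gradients(model, B)
            model.w_enc -= config.learning_rate * g["w_enc"]
            model.b_enc -= config.learning_rate * g["b_enc"]
            model.w_dec -= config.learning_rate * g["w_dec"]
            model.b_dec -= config.learning_rate * g["b_dec"]
        loss = ae_loss(model, X)
        if not np.isfinite(loss):
            raise TrainingError(
                "autoencoder training diverged (loss is not finite); "
                "try a smaller learning_rate"
            )
        trace.append(loss)
    model.loss_trace = trace
    errors = ae_score(model, X)
    model.threshold = fraction_threshold(errors, config.fraction_targets)
    return model


def ae_score(model: AeModel, x: np.ndarray) -> np.ndarray | float:
    """Squared reconstruction error ||x - ae_forward(x)||^2."""
    if model is None or model.w_enc is None:
        raise StateError("autoencoder model is not fitted")
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    err = np.sum((X - ae_forward(model, X)) ** 2, axis=1)
    return float(err[0]) if single else err


def classify_ae(model: AeModel, table: FeatureTable) -> np.ndarray:
    """Label rows: 2 (novel) where reconstruction error > threshold, else 1."""
    if model.threshold is None:
        raise StateError("autoencoder threshold is not calibrated")
    s = ae_score(model, table.values)
    return np.where(s > model.threshold, OTHER, TARGET).astype(np.uint8)
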