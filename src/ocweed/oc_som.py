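"""One-class self-organizing map (OC-SOM).

A Kohonen map (default 8 x 8, rectangular) is trained on target-class
feature vectors only.  The novelty score of a point x is its quantization
error: the squared Euclidean distance to the best matching unit (BMU),

    score(x) = min_i sum_j (x_j - m_ij)^2 ,   i over the grid.

The decision threshold d is placed at an order-statistic midpoint of the
training scores so that a configured fraction of targets (default 95%)
falls inside:

    sorted = sort(distances); k = round(fraction * N)
    d = (sorted[k] + sorted[k + 1]) / 2        (1-based indices)

A point is declared novel (other vegetation) when its quantization error is
strictly greater than d; the threshold point itself is a target.  The same
fraction-threshold rule is shared by every detector in this package.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np

from ocweed.errors import ConfigurationError, InputError, ParameterError, StateError
from ocweed.features import FeatureTable, Standardization
from ocweed.scene_sim import OTHER, TARGET


def fraction_threshold(distances: Sequence[float], fraction: float) -> float:
    """Order-statistic midpoint threshold over a sample of novelty scores.

    With 1-based order statistics s(1) <= ... <= s(n) and
    k = round(fraction * n), returns (s(k) + s(k+1)) / 2.
    """
    d = np.sort(np.asarray(distances, dtype=np.float64))
    n = d.size
    if n < 2:
        raise ParameterError("fraction threshold needs at least 2 distances")
    k = int(np.floor(fraction * n + 0.5))  # round half-up
    if not 1 <= k < n:
        raise ParameterError(
            f"fraction {fraction} is degenerate for sample size {n} (k = {k})"
        )
    return float(0.5 * (d[k - 1] + d[k]))


@dataclasses.dataclass
class SomConfig:
    """OC-SOM hyperparameters.

    The grid is rectangular (default 8 x 8).  Training is online Kohonen
    learning with a Gaussian neighbourhood whose radius decays exponentially
    from ``radius_initial`` (default max(rows, cols) / 2) to ``radius_final``
    while the learning rate decays from ``lr_initial`` to ``lr_final``.
    """

    rows: int = 8
    cols: int = 8
    epochs: int = 20
    radius_initial: Optional[float] = None
    radius_final: float = 0.5
    lr_initial: float = 0.5
    lr_final: float = 0.01
    fraction_targets: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("SOM grid dimensions must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not 0.0 < self.fraction_targets < 1.0:
            raise ConfigurationError("fraction_targets must lie in (0, 1)")
        if self.radius_initial is None:
            self.radius_initial = max(self.rows, self.cols) / 2.0


@dataclasses.dataclass
class SomModel:
    """Trained codebook grid plus (optionally) the calibrated threshold."""

    codebooks: np.ndarray  # (rows*cols, d)
    grid: np.ndarray  # (rows*cols, 2) unit coordinates
    rows: int
    cols: int
    threshold: Optional[float] = None
    fraction_targets: float = 0.95
    qe_trace: Optional[list] = None  # mean quantization error per epoch
    standardization: Optional[Standardization] = None

    def to_dict(self) -> dict:
        return {
            "codebooks": self.codebooks.tolist(),
            "grid": self.grid.tolist(),
            "rows": self.rows, "cols": self.cols,
            "threshold": self.threshold,
            "fraction_targets": self.fraction_targets,
            "qe_trace": self.qe_trace,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SomModel":
        d = dict(d)
        d["codebooks"] = np.asarray(d["codebooks"], dtype=np.float64)
        d["grid"] = np.asarray(d["grid"], dtype=np.float64)
        return cls(**d)


def bmu_distance(model: SomModel, x: np.ndarray) -> tuple[int, float]:
    """Best matching unit of x: (unit index, squared distance).

    Ties are broken by the lowest unit index.
    """
    if model.codebooks is None or model.codebooks.size == 0:
        raise StateError("SOM model has no codebooks")
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.codebooks.shape[1],):
        raise InputError(
            f"feature dimension {x.shape} does not match codebooks "
            f"({model.codebooks.shape[1]},)"
        )
    d = np.sum((model.codebooks - x) ** 2, axis=1)
    i = int(np.argmin(d))  # argmin returns the first minimum: lowest index
    return i, float(d[i])


def quantization_errors(model: SomModel, X: np.ndarray) -> np.ndarray:
    """Vectorised BMU squared distances for an (N, d) matrix (chunked)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.codebooks.shape[1]:
        raise InputError("feature dimension does not match codebooks")
    out = np.empty(X.shape[0])
    cb = model.codebooks
    cb_sq = np.sum(cb**2, axis=1)
    chunk = max(1, int(4e6 // max(cb.shape[0], 1)))
    for lo in range(0, X.shape[0], chunk):
        xc = X[lo:lo + chunk]
        d = np.sum(xc**2, axis=1)[:, None] + cb_sq[None, :] - 2.0 * xc @ cb.T
        out[lo:lo + chunk] = np.maximum(d.min(axis=1), 0.0)
    return out


def train_som(train_targets: FeatureTable, config: SomConfig = None) -> SomModel:
    """Online Kohonen training on target-class rows; threshold left unset.

    Codebooks are initialised from a seeded random sample of the training
    points.  The neighbourhood is Gaussian on the rectangular grid.
    """
    config = config or SomConfig()
    X = np.asarray(train_targets.values, dtype=np.float64)
    n, d = X.shape
    n_units = config.rows * config.cols
    if n < n_units:
        warnings.warn(
            f"training set ({n}) smaller than SOM grid ({n_units}); "
            "codebooks are sampled with replacement", stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(n, size=n_units, replace=n < n_units)
    codebooks = X[init_idx].copy()
    rr, cc = np.meshgrid(np.arange(config.rows), np.arange(config.cols),
                         indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    # pairwise squared grid distances between units
    grid_sq = (
        np.sum(grid**2, axis=1)[:, None]
        + np.sum(grid**2, axis=1)[None, :]
        - 2.0 * grid @ grid.T
    )

    total = config.epochs * n
    r0, rf = config.radius_initial, config.radius_final
    l0, lf = config.lr_initial, config.lr_final
    qe_trace = []
    model = SomModel(codebooks=codebooks, grid=grid,
                     rows=config.rows, cols=config.cols,
                     fraction_targets=config.fraction_targets,
                     standardization=train_targets.standardization)
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total - 1, 1)
            radius = r0 * (rf / r0) ** frac
            lr = l0 * (lf / l0) ** frac
            x = X[i]
            dists = np.sum((codebooks - x) ** 2, axis=1)
            bmu = int(np.argmin(dists))
            h = lr * np.exp(-grid_sq[bmu] / (2.0 * radius * radius))
            codebooks += h[:, None] * (x - codebooks)
            step += 1
        qe_trace.append(float(quantization_errors(model, X).mean()))
    model.qe_trace = qe_trace
    return model


def calibrate_som(model: SomModel, train_targets: FeatureTable) -> SomModel:
    """Set the novelty threshold from training quantization errors."""
    dists = quantization_errors(model, train_targets.values)
    model.threshold = fraction_threshold(dists, model.fraction_targets)
    return model


def classify_som(model: SomModel, table: FeatureTable) -> np.ndarray:
    """Label rows: 2 (novel/other) where quantization error > d, else 1."""
    if model.threshold is None:
        raise StateError("SOM threshold is not calibrated")
    qe = quantization_errors(model, table.values)
    return np.where(qe > model.threshold, OTHER, TARGET).astype(np.uint8)


def calibrate_and_classify_som(
    model: SomModel, train_targets: FeatureTable, table: FeatureTable
) -> np.ndarray:
    """Calibrate the threshold on training targets, then classify ``table``."""
    calibrate_som(model, train_targets)
    return classify_som(model, table)
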