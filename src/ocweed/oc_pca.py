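"""One-class PCA novelty detector.

The orthonormal principal subspace W (d x M) of the target class is obtained
by eigendecomposition of the covariance matrix of (centred) target training
data; M is either given explicitly or chosen as the smallest count whose
cumulative eigenvalue share reaches a user-defined variance fraction.
Novelty is scored by the squared reconstruction distance

    d_PCA(z) = ||z - W (W'W)^-1 W' z||^2 = ||z - W W' z||^2

(the simplification holds because W is orthonormal), computed after
subtracting the training mean.  The decision threshold is placed by the
shared fraction rule so a configured share of training targets is rejected
(default outlier fraction 10%).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np

from ocweed.errors import ConfigurationError, InputError, StateError
from ocweed.features import FeatureTable, Standardization
from ocweed.oc_som import fraction_threshold
from ocweed.scene_sim import OTHER, TARGET


@dataclasses.dataclass
class PcaConfig:
    """Exactly one of ``variance_fraction`` / ``n_components`` selects M."""

    variance_fraction: Optional[float] = None
    n_components: Optional[int] = None
    outlier_fraction: float = 0.10
    center: bool = True

    def __post_init__(self):
        if self.variance_fraction is not None and self.n_components is not None:
            raise ConfigurationError(
                "specify either variance_fraction or n_components, not both"
            )
        if self.variance_fraction is None and self.n_components is None:
            self.variance_fraction = 0.95
        if self.variance_fraction is not None and not 0.0 < self.variance_fraction <= 1.0:
            raise ConfigurationError("variance_fraction must lie in (0, 1]")
        if self.n_components is not None and self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if not 0.0 < self.outlier_fraction < 1.0:
            raise ConfigurationError("outlier_fraction must lie in (0, 1)")


@dataclasses.dataclass
class PcaModel:
    """Principal subspace of the target class plus the error threshold."""

    mean: np.ndarray  # (d,); zeros when centring is off
    basis: np.ndarray  # (d, M), orthonormal columns
    eigenvalues: np.ndarray  # all d, descending
    threshold: Optional[float] = None
    outlier_fraction: float = 0.10
    n_free_parameters: Optional[int] = None  # d * M, informational
    standardization: Optional[Standardization] = None

    @property
    def n_components(self) -> int:
        return int(self.basis.shape[1])

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "basis": self.basis.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "threshold": self.threshold,
            "outlier_fraction": self.outlier_fraction,
            "n_free_parameters": self.n_free_parameters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        d = dict(d)
        for k in ("mean", "basis", "eigenvalues"):
            d[k] = np.asarray(d[k], dtype=np.float64)
        return cls(**d)


def fit_pca(train_targets: FeatureTable, config: PcaConfig = None) -> PcaModel:
    """Principal-subspace fit on target rows; threshold auto-calibrated."""
    config = config or PcaConfig()
    X = np.asarray(train_targets.values, dtype=np.float64)
    n, d = X.shape
    if n <= d:
        raise InputError(f"PCA needs more rows ({n}) than features ({d})")
    mean = X.mean(axis=0) if config.center else np.zeros(d)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    if not np.all(np.isfinite(cov)):
        raise InputError("covariance is not finite")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]

    total = evals.sum()
    rank = int(np.sum(evals > max(total, 1.0) * 1e-12))
    if config.n_components is not None:
        m = min(config.n_components, d)
    else:
        if config.variance_fraction >= 1.0 - 1e-12:
            m = d  # full basis requested; capped at rank below
        else:
            share = np.cumsum(evals) / total if total > 0 else np.ones(d)
            m = int(np.searchsorted(share, config.variance_fraction - 1e-12) + 1)
            m = min(m, d)
        if m > rank:
            warnings.warn(
                f"covariance rank {rank} < requested components {m}; capping",
                stacklevel=2,
            )
            m = max(rank, 1)

    model = PcaModel(
        mean=mean,
        basis=evecs[:, :m],
        eigenvalues=evals,
        outlier_fraction=config.outlier_fraction,
        n_free_parameters=d * m,
        standardization=train_targets.standardization,
    )
    errors = pca_reconstruction_error(model, X)
    model.threshold = fraction_threshold(errors, 1.0 - config.outlier_fraction)
    return model


def pca_reconstruction_error(model: PcaModel, z: np.ndarray) -> np.ndarray | float:
    """Squared off-subspace distance ||(z - mean) - W W'(z - mean)||^2."""
    if model is None or model.basis is None:
        raise StateError("PCA model is not fitted")
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    if Z.shape[1] != model.basis.shape[0]:
        raise InputError(
            f"feature dimension {Z.shape[1]} does not match model "
            f"({model.basis.shape[0]})"
        )
    Z = Z - model.mean
    resid = Z - (Z @ model.basis) @ model.basis.T
    err = np.maximum(np.sum(resid**2, axis=1), 0.0)
    return float(err[0]) if single else err


def classify_pca(model: PcaModel, table: FeatureTable) -> np.ndarray:
    """Label rows: 2 (novel) where reconstruction error > threshold, else 1."""
    if model.threshold is None:
        raise StateError("PCA threshold is not calibrated")
    e = pca_reconstruction_error(model, table.values)
    return np.where(e > model.threshold, OTHER, TARGET).astype(np.uint8)
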