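"""One-class SVM via Support Vector Data Description (SVDD).

SVDD encloses the target class in the smallest supersphere in RBF feature
space, with centre a = sum_i alpha_i phi(x_i) and radius R.  The primal

    min  R^2 + C sum_i xi_i   s.t.  ||phi(x_i) - a||^2 <= R^2 + xi_i

with C = 1 / (N nu) leads to the dual

    max  sum_i alpha_i K(x_i, x_i) - sum_ij alpha_i alpha_j K(x_i, x_j)
    s.t. sum_i alpha_i = 1,  0 <= alpha_i <= C

which for the RBF kernel K(x, z) = exp(-||x - z||^2 / sigma^2) reduces to
minimising alpha' K alpha over the capped simplex.  The solver is
Nesterov-accelerated projected gradient; the projection onto
{sum = 1, 0 <= alpha <= C} is computed by bisection on the shift.

A point v is a target when its kernel-space distance to the centre,
K(v,v) - 2 sum_i alpha_i K(x_i, v) + sum_ij alpha_i alpha_j K(x_i, x_j),
does not exceed R^2 (the boundary itself is inside).  R^2 is calibrated as
the order-statistic midpoint of the training distances at fraction 1 - nu,
so the training rejection rate equals nu exactly up to rounding; the
boundary-support-vector radius is recorded alongside for reference.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from ocweed.errors import ConfigurationError, InputError, StateError, TrainingError
from ocweed.features import FeatureTable, Standardization
from ocweed.oc_som import fraction_threshold
from ocweed.scene_sim import OTHER, TARGET


@dataclasses.dataclass
class SvddConfig:
    """SVDD hyperparameters: RBF spread sigma (default 2.5 on standardized
    features) and expected outlier fraction nu (default 0.05)."""

    sigma: float = 2.5
    nu: float = 0.05
    tolerance: float = 1e-8
    max_iterations: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if not 0.0 < self.nu < 1.0:
            raise ConfigurationError("nu must lie strictly between 0 and 1")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")


def rbf_kernel(x: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """K(x, z) = exp(-||x - z||^2 / sigma^2); symmetric, K(x, x) = 1."""
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if x.shape != z.shape:
        raise InputError(f"dimension mismatch: {x.shape} vs {z.shape}")
    if sigma <= 0:
        raise InputError("sigma must be positive")
    return float(np.exp(-np.sum((x - z) ** 2) / sigma**2))


def _kernel_matrix(X: np.ndarray, Z: np.ndarray, sigma: float) -> np.ndarray:
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / sigma**2)


def _project_capped_simplex(y: np.ndarray, cap: float) -> np.ndarray:
    """Euclidean projection onto {a : sum a = 1, 0 <= a <= cap} by bisection."""
    lo = np.min(y) - cap - 1.0
    hi = np.max(y)
    for _ in range(100):
        tau = 0.5 * (lo + hi)
        s = np.clip(y - tau, 0.0, cap).sum()
        if s > 1.0:
            lo = tau
        else:
            hi = tau
    return np.clip(y - 0.5 * (lo + hi), 0.0, cap)


@dataclasses.dataclass
class SvddModel:
    """Fitted SVDD: support expansion of the centre plus decision radius."""

    support_points: np.ndarray
    alphas: np.ndarray
    sigma: float
    C: float
    offset: float  # sum_ij alpha_i alpha_j K(x_i, x_j), cached
    radius_sq: Optional[float] = None  # calibrated decision radius
    boundary_radius_sq: Optional[float] = None  # from boundary SVs, logged
    standardization: Optional[Standardization] = None
    nu: float = 0.05
    n_train: int = 0
    iterations: int = 0
    residual: float = 0.0

    @property
    def n_support(self) -> int:
        return int(self.support_points.shape[0])

    def to_dict(self) -> dict:
        return {
            "support_points": self.support_points.tolist(),
            "alphas": self.alphas.tolist(),
            "sigma": self.sigma, "C": self.C, "offset": self.offset,
            "radius_sq": self.radius_sq,
            "boundary_radius_sq": self.boundary_radius_sq,
            "nu": self.nu, "n_train": self.n_train,
            "iterations": self.iterations, "residual": self.residual,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvddModel":
        d = dict(d)
        d["support_points"] = np.asarray(d["support_points"], dtype=np.float64)
        d["alphas"] = np.asarray(d["alphas"], dtype=np.float64)
        return cls(**d)


def solve_svdd_dual(K: np.ndarray, C: float, tolerance: float = 1e-8,
                    max_iterations: int = 20000) -> tuple[np.ndarray, int, float]:
    """Minimise alpha' K alpha over the capped simplex (FISTA).

    Returns (alpha, iterations, kkt_residual).  The residual is the norm of
    the difference between alpha and its projected-gradient update at unit
    relative step, so 0 at exact optimality.
    """
    n = K.shape[0]
    if C * n < 1.0:
        raise ConfigurationError(
            f"infeasible constraints: C*N = {C * n:.4g} < 1 (nu too large for N)"
        )
    alpha = np.full(n, 1.0 / n)
    # Lipschitz constant of the gradient 2 K alpha.
    if n == 1:
        return np.array([1.0]), 0, 0.0
    lam = np.linalg.eigvalsh(K)[-1] if n <= 512 else _power_iteration(K)
    step = 1.0 / max(2.0 * lam, 1e-12)
    y = alpha.copy()
    t = 1.0
    residual = np.inf
    for it in range(1, max_iterations + 1):
        grad = 2.0 * (K @ y)
        alpha_new = _project_capped_simplex(y - step * grad, C)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = alpha_new + ((t - 1.0) / t_new) * (alpha_new - alpha)
        # monotone restart keeps FISTA stable on this quadratic
        if (alpha_new - alpha) @ (2.0 * (K @ alpha_new)) > 0 and it % 50 == 0:
            y = alpha_new
            t_new = 1.0
        alpha, t = alpha_new, t_new
        if it % 10 == 0 or it == max_iterations:
            g = 2.0 * (K @ alpha)
            residual = float(
                np.linalg.norm(alpha - _project_capped_simplex(alpha - step * g, C))
            ) / step
            if residual < tolerance * max(1.0, float(np.abs(g).max())):
                return alpha, it, residual
    raise TrainingError(
        f"SVDD dual did not converge in {max_iterations} iterations "
        f"(KKT residual {residual:.3g})"
    )


def _power_iteration(K: np.ndarray, iters: int = 100) -> float:
    v = np.ones(K.shape[0]) / np.sqrt(K.shape[0])
    lam = 1.0
    for _ in range(iters):
        w = K @ v
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 1.0
        v = w / lam
    return lam


def fit_svdd(train_targets: FeatureTable, config: SvddConfig = None) -> SvddModel:
    """Fit SVDD on target-class training rows (standardized features)."""
    config = config or SvddConfig()
    X = np.asarray(train_targets.values, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise InputError("SVDD requires at least 2 training points")
    C = 1.0 / (n * config.nu)
    K = _kernel_matrix(X, X, config.sigma)
    alpha, iters, residual = solve_svdd_dual(
        K, C, tolerance=config.tolerance, max_iterations=config.max_iterations
    )
    offset = float(alpha @ K @ alpha)
    support = alpha > 1e-4 * C
    model = SvddModel(
        support_points=X[support],
        alphas=alpha[support],
        sigma=config.sigma,
        C=C,
        offset=offset,
        standardization=train_targets.standardization,
        nu=config.nu,
        n_train=n,
        iterations=iters,
        residual=residual,
    )
    dists = svdd_distance_sq(model, X)
    # Boundary-SV radius: distance of unbounded support vectors (0 < a < C).
    on_boundary = support & (alpha < C * (1.0 - 1e-6))
    if on_boundary.any():
        model.boundary_radius_sq = float(np.median(dists[on_boundary]))
    else:
        model.boundary_radius_sq = float(dists[support].max()) if support.any() else 0.0
    model.radius_sq = fraction_threshold(dists, 1.0 - config.nu)
    return model


def svdd_distance_sq(model: SvddModel, v: np.ndarray) -> np.ndarray | float:
    """Kernel-space squared distance of v to the SVDD centre.

    Accepts a single feature vector or an (N, d) matrix; large matrices are
    processed in chunks so whole-mosaic scoring stays within modest memory.
    """
    if model is None or model.alphas is None or model.alphas.size == 0:
        raise StateError("SVDD model is not fitted")
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1
    V = np.atleast_2d(v)
    if V.shape[1] != model.support_points.shape[1]:
        raise InputError(
            f"feature dimension {V.shape[1]} does not match model "
            f"({model.support_points.shape[1]})"
        )
    out = np.empty(V.shape[0])
    chunk = max(1, int(4e6 // max(model.n_support, 1)))
    for lo in range(0, V.shape[0], chunk):
        Kc = _kernel_matrix(V[lo:lo + chunk], model.support_points, model.sigma)
        out[lo:lo + chunk] = 1.0 - 2.0 * (Kc @ model.alphas) + model.offset
    np.maximum(out, 0.0, out=out)  # clip rounding below 0
    return float(out[0]) if single else out


def classify_svdd(model: SvddModel, table: FeatureTable) -> np.ndarray:
    """Label rows: 1 (target) where distance^2 <= R^2, else 2 (other)."""
    if model.radius_sq is None:
        raise StateError("SVDD radius is not calibrated")
    if model.standardization is not None:
        if table.standardization is None or (
            table.standardization.digest() != model.standardization.digest()
        ):
            raise InputError(
                "feature table was not standardized with the model's training map"
            )
    d = svdd_distance_sq(model, table.values)
    return np.where(d <= model.radius_sq, TARGET, OTHER).astype(np.uint8)
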