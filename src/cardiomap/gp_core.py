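"""Gaussian-process surrogate: kernels, posterior inference, evidence, entropy.

The voltage map over the endocardium (or a 2D benchmark grid) is modelled as a
zero-mean Gaussian process.  Conditioning on the mapped points A = (X, y) gives
the predictive distribution at query points X*:

    mu*    = K(X*, X) [K(X, X) + sigma^2 I]^{-1} y
    Sigma* = K(X*, X*) - K(X*, X) [K(X, X) + sigma^2 I]^{-1} K(X, X*)

Everything downstream (the entropy acquisition, the particle filter, the
benchmark regression) queries this module.  Linear systems are solved by
Cholesky factorization with an adaptive jitter rather than an explicit
inverse.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("cardiomap.gp")

KERNEL_FAMILIES = ("linear", "squared_exponential", "matern", "rational_quadratic")

#: Matern smoothness values with closed-form kernels.
MATERN_NU_VALUES = (0.5, 1.5, 2.5)

#: Adaptive jitter ladder for Cholesky factorizations.
JITTER_START = 1e-10
JITTER_MAX = 1e-4

LOG_2PIE = math.log(2.0 * math.pi * math.e)


class IllConditionedError(np.linalg.LinAlgError):
    """Gram matrix could not be factorized even at the maximum jitter."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus hyperparameters theta and observation noise.

    Parameters
    ----------
    family:
        One of ``linear``, ``squared_exponential``, ``matern``,
        ``rational_quadratic``.
    length_scale:
        Isotropic length scale ``l`` in coordinate units (for the linear
        kernel it scales the inner product).
    signal_variance:
        Prior marginal variance ``sigma_f^2`` in squared value units.
    noise_variance:
        Observation noise ``sigma^2`` (>= 0).
    nu:
        Matern smoothness; only 1/2, 3/2, 5/2 are supported (closed forms).
    alpha:
        Rational-quadratic mixture parameter.
    """

    family: str
    length_scale: float
    signal_variance: float
    noise_variance: float = 0.0
    nu: float = 2.5
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; "
                             f"expected one of {KERNEL_FAMILIES}")
        if not (self.length_scale > 0 and np.isfinite(self.length_scale)):
            raise ValueError(f"length_scale must be positive, got {self.length_scale}")
        if not (self.signal_variance > 0 and np.isfinite(self.signal_variance)):
            raise ValueError(f"signal_variance must be positive, got {self.signal_variance}")
        if not (self.noise_variance >= 0 and np.isfinite(self.noise_variance)):
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")
        if self.family == "matern" and not any(
            math.isclose(self.nu, v) for v in MATERN_NU_VALUES
        ):
            raise ValueError(f"matern nu must be one of {MATERN_NU_VALUES}, got {self.nu}")
        if self.family == "rational_quadratic" and not self.alpha > 0:
            raise ValueError(f"rational_quadratic alpha must be positive, got {self.alpha}")

    @property
    def is_stationary(self) -> bool:
        return self.family != "linear"

    def replace(self, **kwargs) -> "KernelSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


@dataclass
class ObservationSet:
    """The mapped set A: positions X (n x d) paired with values y (n,)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.size == 0:
            self.X = self.X.reshape(0, self.X.shape[1] if self.X.ndim == 2 and self.X.shape[1] else 2)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"positions and values disagree: {self.X.shape[0]} rows vs {self.y.shape[0]} values"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def append(self, x: np.ndarray, value: float) -> "ObservationSet":
        x = np.asarray(x, dtype=float).reshape(1, -1)
        if self.n == 0:
            return ObservationSet(x, np.array([value]))
        return ObservationSet(np.vstack([self.X, x]), np.append(self.y, value))

    @classmethod
    def empty(cls, dim: int = 2) -> "ObservationSet":
        return cls(np.empty((0, dim)), np.empty(0))


@dataclass
class GPPosterior:
    """Gaussian predictive distribution at the query points."""

    mean: np.ndarray
    cov: np.ndarray
    query_indices: np.ndarray | None = None

    @property
    def variance(self) -> np.ndarray:
        return np.diag(self.cov)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(self.variance, 0.0, None))


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def kernel_from_r(spec: KernelSpec, r: np.ndarray) -> np.ndarray:
    """Stationary kernel value at distance ``r`` (elementwise).

    Only valid for stationary families; raises for the linear kernel.
    """
    if not spec.is_stationary:
        raise ValueError("linear kernel is not stationary; use kernel_eval")
    r = np.asarray(r, dtype=float)
    l = spec.length_scale
    sf2 = spec.signal_variance
    if spec.family == "squared_exponential":
        return sf2 * np.exp(-0.5 * (r / l) ** 2)
    if spec.family == "matern":
        if math.isclose(spec.nu, 0.5):
            return sf2 * np.exp(-r / l)
        if math.isclose(spec.nu, 1.5):
            a = math.sqrt(3.0) * r / l
            return sf2 * (1.0 + a) * np.exp(-a)
        a = math.sqrt(5.0) * r / l
        return sf2 * (1.0 + a + a * a / 3.0) * np.exp(-a)
    # rational quadratic
    al = spec.alpha
    return sf2 * (1.0 + r * r / (2.0 * al * l * l)) ** (-al)


def kernel_eval(spec: KernelSpec, A_pts: np.ndarray, B_pts: np.ndarray) -> np.ndarray:
    """Cross-covariance matrix K(A, B) under ``spec`` (noise-free)."""
    A_pts = np.atleast_2d(np.asarray(A_pts, dtype=float))
    B_pts = np.atleast_2d(np.asarray(B_pts, dtype=float))
    if A_pts.shape[1] != B_pts.shape[1]:
        raise ValueError(
            f"point dimensionality mismatch: {A_pts.shape[1]} vs {B_pts.shape[1]}"
        )
    if spec.family == "linear":
        # sigma_f^2 (1 + x.x'/l^2): the constant offset lets the GP carry an
        # intercept, so exactly-affine fields are representable.
        return spec.signal_variance * (1.0 + A_pts @ B_pts.T / spec.length_scale**2)
    if A_pts is B_pts or (A_pts.shape == B_pts.shape and np.array_equal(A_pts, B_pts)):
        r = cdist(A_pts, A_pts)
        K = kernel_from_r(spec, r)
        return 0.5 * (K + K.T)
    return kernel_from_r(spec, cdist(A_pts, B_pts))


# ---------------------------------------------------------------------------
# Linear algebra helpers
# ---------------------------------------------------------------------------

def chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of ``K + jitter*I``, escalating jitter as needed.

    Returns the factor and the jitter actually used.  Raises
    :class:`IllConditionedError` with a condition-number diagnostic if even
    the maximum jitter fails.
    """
    jitter = 0.0
    while True:
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(K.shape[0]) if jitter else K)
            if jitter:
                logger.debug("cholesky needed jitter %.1e", jitter)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = JITTER_START if jitter == 0.0 else jitter * 10.0
            if jitter > JITTER_MAX:
                try:
                    cond = np.linalg.cond(K)
                except np.linalg.LinAlgError:  # pragma: no cover
                    cond = np.inf
                raise IllConditionedError(
                    f"Gram matrix not factorizable at jitter {JITTER_MAX:.0e} "
                    f"(condition number ~{cond:.3e}); duplicate points with "
                    f"zero noise are the usual cause"
                )


def _gram(spec: KernelSpec, X: np.ndarray) -> np.ndarray:
    if spec.noise_variance == 0.0 and X.shape[0] > 1:
        # exact duplicates make the noise-free Gram exactly singular; jitter
        # would silently average the conflicting values instead
        _, counts = np.unique(X.round(decimals=12), axis=0, return_counts=True)
        if counts.max() > 1:
            raise IllConditionedError(
                "duplicate observation points with zero noise variance make "
                "the Gram matrix singular; dedupe the points or set sigma^2 > 0"
            )
    return kernel_eval(spec, X, X) + spec.noise_variance * np.eye(X.shape[0])


# ---------------------------------------------------------------------------
# Posterior, evidence, entropy
# ---------------------------------------------------------------------------

def gp_posterior(
    spec: KernelSpec,
    obs: ObservationSet,
    query_pts: np.ndarray,
    query_indices: np.ndarray | None = None,
) -> GPPosterior:
    """Predictive mean and covariance at ``query_pts`` given the mapped set.

    With no observations this is the prior: zero mean and covariance
    K(X*, X*).  The caller is responsible for centring ``obs.y`` (the model
    assumes a zero prior mean).
    """
    query_pts = np.atleast_2d(np.asarray(query_pts, dtype=float))
    if query_pts.shape[0] == 0:
        raise ValueError("query_pts must be non-empty")
    Kss = kernel_eval(spec, query_pts, query_pts)
    if obs.n == 0:
        return GPPosterior(np.zeros(query_pts.shape[0]), Kss, query_indices)
    if obs.dim != query_pts.shape[1]:
        raise ValueError("observation and query dimensionality mismatch")
    K = _gram(spec, obs.X)
    L, _ = chol_with_jitter(K)
    Ks = kernel_eval(spec, query_pts, obs.X)  # q x n
    A = np.linalg.solve(L, Ks.T)              # n x q
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, obs.y))
    mean = Ks @ alpha
    cov = Kss - A.T @ A
    cov = 0.5 * (cov + cov.T)
    return GPPosterior(mean, cov, query_indices)


def posterior_entropy(cov: np.ndarray | float) -> float:
    """Differential entropy of a Gaussian with covariance ``cov`` (nats).

    H = 1/2 log|Sigma| + D/2 log(2 pi e).  For the sequential planner D = 1
    and ``cov`` is the scalar predictive variance.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        v = float(cov)
        if v < 0:
            raise ValueError(f"variance must be non-negative, got {v}")
        return 0.5 * (math.log(v) if v > 0 else -math.inf) + 0.5 * LOG_2PIE
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be a square matrix or a scalar")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("cov must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    scale = max(1.0, float(w.max(initial=0.0)))
    if w.min(initial=0.0) < -1e-10 * scale:
        raise ValueError(f"cov is not PSD (min eigenvalue {w.min():.3e})")
    w = np.clip(w, 0.0, None)
    D = cov.shape[0]
    with np.errstate(divide="ignore"):
        logdet = float(np.sum(np.log(w)))
    return 0.5 * logdet + 0.5 * D * LOG_2PIE


def scalar_entropy(variance: np.ndarray) -> np.ndarray:
    """Vectorized D=1 entropy, used by the planner on candidate variances."""
    v = np.clip(np.asarray(variance, dtype=float), 1e-300, None)
    return 0.5 * np.log(v) + 0.5 * LOG_2PIE


def log_marginal_likelihood(spec: KernelSpec, obs: ObservationSet) -> float:
    """GP evidence log N(y | 0, K(X,X) + sigma^2 I)."""
    if obs.n < 1:
        raise ValueError("need at least one observation")
    K = _gram(spec, obs.X)
    L, _ = chol_with_jitter(K)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, obs.y))
    return float(
        -0.5 * obs.y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * obs.n * math.log(2 * math.pi)
    )


def one_step_predictive_logpdf(
    spec: KernelSpec, obs: ObservationSet, x_new: np.ndarray, y_new: float
) -> float:
    """Log density of a new observed value under the GP predictive.

    The predictive variance for an *observed* value includes the noise term
    sigma^2 on top of the latent posterior variance.
    """
    x_new = np.asarray(x_new, dtype=float).reshape(1, -1)
    if obs.n == 0:
        mu = 0.0
        v = float(kernel_eval(spec, x_new, x_new)[0, 0]) + spec.noise_variance
    else:
        post = gp_posterior(spec, obs, x_new)
        mu = float(post.mean[0])
        v = max(float(post.cov[0, 0]), 0.0) + spec.noise_variance
    v = max(v, 1e-12)
    return -0.5 * (math.log(2 * math.pi * v) + (y_new - mu) ** 2 / v)


# ---------------------------------------------------------------------------
# Evidence gradients (for hyperparameter fitting)
# ---------------------------------------------------------------------------

def _dK_dlog(spec: KernelSpec, X: np.ndarray, param: str) -> np.ndarray:
    """Derivative of the noisy Gram matrix w.r.t. log(param)."""
    n = X.shape[0]
    l = spec.length_scale
    sf2 = spec.signal_variance
    if param == "noise_variance":
        return spec.noise_variance * np.eye(n)
    if param == "signal_variance":
        return kernel_eval(spec, X, X)
    if spec.family == "linear":
        if param == "length_scale":
            return -2.0 * sf2 * (X @ X.T) / l**2
        raise ValueError(param)
    r = cdist(X, X)
    if param == "length_scale":
        if spec.family == "squared_exponential":
            return kernel_from_r(spec, r) * (r / l) ** 2
        if spec.family == "matern":
            if math.isclose(spec.nu, 0.5):
                return sf2 * np.exp(-r / l) * (r / l)
            if math.isclose(spec.nu, 1.5):
                a = math.sqrt(3.0) * r / l
                return sf2 * a * a * np.exp(-a)
            a = math.sqrt(5.0) * r / l
            return sf2 * (a * a / 3.0) * (1.0 + a) * np.exp(-a)
        # rational quadratic
        al = spec.alpha
        u = 1.0 + r * r / (2.0 * al * l * l)
        return sf2 * u ** (-al - 1.0) * (r * r / l**2)
    if param == "alpha":
        al = spec.alpha
        u = 1.0 + r * r / (2.0 * al * l * l)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(u > 1.0, -np.log(u) + r * r / (2.0 * al * l * l * u), 0.0)
        return sf2 * u ** (-al) * term * al
    raise ValueError(param)


def lml_value_and_grad(
    spec: KernelSpec, obs: ObservationSet, free_params: Sequence[str]
) -> tuple[float, np.ndarray]:
    """Evidence and its gradient w.r.t. the log of each free hyperparameter.

    Uses the standard identity dL/dtheta = 1/2 tr((aa^T - K^{-1}) dK/dtheta)
    with a = K^{-1} y.
    """
    K = _gram(spec, obs.X)
    L, _ = chol_with_jitter(K)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, obs.y))
    lml = float(
        -0.5 * obs.y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * obs.n * math.log(2 * math.pi)
    )
    Kinv = np.linalg.solve(L.T, np.linalg.solve(L, np.eye(obs.n)))
    M = np.outer(alpha, alpha) - Kinv
    grad = np.array(
        [0.5 * np.sum(M * _dK_dlog(spec, obs.X, p)) for p in free_params]
    )
    return lml, grad
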