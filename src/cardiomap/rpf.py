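"""Regularized particle filter over the GP kernel hyperparameter.

The implicit-exploration planner treats the kernel hyperparameter as a random
variable theta_A with distribution p(theta_A), initialized around the prior
theta_0 learned from demonstrations and updated after every new mapping
point.  Particles live in the log domain of (length_scale, signal_variance);
noise variance and Matern smoothness are held fixed.  Degeneracy is handled
by a resample-move step: systematic resampling followed by a jitter drawn
from an Epanechnikov kernel at the optimal bandwidth, i.e. resampling from a
kernel-smoothed continuous approximation of the posterior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .gp_core import KernelSpec, ObservationSet, one_step_predictive_logpdf

logger = logging.getLogger("cardiomap.rpf")

#: Names (and order) of the filtered hyperparameters.
FILTERED_PARAMS = ("length_scale", "signal_variance")


@dataclass
class ParticleSet:
    """Weighted particles approximating p(theta_A).

    ``particles`` is an m x 2 array of (log length_scale, log signal_variance);
    ``base_spec`` carries the fixed components (family, nu, noise).
    """

    particles: np.ndarray
    weights: np.ndarray
    base_spec: KernelSpec
    rng_state: int | None = None

    def __post_init__(self) -> None:
        self.particles = np.atleast_2d(np.asarray(self.particles, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.particles.shape[0] != self.weights.shape[0]:
            raise ValueError("particles and weights disagree in length")
        if self.particles.shape[0] < 2:
            raise ValueError("need at least 2 particles")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @property
    def m(self) -> int:
        return self.particles.shape[0]

    def spec_of(self, i: int) -> KernelSpec:
        log_l, log_sf2 = self.particles[i]
        return self.base_spec.replace(
            length_scale=math.exp(log_l), signal_variance=math.exp(log_sf2)
        )

    def mean_log(self) -> np.ndarray:
        """Weighted posterior mean in the log domain."""
        return self.weights @ self.particles

    def mean_spec(self) -> KernelSpec:
        """KernelSpec at the weighted-mean (log-domain) hyperparameter."""
        log_l, log_sf2 = self.mean_log()
        return self.base_spec.replace(
            length_scale=math.exp(log_l), signal_variance=math.exp(log_sf2)
        )

    def sd_log(self) -> np.ndarray:
        mu = self.mean_log()
        var = self.weights @ (self.particles - mu) ** 2
        return np.sqrt(var)


def init_particles(theta0: KernelSpec, m: int = 100, spread: float = 0.5,
                   seed: int = 0) -> ParticleSet:
    """Uniform initial particle cloud centred (in log domain) on theta_0.

    Particles are drawn uniformly on ``[theta0/(1+spread), theta0*(1+spread)]``
    per component — symmetric about theta_0 in the log domain, so the support
    mean is theta_0 there.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    centre = np.log([theta0.length_scale, theta0.signal_variance])
    half = math.log1p(spread)
    particles = rng.uniform(centre - half, centre + half, size=(m, 2))
    weights = np.full(m, 1.0 / m)
    return ParticleSet(particles, weights, theta0, rng_state=seed)


def update_weights(
    ps: ParticleSet, obs_before: ObservationSet, new_obs: tuple[np.ndarray, float]
) -> ParticleSet:
    """Bayes update of the particle weights on a new (position, value) pair.

    Each weight is multiplied by the one-step GP predictive density of the
    new value at the new point given the previous observations under that
    particle's hyperparameters, then renormalized.  A total underflow resets
    to uniform weights with a warning.
    """
    x_new, y_new = new_obs
    x_new = np.asarray(x_new, dtype=float).ravel()
    if obs_before.n and np.any(np.all(np.isclose(obs_before.X, x_new), axis=1)):
        raise ValueError("new observation point already present in the mapped set")
    log_lik = np.array([
        one_step_predictive_logpdf(ps.spec_of(i), obs_before, x_new, y_new)
        for i in range(ps.m)
    ])
    log_w = np.log(np.clip(ps.weights, 1e-300, None)) + log_lik
    log_w -= log_w.max()
    w = np.exp(log_w)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        logger.warning("all particle likelihoods underflowed; resetting to uniform weights")
        w = np.full(ps.m, 1.0 / ps.m)
    else:
        w /= total
    return replace(ps, weights=w)


# -- Epanechnikov sampling ---------------------------------------------------

def _sample_epanechnikov(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Draws from the d-variate Epanechnikov kernel K(x) ~ (1 - |x|^2) on |x|<1."""
    if d == 1:
        # median of three U(-1,1) has the Epanechnikov density
        u = rng.uniform(-1.0, 1.0, size=(n, 3))
        return np.median(u, axis=1).reshape(n, 1)
    if d == 2:
        # radius CDF F(r) = 2r^2 - r^4 inverts in closed form
        direction = rng.normal(size=(n, 2))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        r = np.sqrt(1.0 - np.sqrt(1.0 - rng.uniform(size=n)))
        return direction * r[:, None]
    # generic rejection from the unit cube
    out = np.empty((n, d))
    filled = 0
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - filled), d))
        r2 = np.sum(cand**2, axis=1)
        acc = cand[rng.uniform(size=cand.shape[0]) < np.clip(1.0 - r2, 0.0, None)]
        take = min(len(acc), n - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
    return out


def epanechnikov_bandwidth(ps: ParticleSet, scale: float = 1.0) -> tuple[float, np.ndarray]:
    """Optimal-bandwidth rule h = scale * A * m^(-1/(d+4)) with A for the
    Epanechnikov kernel, plus the Cholesky factor of the weighted particle
    covariance (the jitter is h * L * eps)."""
    d = ps.particles.shape[1]
    c_d = math.pi ** (d / 2.0) / math.gamma(d / 2.0 + 1.0)  # unit-ball volume
    A = (8.0 / c_d * (d + 4.0) * (2.0 * math.sqrt(math.pi)) ** d) ** (1.0 / (d + 4.0))
    h = scale * A * ps.m ** (-1.0 / (d + 4.0))
    mu = ps.mean_log()
    diff = ps.particles - mu
    cov = (ps.weights[:, None] * diff).T @ diff
    cov += 1e-12 * np.eye(d)  # guard a collapsed cloud
    L = np.linalg.cholesky(cov)
    return h, L


def resample_move(ps: ParticleSet, seed: int, bandwidth_scale: float = 1.0,
                  shrinkage: bool = True) -> ParticleSet:
    """Systematic resampling followed by an Epanechnikov kernel move.

    Output weights are uniform.  The move is applied in the log domain, so
    hyperparameters stay positive.  With ``shrinkage`` (default), resampled
    particles are first contracted towards the weighted mean by
    ``sqrt(1 - h^2/(d+4))`` — the kernel-location shrinkage of the particle-
    filter literature — so that the kernel move preserves the first two
    moments of the posterior instead of inflating its spread every step.
    """
    rng = np.random.default_rng(seed)
    d = ps.particles.shape[1]
    # systematic resampling
    positions = (rng.uniform() + np.arange(ps.m)) / ps.m
    cumw = np.cumsum(ps.weights)
    cumw[-1] = 1.0
    idx = np.searchsorted(cumw, positions)
    h, L = epanechnikov_bandwidth(ps, bandwidth_scale)
    eps = _sample_epanechnikov(rng, ps.m, d)
    resampled = ps.particles[idx]
    if shrinkage:
        # unit-ball Epanechnikov has per-component variance 1/(d+4)
        a = math.sqrt(max(1.0 - h * h / (d + 4.0), 0.0))
        mu = ps.mean_log()
        resampled = mu + a * (resampled - mu)
    new_particles = resampled + h * eps @ L.T
    return ParticleSet(new_particles, np.full(ps.m, 1.0 / ps.m), ps.base_spec,
                       rng_state=seed)


def effective_sample_size(ps: ParticleSet) -> float:
    """ESS = 1 / sum w_i^2; ranges from 1 (degenerate) to m (uniform)."""
    return float(1.0 / np.sum(ps.weights**2))


def particles_to_frame(ps: ParticleSet):
    """Particle snapshot as a DataFrame (particle_id, log_l, log_sf2, weight)."""
    import pandas as pd

    return pd.DataFrame({
        "particle_id": np.arange(ps.m),
        "log_l": ps.particles[:, 0],
        "log_sf2": ps.particles[:, 1],
        "weight": ps.weights,
    })
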