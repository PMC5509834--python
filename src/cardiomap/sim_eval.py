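"""Synthetic ground-truth fields, evaluation metrics, and the 2D benchmark.

The benchmark emulates voltage maps of varying complexity: ground truth is a
sum of k isotropic 2D Gaussian bumps with random centres, widths and
amplitudes on a 10 x 10 square sampled by a 60 x 60 lattice (3600 candidate
points).  k in {5, 20, 40, 60} spans simple to complex fields.  Two planners
map m = 30 points from the grid centre — implicit exploration (IE, no travel
cost) and the geometry-coverage baseline (ratio = 1) — their observations
are GP-regressed onto the full grid, and estimate/truth similarity is scored
by SSIM.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .baseline_geometry import plan_geometry
from .gp_core import KernelSpec, ObservationSet, chol_with_jitter, kernel_eval
from .planner import PlanConfig, _mean_and_var, run_mapping
from .surfaces import SampleDomain, make_grid_domain

logger = logging.getLogger("cardiomap.sim")

#: Benchmark prior: Matern kernel with l = 1, sigma_f = 1.
BENCHMARK_THETA0 = KernelSpec(
    family="matern", length_scale=1.0, signal_variance=1.0,
    noise_variance=1e-3, nu=2.5,
)

BENCHMARK_METHODS = ("IE", "geometry")


@dataclass
class MixtureSpec:
    """Sum-of-Gaussians ground truth: k components on the domain square."""

    means: np.ndarray       # (k, 2)
    covs: np.ndarray        # (k, 2, 2) SPD
    amplitudes: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        k = self.means.shape[0]
        if k < 1:
            raise ValueError("need at least one mixture component")
        if self.covs.shape != (k, 2, 2):
            raise ValueError("covs must have shape (k, 2, 2)")
        if self.amplitudes.shape[0] != k:
            raise ValueError("amplitudes must have length k")
        for C in self.covs:
            if not np.allclose(C, C.T) or np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("each component covariance must be SPD")

    @property
    def k(self) -> int:
        return self.means.shape[0]


def sample_mixtures(k: int, extent: float = 10.0, seed: int = 0) -> MixtureSpec:
    """Random mixture: centres uniform on the square, isotropic widths
    log-uniform on [(extent/20)^2, (extent/4)^2], amplitudes U(0.5, 1.5)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    means = rng.uniform(0.0, extent, size=(k, 2))
    lo, hi = math.log((extent / 20.0) ** 2), math.log((extent / 4.0) ** 2)
    var = np.exp(rng.uniform(lo, hi, size=k))
    covs = var[:, None, None] * np.eye(2)[None]
    amps = rng.uniform(0.5, 1.5, size=k)
    return MixtureSpec(means, covs, amps)


def mixture_field(spec: MixtureSpec, domain: SampleDomain | np.ndarray) -> np.ndarray:
    """value(x) = sum_j amp_j exp(-1/2 (x-mu_j)^T Sigma_j^{-1} (x-mu_j))."""
    pts = domain.points if isinstance(domain, SampleDomain) else np.atleast_2d(domain)
    if pts.shape[1] != 2:
        raise ValueError("mixture fields are 2D")
    out = np.zeros(pts.shape[0])
    for mu, C, a in zip(spec.means, spec.covs, spec.amplitudes):
        diff = pts - mu
        Cinv = np.linalg.inv(C)
        q = np.einsum("ij,jk,ik->i", diff, Cinv, diff)
        out += a * np.exp(-0.5 * q)
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def ssim_index(est_grid: np.ndarray, truth_grid: np.ndarray) -> float:
    """Mean structural similarity between two 2D value arrays.

    Gaussian-weighted local statistics (sigma = 1.5, 11 x 11 window,
    population covariance), stabilizers C1 = (0.01 L)^2 and C2 = (0.03 L)^2
    with L the dynamic range of the ground truth, and the border strip of
    the window radius cropped before averaging — the standard definition.
    """
    est = np.asarray(est_grid, dtype=float)
    truth = np.asarray(truth_grid, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("estimate and truth must have the same shape")
    if est.ndim != 2:
        raise ValueError("ssim_index expects 2D arrays")
    sigma, truncate = 1.5, 3.5
    radius = int(truncate * sigma + 0.5)
    win = 2 * radius + 1
    if min(est.shape) < win:
        raise ValueError(f"arrays must be at least {win} x {win}")
    L = float(truth.max() - truth.min())
    if L == 0.0:
        if np.array_equal(est, truth):
            return 1.0
        raise ValueError("ground truth has zero dynamic range")
    C1, C2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    f = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(est, **f)
    uy = gaussian_filter(truth, **f)
    uxx = gaussian_filter(est * est, **f)
    uyy = gaussian_filter(truth * truth, **f)
    uxy = gaussian_filter(est * truth, **f)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / ((ux**2 + uy**2 + C1) * (vx + vy + C2))
    return float(S[radius:-radius, radius:-radius].mean(dtype=np.float64))


def mean_l1_error(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute difference between estimated and true values."""
    est = np.asarray(est, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if est.shape != truth.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(est - truth)))


def sample_gp_field(domain: SampleDomain, spec: KernelSpec, seed: int = 0) -> np.ndarray:
    """One zero-mean GP draw over the domain points (dense covariance)."""
    if domain.n > 5000:
        raise ValueError("domain too large for a dense GP draw (N <= 5000)")
    K = kernel_eval(spec, domain.points, domain.points)
    if spec.signal_variance < 1e-300:  # pragma: no cover - degenerate guard
        return np.zeros(domain.n)
    L, _ = chol_with_jitter(K + 1e-10 * spec.signal_variance * np.eye(domain.n))
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal(domain.n)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per-trial SSIM results of the 2D grid benchmark."""

    rows: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["group_k", "trial", "method", "ssim", "seed"])

    def group_means(self) -> pd.DataFrame:
        df = self.frame()
        return df.groupby(["group_k", "method"], as_index=False)["ssim"].mean()

    def mean_ssim(self, group_k: int, method: str) -> float:
        df = self.frame()
        sel = df[(df.group_k == group_k) & (df.method == method)]
        if sel.empty:
            raise KeyError(f"no rows for k={group_k}, method={method}")
        return float(sel.ssim.mean())

    def save(self, out_dir: str | Path, prefix: str = "benchmark") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv = out_dir / f"{prefix}_trials.csv"
        summary = out_dir / f"{prefix}_summary.json"
        self.frame().to_csv(csv, index=False)
        means = {
            f"k{int(r.group_k)}_{r.method}": round(float(r.ssim), 6)
            for r in self.group_means().itertuples()
        }
        summary.write_text(json.dumps(
            {"config": self.config, "group_means": means,
             "n_failures": len(self.failures)},
            indent=2, sort_keys=True) + "\n")
        return {"trials": csv, "summary": summary}


def centre_index(domain: SampleDomain) -> int:
    """Domain index nearest the bounding-box centre (lowest index on ties)."""
    centre = 0.5 * (domain.points.min(axis=0) + domain.points.max(axis=0))
    return int(np.argmin(np.linalg.norm(domain.points - centre, axis=1)))


def run_benchmark(
    groups=(5, 20, 40, 60),
    trials: int = 20,
    m: int = 30,
    methods=BENCHMARK_METHODS,
    seed: int = 0,
    extent: float = 10.0,
    n_per_side: int = 60,
    theta0: KernelSpec = BENCHMARK_THETA0,
    n_particles: int = 100,
) -> BenchmarkReport:
    """The 2D grid mapping benchmark.

    Per trial: draw a k-component mixture field (shared by all methods), run
    each method for m points from the grid centre, GP-regress its
    observations onto the full grid, and score SSIM against the truth.  IE's
    regression uses its final particle-posterior-mean hyperparameter; the
    geometry baseline uses the fixed prior theta_0.  Trial failures are
    recorded and group means are taken over completed trials.
    """
    unknown = [meth for meth in methods if meth not in BENCHMARK_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; valid: {list(BENCHMARK_METHODS)}")
    domain = make_grid_domain(extent, n_per_side)
    start = centre_index(domain)
    shape = domain.grid_shape
    report = BenchmarkReport(config={
        "groups": list(groups), "trials": trials, "m": m,
        "methods": list(methods), "seed": seed, "extent": extent,
        "n_per_side": n_per_side, "theta0": theta0.to_dict(),
        "n_particles": n_particles, "start_index": start,
    })
    root = np.random.SeedSequence(seed)
    group_seeds = root.spawn(len(groups))
    for gi, k in enumerate(groups):
        trial_seeds = group_seeds[gi].spawn(trials)
        for t in range(trials):
            sub = trial_seeds[t].spawn(2)
            mix_seed = int(sub[0].generate_state(1)[0] % (2**31))
            run_seed = int(sub[1].generate_state(1)[0] % (2**31))
            mix = sample_mixtures(k, extent, mix_seed)
            truth = mixture_field(mix, domain)
            trial_domain = domain.with_values(truth)
            for method in methods:
                try:
                    ssim = _benchmark_trial(
                        trial_domain, truth, method, m, start, theta0,
                        n_particles, run_seed, shape,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    logger.error("trial failed (k=%d, trial=%d, %s): %s",
                                 k, t, method, exc)
                    report.failures.append(
                        {"group_k": k, "trial": t, "method": method, "error": str(exc)})
                    continue
                report.rows.append({
                    "group_k": k, "trial": t, "method": method,
                    "ssim": ssim, "seed": run_seed,
                })
        logger.info("benchmark group k=%d done", k)
    return report


def _benchmark_trial(domain, truth, method, m, start, theta0, n_particles,
                     run_seed, shape) -> float:
    if method == "IE":
        cfg = PlanConfig(strategy="IE", use_travel_cost=False, n_points=m,
                         start_index=start, n_particles=n_particles,
                         seed=run_seed)
        run = run_mapping(domain, truth, theta0, cfg)
        obs = ObservationSet(run.positions, run.values)
        regress_spec = run.final_spec
    else:
        run = plan_geometry(domain, m, ratio=1.0, start_index=start)
        obs = ObservationSet(run.positions, truth[run.indices])
        regress_spec = theta0
    est, _ = _mean_and_var(regress_spec, obs, domain.points)
    return ssim_index(est.reshape(shape), truth.reshape(shape))
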