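"""Sequential next-best-point planning for voltage mapping.

Two acquisition strategies over the unobserved candidate set Abar = V - A:

* **PE (pure exploitation)** — pick the candidate with maximal scalar
  posterior entropy under the fixed prior hyperparameter theta_0.
* **IE (implicit exploration)** — pick the candidate with maximal expected
  posterior entropy under the particle approximation of p(theta_A), the
  hyperparameter posterior tracked by the regularized particle filter.

With travel cost enabled, each candidate's entropy is divided by the
Euclidean distance s from the current catheter position, and candidates
within the exclusion radius s_min are masked out so consecutive points do not
collapse onto each other.

The closed loop (`run_mapping`) needs only the first mapping point as input;
every subsequent point is computed from the previous observations, so a run
is fully determined by (start point, oracle, theta_0, config, seed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import rpf as rpf_mod
from .gp_core import (
    KernelSpec,
    ObservationSet,
    chol_with_jitter,
    kernel_eval,
    kernel_from_r,
    scalar_entropy,
)
from .surfaces import SampleDomain

logger = logging.getLogger("cardiomap.planner")

STRATEGIES = ("PE", "IE")


@dataclass
class PlanConfig:
    """Configuration of a mapping run.

    ``s_min`` of ``None`` defaults to 5% of the domain bounding-box diagonal
    when travel cost is enabled (0 otherwise).
    """

    strategy: str = "IE"
    use_travel_cost: bool = False
    s_min: float | None = None
    n_points: int = 30
    start_index: int = 0
    n_particles: int = 100
    seed: int = 0
    spread: float = 0.5
    bandwidth_scale: float = 1.0
    ie_score: str = "expectation"      # or "mean_theta"
    estimate_mode: str = "mean_particle"  # or "mixture"
    record_fields: bool = False
    geodesic: bool = False             # mesh-graph travel distances

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.s_min is not None and self.s_min < 0:
            raise ValueError("s_min must be >= 0")
        if self.ie_score not in ("expectation", "mean_theta"):
            raise ValueError("ie_score must be 'expectation' or 'mean_theta'")
        if self.estimate_mode not in ("mean_particle", "mixture"):
            raise ValueError("estimate_mode must be 'mean_particle' or 'mixture'")

    def resolved_s_min(self, domain: SampleDomain) -> float:
        if self.s_min is not None:
            return self.s_min
        return 0.05 * domain.bbox_diagonal if self.use_travel_cost else 0.0


@dataclass
class PlannerState:
    """Snapshot of a mapping run between selections."""

    domain: SampleDomain
    theta0: KernelSpec
    config: PlanConfig
    obs: ObservationSet
    observed_indices: list[int] = field(default_factory=list)
    particles: rpf_mod.ParticleSet | None = None
    current_index: int | None = None

    @property
    def unobserved(self) -> np.ndarray:
        mask = np.ones(self.domain.n, dtype=bool)
        mask[self.observed_indices] = False
        return np.flatnonzero(mask)


@dataclass
class MappingRun:
    """Ordered mapping sequence with per-step estimates and diagnostics."""

    indices: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    travel_dist: np.ndarray           # cumulative Euclidean path length
    max_sd: np.ndarray                # over unobserved points, per step
    median_sd: np.ndarray
    mean_l1: np.ndarray               # vs domain ground truth (NaN if absent)
    ess: np.ndarray                   # particle ESS per step (NaN for PE)
    final_spec: KernelSpec
    theta0: KernelSpec
    config: PlanConfig
    estimates: list[np.ndarray] | None = None
    final_estimate: np.ndarray | None = None
    method_label: str = ""

    @property
    def m(self) -> int:
        return len(self.indices)

    def sequence_frame(self) -> pd.DataFrame:
        pos = self.positions
        cols = {"step": np.arange(1, self.m + 1), "index": self.indices}
        for j, name in enumerate("xyz"[: pos.shape[1]]):
            cols[name] = pos[:, j]
        if pos.shape[1] == 2:
            cols["z"] = np.zeros(self.m)
        cols["value"] = self.values
        cols["travel_dist"] = self.travel_dist
        return pd.DataFrame(cols)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(1, self.m + 1),
            "max_sd": self.max_sd,
            "median_sd": self.median_sd,
            "mean_l1": self.mean_l1,
            "ess": self.ess,
        })

    def save(self, out_dir: str | Path, prefix: str = "run") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        seq = out_dir / f"{prefix}_sequence.csv"
        met = out_dir / f"{prefix}_metrics.csv"
        man = out_dir / f"{prefix}_manifest.json"
        self.sequence_frame().to_csv(seq, index=False)
        self.metrics_frame().to_csv(met, index=False)
        manifest = {
            "method": self.method_label or self.config.strategy,
            "config": asdict(self.config),
            "theta0": self.theta0.to_dict(),
            "final_spec": self.final_spec.to_dict(),
            "n_points": self.m,
        }
        man.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return {"sequence": seq, "metrics": met, "manifest": man}


# ---------------------------------------------------------------------------
# Travel distances
# ---------------------------------------------------------------------------

def geodesic_distances(domain: SampleDomain, source: int) -> np.ndarray:
    """Shortest-path distances from ``source`` along mesh edges.

    Edge weights are Euclidean edge lengths; this is the usual graph
    approximation of geodesic distance on a triangulated surface.  The
    sparse edge graph is cached on the domain object.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    if domain.faces is None or len(domain.faces) == 0:
        raise ValueError("geodesic travel cost requires a triangulated mesh")
    graph = getattr(domain, "_edge_graph", None)
    if graph is None:
        F = domain.faces
        edges = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
        edges = np.unique(np.sort(edges, axis=1), axis=0)  # shared edges once
        w = np.linalg.norm(domain.points[edges[:, 0]] - domain.points[edges[:, 1]],
                           axis=1)
        graph = coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([edges[:, 0], edges[:, 1]]),
              np.concatenate([edges[:, 1], edges[:, 0]]))),
            shape=(domain.n, domain.n)).tocsr()
        domain._edge_graph = graph
    return dijkstra(graph, directed=False, indices=source)


# ---------------------------------------------------------------------------
# Fast per-candidate posterior variance
# ---------------------------------------------------------------------------

def _candidate_variances(
    spec: KernelSpec,
    obs: ObservationSet,
    cand_pts: np.ndarray,
    D_cand: np.ndarray | None = None,
    D_obs: np.ndarray | None = None,
) -> np.ndarray:
    """Scalar posterior variance at each candidate (D=1 per candidate).

    Distance matrices can be supplied so the geometry is computed once and
    reused across particles (they share distances, not kernel values).
    """
    if obs.n == 0:
        if spec.is_stationary:
            return np.full(cand_pts.shape[0], spec.signal_variance)
        return np.einsum("ij,ij->i", cand_pts, cand_pts) / spec.length_scale**2 \
            * spec.signal_variance + spec.signal_variance
    if spec.is_stationary:
        if D_obs is None:
            D_obs = cdist(obs.X, obs.X)
        if D_cand is None:
            D_cand = cdist(cand_pts, obs.X)
        Kxx = kernel_from_r(spec, D_obs) + spec.noise_variance * np.eye(obs.n)
        Kc = kernel_from_r(spec, D_cand)
        k0 = spec.signal_variance
    else:
        Kxx = kernel_eval(spec, obs.X, obs.X) + spec.noise_variance * np.eye(obs.n)
        Kc = kernel_eval(spec, cand_pts, obs.X)
        k0 = np.diag(kernel_eval(spec, cand_pts, cand_pts))
    L, _ = chol_with_jitter(Kxx)
    A = np.linalg.solve(L, Kc.T)
    return np.maximum(k0 - np.einsum("ij,ij->j", A, A), 0.0)


def _mean_and_var(
    spec: KernelSpec, obs: ObservationSet, pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean (centred-y convention handled here) and variance at pts."""
    if obs.n == 0:
        return np.zeros(pts.shape[0]), _candidate_variances(spec, obs, pts)
    ybar = float(obs.y.mean())
    yc = obs.y - ybar
    if spec.is_stationary:
        D_obs = cdist(obs.X, obs.X)
        D_c = cdist(pts, obs.X)
        Kxx = kernel_from_r(spec, D_obs) + spec.noise_variance * np.eye(obs.n)
        Kc = kernel_from_r(spec, D_c)
        k0 = spec.signal_variance
    else:
        Kxx = kernel_eval(spec, obs.X, obs.X) + spec.noise_variance * np.eye(obs.n)
        Kc = kernel_eval(spec, pts, obs.X)
        k0 = np.diag(kernel_eval(spec, pts, pts))
    L, _ = chol_with_jitter(Kxx)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, yc))
    A = np.linalg.solve(L, Kc.T)
    mean = Kc @ alpha + ybar
    var = np.maximum(k0 - np.einsum("ij,ij->j", A, A), 0.0)
    return mean, var


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

def score_candidates(state: PlannerState, candidates: Sequence[int]) -> np.ndarray:
    """Acquisition score for each candidate index (higher is better).

    PE: scalar posterior entropy under theta_0.  IE: particle-weighted
    average of the per-particle entropies (or the entropy at the weighted-
    mean hyperparameter when ``ie_score='mean_theta'``).  With travel cost,
    scores are divided by the Euclidean distance s from the current point and
    candidates within s_min are masked to -inf.
    """
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("no candidates to score")
    observed = set(state.observed_indices)
    if any(int(c) in observed for c in candidates):
        raise ValueError("candidates must be unobserved domain points")
    cand_pts = state.domain.points[candidates]
    obs = state.obs
    cfg = state.config

    D_obs = cdist(obs.X, obs.X) if obs.n else None
    D_cand = cdist(cand_pts, obs.X) if obs.n else None

    if cfg.strategy == "PE" or state.particles is None:
        v = _candidate_variances(state.theta0, obs, cand_pts, D_cand, D_obs)
        H = scalar_entropy(v)
    elif cfg.ie_score == "mean_theta":
        spec = state.particles.mean_spec()
        v = _candidate_variances(spec, obs, cand_pts, D_cand, D_obs)
        H = scalar_entropy(v)
    else:
        ps = state.particles
        H = np.zeros(candidates.size)
        for i in range(ps.m):
            if ps.weights[i] <= 0:
                continue
            v = _candidate_variances(ps.spec_of(i), obs, cand_pts, D_cand, D_obs)
            H += ps.weights[i] * scalar_entropy(v)

    if cfg.use_travel_cost:
        if state.current_index is None:
            raise ValueError("travel cost requires a current catheter position")
        if cfg.geodesic:
            s = geodesic_distances(state.domain, state.current_index)[candidates]
        else:
            cur = state.domain.points[state.current_index]
            s = np.linalg.norm(cand_pts - cur, axis=1)
        s_min = cfg.resolved_s_min(state.domain)
        eligible = s >= s_min
        if not eligible.any():
            raise ValueError(
                f"all candidates lie within s_min={s_min:g} of the current "
                f"point; relax s_min or enlarge the candidate set"
            )
        scores = np.where(eligible, H / np.maximum(s, 1e-300), -np.inf)
        return scores
    return H


def select_next(state: PlannerState) -> int:
    """Maximizing candidate index; ties broken by lowest domain index."""
    candidates = state.unobserved
    if candidates.size == 0:
        raise ValueError("no unobserved candidates remain")
    scores = score_candidates(state, candidates)
    # candidates are in ascending index order, so argmax's first-max rule
    # implements the lowest-index tie-break
    return int(candidates[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

def _resolve_oracle(value_oracle) -> Callable[[int, np.ndarray], float]:
    if callable(value_oracle):
        return value_oracle
    arr = np.asarray(value_oracle, dtype=float).ravel()

    def _lookup(idx: int, _pos: np.ndarray) -> float:
        return float(arr[idx])

    return _lookup


def run_mapping(
    domain: SampleDomain,
    value_oracle,
    theta0: KernelSpec,
    config: PlanConfig,
) -> MappingRun:
    """Run the closed mapping loop for ``config.n_points`` points.

    ``value_oracle`` is either a per-domain-point value array or a callable
    ``(index, position) -> value``.  Each step: observe the current point,
    update the hyperparameter posterior (IE), record the field estimate and
    uncertainty summaries, then select the next point.  Estimates use the
    centred-y convention (training mean subtracted and re-added).
    """
    oracle = _resolve_oracle(value_oracle)
    if not (0 <= config.start_index < domain.n):
        raise ValueError("start_index outside the domain")
    m = config.n_points
    if m > domain.n:
        raise ValueError("cannot map more points than the domain contains")

    seed_seq = np.random.SeedSequence(config.seed)
    init_seed, *move_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(m + 1)
    ]

    state = PlannerState(
        domain=domain,
        theta0=theta0,
        config=config,
        obs=ObservationSet.empty(domain.dim),
    )
    if config.strategy == "IE":
        state.particles = rpf_mod.init_particles(
            theta0, config.n_particles, config.spread, init_seed
        )

    idx = int(config.start_index)
    indices: list[int] = []
    values: list[float] = []
    travel: list[float] = []
    max_sd = np.empty(m)
    median_sd = np.empty(m)
    mean_l1 = np.full(m, np.nan)
    ess = np.full(m, np.nan)
    estimates: list[np.ndarray] | None = [] if config.record_fields else None
    final_estimate = None

    truth = domain.values

    for step in range(m):
        pos = domain.points[idx]
        try:
            y_val = float(oracle(idx, pos))
        except Exception as exc:
            logger.error("value oracle failed at point %d: %s; aborting run", idx, exc)
            m_done = step
            return _finalize(
                state, indices[:m_done], values[:m_done], travel[:m_done],
                max_sd[:m_done], median_sd[:m_done], mean_l1[:m_done],
                ess[:m_done], estimates, final_estimate, domain, theta0, config,
            )
        if not np.isfinite(y_val):
            raise ValueError(f"value oracle returned non-finite value at point {idx}")

        if config.strategy == "IE":
            state.particles = rpf_mod.update_weights(
                state.particles, state.obs, (pos, y_val)
            )
            ess[step] = rpf_mod.effective_sample_size(state.particles)
            logger.debug("step %d: ESS %.1f", step + 1, ess[step])
            state.particles = rpf_mod.resample_move(
                state.particles, move_seeds[step], config.bandwidth_scale
            )

        state.obs = state.obs.append(pos, y_val)
        state.observed_indices.append(idx)
        state.current_index = idx
        indices.append(idx)
        values.append(y_val)
        travel.append(
            (travel[-1] if travel else 0.0)
            + (np.linalg.norm(pos - domain.points[indices[-2]]) if len(indices) > 1 else 0.0)
        )

        report_spec = (
            theta0 if config.strategy == "PE" else _reporting_spec(state, config)
        )
        est, var_all = _estimate_field(state, report_spec, config)
        unobs = state.unobserved
        sd_unobs = np.sqrt(var_all[unobs]) if unobs.size else np.array([0.0])
        max_sd[step] = sd_unobs.max()
        median_sd[step] = float(np.median(sd_unobs))
        if truth is not None:
            mean_l1[step] = float(np.mean(np.abs(est - truth)))
        if estimates is not None:
            estimates.append(est)
        final_estimate = est

        if step < m - 1:
            idx = select_next(state)

    return _finalize(state, indices, values, travel, max_sd, median_sd,
                     mean_l1, ess, estimates, final_estimate, domain, theta0, config)


def _reporting_spec(state: PlannerState, config: PlanConfig) -> KernelSpec:
    return state.particles.mean_spec() if state.particles is not None else state.theta0


def _estimate_field(
    state: PlannerState, spec: KernelSpec, config: PlanConfig
) -> tuple[np.ndarray, np.ndarray]:
    if config.strategy == "IE" and config.estimate_mode == "mixture":
        ps = state.particles
        mean = np.zeros(state.domain.n)
        var = np.zeros(state.domain.n)
        for i in range(ps.m):
            if ps.weights[i] <= 0:
                continue
            mu_i, v_i = _mean_and_var(ps.spec_of(i), state.obs, state.domain.points)
            mean += ps.weights[i] * mu_i
            var += ps.weights[i] * v_i  # within-particle part only
        return mean, var
    return _mean_and_var(spec, state.obs, state.domain.points)


def _finalize(state, indices, values, travel, max_sd, median_sd, mean_l1,
              ess, estimates, final_estimate, domain, theta0, config) -> MappingRun:
    final_spec = theta0 if config.strategy == "PE" else _reporting_spec(state, config)
    return MappingRun(
        indices=np.asarray(indices, dtype=int),
        positions=domain.points[np.asarray(indices, dtype=int)] if indices else np.empty((0, domain.dim)),
        values=np.asarray(values, dtype=float),
        travel_dist=np.asarray(travel, dtype=float),
        max_sd=np.asarray(max_sd, dtype=float),
        median_sd=np.asarray(median_sd, dtype=float),
        mean_l1=np.asarray(mean_l1, dtype=float),
        ess=np.asarray(ess, dtype=float),
        final_spec=final_spec,
        theta0=theta0,
        config=config,
        estimates=estimates,
        final_estimate=final_estimate,
        method_label=config.strategy,
    )
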