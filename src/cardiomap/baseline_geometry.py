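"""Geometry-coverage baseline planner ("baseline-approx").

A greedy coverage rule over the candidate set: each step picks the candidate
maximizing ``ratio * dhat + (1 - ratio) * chat`` where ``dhat`` is the
min-distance to the already-selected points and ``chat`` the per-point
curvature magnitude, both min-max normalized over the remaining candidates.
``ratio = 1`` is pure farthest-point coverage ("distance only");
``ratio = 0.5`` mixes in curvature so points cluster at high-curvature
anatomy ("distance and curvature").  The visiting order is the selection
order.  This is a documented approximation of the published mesh-coverage
planner it stands in for, anchored by the two behaviours above; outputs are
labelled ``baseline-approx``.
"""

from __future__ import annotations

import logging

import numpy as np

from .gp_core import KernelSpec
from .planner import MappingRun, PlanConfig
from .surfaces import SampleDomain

logger = logging.getLogger("cardiomap.baseline")

BASELINE_LABEL = "baseline-approx"


def plan_geometry(
    domain: SampleDomain, m: int, ratio: float = 1.0, start_index: int = 0
) -> MappingRun:
    """Greedy geometry-coverage plan of ``m`` points from ``start_index``.

    Field values play no role; if the domain carries ground-truth values
    they are recorded for convenience, otherwise values are NaN.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    if not (0 <= start_index < domain.n):
        raise ValueError("start_index outside the domain")
    if m > domain.n:
        raise ValueError("cannot select more points than the domain contains")
    curv = domain.curvature
    if ratio < 1.0:
        if curv is None:
            raise ValueError(
                "ratio < 1 requires per-point curvature on the domain "
                "(compute it with vertex_curvature)"
            )
        curv = np.asarray(curv, dtype=float)

    pts = domain.points
    selected = [int(start_index)]
    # min distance from every point to the selected set, updated incrementally
    min_d = np.linalg.norm(pts - pts[start_index], axis=1)
    remaining = np.ones(domain.n, dtype=bool)
    remaining[start_index] = False

    for _ in range(m - 1):
        rem_idx = np.flatnonzero(remaining)
        d = min_d[rem_idx]
        score = ratio * _minmax(d)
        if ratio < 1.0:
            score = score + (1.0 - ratio) * _minmax(curv[rem_idx])
        nxt = int(rem_idx[int(np.argmax(score))])
        selected.append(nxt)
        remaining[nxt] = False
        min_d = np.minimum(min_d, np.linalg.norm(pts - pts[nxt], axis=1))

    sel = np.asarray(selected, dtype=int)
    pos = pts[sel]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    travel = np.concatenate([[0.0], np.cumsum(steps)])
    values = (domain.values[sel] if domain.values is not None
              else np.full(m, np.nan))
    nan = np.full(m, np.nan)
    dummy_spec = KernelSpec("matern", 1.0, 1.0)
    cfg = PlanConfig(strategy="PE", n_points=m, start_index=int(start_index))
    return MappingRun(
        indices=sel, positions=pos, values=values, travel_dist=travel,
        max_sd=nan.copy(), median_sd=nan.copy(), mean_l1=nan.copy(),
        ess=nan.copy(), final_spec=dummy_spec, theta0=dummy_spec, config=cfg,
        method_label=f"{BASELINE_LABEL} (ratio={ratio:g})",
    )


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-300:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Discrete curvature
# ---------------------------------------------------------------------------

def vertex_curvature(mesh: SampleDomain) -> np.ndarray:
    """Per-vertex discrete mean-curvature magnitude via the cotangent Laplacian.

    H_i = |sum_j (cot a_ij + cot b_ij)(x_i - x_j)| / (4 A_i) with A_i the
    one-third barycentric vertex area.  On a sphere of radius R this
    approaches 1/R.  Vertices touching degenerate (near-zero-area) triangles
    get the mean of their neighbours' values instead, with a warning.
    """
    if mesh.faces is None or len(mesh.faces) == 0:
        raise ValueError("vertex_curvature requires a triangulated mesh")
    V = mesh.points
    if V.shape[1] == 2:  # planar mesh: embed in 3D
        V = np.column_stack([V, np.zeros(V.shape[0])])
    F = mesh.faces
    n = V.shape[0]
    lap = np.zeros((n, 3))
    area = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    adj: list[set[int]] = [set() for _ in range(n)]

    tri = V[F]  # (M, 3, 3)
    e0 = tri[:, 1] - tri[:, 0]
    e1 = tri[:, 2] - tri[:, 0]
    cross = np.cross(e0, e1)
    face_area = 0.5 * np.linalg.norm(cross, axis=1)
    degenerate = face_area < 1e-12 * max(1.0, float(np.abs(V).max())) ** 2

    for fi, (a, b, c) in enumerate(F):
        for u, v in ((a, b), (b, c), (c, a)):
            adj[u].add(v)
            adj[v].add(u)
        if degenerate[fi]:
            bad[[a, b, c]] = True
            continue
        idx = (a, b, c)
        for k in range(3):
            i, j, opp = idx[k], idx[(k + 1) % 3], idx[(k + 2) % 3]
            u = V[i] - V[opp]
            w = V[j] - V[opp]
            cot = float(u @ w) / max(float(np.linalg.norm(np.cross(u, w))), 1e-300)
            lap[i] += cot * (V[i] - V[j])
            lap[j] += cot * (V[j] - V[i])
        area[[a, b, c]] += face_area[fi] / 3.0
    ok = area > 0
    H = np.zeros(n)
    H[ok] = np.linalg.norm(lap[ok], axis=1) / (4.0 * area[ok])
    bad |= ~ok
    if bad.any():
        logger.warning("%d vertices touch degenerate triangles; using neighbour averages",
                       int(bad.sum()))
        for i in np.flatnonzero(bad):
            good_nb = [j for j in adj[i] if not bad[j]]
            H[i] = float(np.mean(H[good_nb])) if good_nb else 0.0
    return H
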