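"""Candidate sampling domains: 2D grids and triangulated surface meshes.

A :class:`SampleDomain` is the total candidate set V the planner draws from —
either a regular lattice over a square (the 2D benchmark) or the vertex set of
a triangulated anatomical mesh.  The module also carries the preprocessing
used on exported mapping data: removal of duplicate mapping points (which
destabilize GP regression) and nearest-neighbour projection of scattered
points/values onto mesh vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .gp_core import ObservationSet

logger = logging.getLogger("cardiomap.surfaces")


@dataclass
class SampleDomain:
    """Candidate point set V, optionally backed by a triangulated mesh.

    Attributes
    ----------
    points:
        N x d coordinates (d in {2, 3}).
    kind:
        ``grid`` or ``mesh``.
    faces:
        M x 3 vertex indices (mesh only).
    curvature:
        Optional per-point curvature magnitudes.
    values:
        Optional per-point ground-truth scalar field (used as the value
        oracle in simulations).
    grid_shape:
        (rows, cols) when ``kind == 'grid'``; lets 1D value vectors be
        reshaped to images for SSIM.
    """

    points: np.ndarray
    kind: str = "grid"
    faces: np.ndarray | None = None
    curvature: np.ndarray | None = None
    values: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise ValueError("a sampling domain needs at least 2 points")
        if self.kind not in ("grid", "mesh"):
            raise ValueError(f"kind must be 'grid' or 'mesh', got {self.kind!r}")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int)
            if self.faces.size and self.faces.max() >= self.n:
                raise ValueError("face indices exceed the number of points")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float).ravel()
            if self.values.shape[0] != self.n:
                raise ValueError("values length must match the number of points")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def bbox_diagonal(self) -> float:
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(span))

    def with_values(self, values: np.ndarray) -> "SampleDomain":
        return SampleDomain(self.points, self.kind, self.faces, self.curvature,
                            values, self.grid_shape)


def make_grid_domain(
    extent: float = 10.0, n_per_side: int = 60, cell_centred: bool = False
) -> SampleDomain:
    """Regular lattice of ``n_per_side**2`` points over ``[0, extent]^2``.

    With the defaults this is the 3600-point candidate set over a 10 x 10
    area used by the 2D benchmark.  The inclusive lattice places points on
    both boundaries (spacing ``extent/(n_per_side-1)``); ``cell_centred``
    instead centres points in ``n_per_side`` equal cells.
    """
    if n_per_side < 2:
        raise ValueError("n_per_side must be >= 2")
    if cell_centred:
        h = extent / n_per_side
        axis = h / 2.0 + h * np.arange(n_per_side)
    else:
        axis = np.linspace(0.0, extent, n_per_side)
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return SampleDomain(pts, kind="grid", grid_shape=(n_per_side, n_per_side))


# ---------------------------------------------------------------------------
# Mesh loading
# ---------------------------------------------------------------------------

def _parse_vtk_ascii(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal reader for legacy VTK ASCII POLYDATA (POINTS + POLYGONS)."""
    with open(path) as fh:
        tokens = fh.read().split()
    toks = [t for t in tokens]
    try:
        i = next(k for k, t in enumerate(toks) if t.upper() == "POINTS")
    except StopIteration:
        raise ValueError(f"{path}: no POINTS section found in VTK file")
    n_pts = int(toks[i + 1])
    coords = np.array(toks[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    try:
        j = next(k for k, t in enumerate(toks) if t.upper() == "POLYGONS")
    except StopIteration:
        raise ValueError(f"{path}: no POLYGONS section found in VTK file")
    n_poly = int(toks[j + 1])
    faces = []
    pos = j + 3
    for _ in range(n_poly):
        sz = int(toks[pos])
        poly = [int(t) for t in toks[pos + 1 : pos + 1 + sz]]
        # fan-split anything beyond a triangle
        for a in range(1, sz - 1):
            faces.append((poly[0], poly[a], poly[a + 1]))
        pos += sz + 1
    if not faces:
        raise ValueError(f"{path}: VTK file contains no polygons")
    return coords, np.asarray(faces, dtype=int)


def load_mesh(path: str, fmt: str | None = None) -> SampleDomain:
    """Load a triangulated mesh (PLY, OBJ, or legacy VTK ASCII) as a domain.

    Non-triangular faces are fan-triangulated.  Coordinates pass through
    unchanged (no unit conversion).
    """
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "vtk":
        vertices, faces = _parse_vtk_ascii(path)
    elif fmt in ("ply", "obj"):
        import trimesh

        mesh = trimesh.load(path, file_type=fmt, force="mesh", process=False)
        if mesh.vertices.shape[0] == 0:
            raise ValueError(f"{path}: mesh has no vertices")
        vertices = np.asarray(mesh.vertices, dtype=float)
        faces = np.asarray(mesh.faces, dtype=int)
        if faces.size == 0:
            raise ValueError(f"{path}: mesh has no faces")
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected ply, obj or vtk")
    return SampleDomain(vertices, kind="mesh", faces=faces)


# ---------------------------------------------------------------------------
# Preprocessing of exported mapping points
# ---------------------------------------------------------------------------

def dedupe_points(obs: ObservationSet, tol: float = 1e-6) -> tuple[ObservationSet, int]:
    """Remove duplicate mapping points, keeping the first of each cluster.

    Points within ``tol`` of an already-kept point are dropped (greedy
    first-kept rule in input order).  Returns the thinned set and the number
    of removed points.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if obs.n == 0:
        return obs, 0
    kept: list[int] = []
    kept_pts = np.empty((0, obs.dim))
    for i in range(obs.n):
        if kept_pts.shape[0]:
            d = np.linalg.norm(kept_pts - obs.X[i], axis=1)
            if d.min() <= tol:
                continue
        kept.append(i)
        kept_pts = np.vstack([kept_pts, obs.X[i]])
    removed = obs.n - len(kept)
    if removed:
        logger.info("dedupe_points removed %d of %d points (tol=%g)", removed, obs.n, tol)
    return ObservationSet(obs.X[kept], obs.y[kept]), removed


def project_points_nn(
    mesh_domain: SampleDomain, points: np.ndarray, values: np.ndarray
) -> tuple[dict[int, float], np.ndarray]:
    """Project scattered (point, value) pairs onto nearest mesh vertices.

    Each point maps to its Euclidean-nearest vertex.  When several points hit
    the same vertex their values are averaged.  Returns the sparse per-vertex
    value map and the point -> vertex index array.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if points.shape[0] != values.shape[0]:
        raise ValueError("points and values must pair one-to-one")
    tree = cKDTree(mesh_domain.points)
    _, idx = tree.query(points)
    idx = np.asarray(idx, dtype=int)
    vertex_values: dict[int, float] = {}
    counts: dict[int, int] = {}
    for v, val in zip(idx, values):
        vertex_values[int(v)] = vertex_values.get(int(v), 0.0) + val
        counts[int(v)] = counts.get(int(v), 0) + 1
    multi = sum(1 for c in counts.values() if c > 1)
    if multi:
        logger.info("project_points_nn: %d vertices received multiple points (averaged)", multi)
    for v in vertex_values:
        vertex_values[v] /= counts[v]
    return vertex_values, idx


def read_observations_csv(path: str, dedupe_tol: float | None = None) -> ObservationSet:
    """Read an `x,y,z,value` table of mapping points (optionally deduplicated)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"x", "y", "z", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    obs = ObservationSet(df[["x", "y", "z"]].to_numpy(float),
                         df["value"].to_numpy(float))
    if dedupe_tol is not None:
        obs, _ = dedupe_points(obs, dedupe_tol)
    return obs


def observations_from_projection(
    mesh_domain: SampleDomain, points: np.ndarray, values: np.ndarray
) -> ObservationSet:
    """Projected observations located at mesh vertices, centring left to caller."""
    vmap, _ = project_points_nn(mesh_domain, points, values)
    idx = np.array(sorted(vmap), dtype=int)
    return ObservationSet(mesh_domain.points[idx], np.array([vmap[i] for i in idx]))
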