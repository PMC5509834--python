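import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cardiomap import KernelSpec, ObservationSet, make_grid_domain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def matern_spec():
    return KernelSpec("matern", length_scale=1.0, signal_variance=1.0,
                      noise_variance=0.01, nu=2.5)


@pytest.fixture
def small_obs(rng):
    X = rng.uniform(0, 5, size=(6, 2))
    y = rng.normal(size=6)
    return ObservationSet(X, y)


@pytest.fixture
def small_grid():
    return make_grid_domain(extent=10.0, n_per_side=8)


def write_tetra_ply(path):
    """Minimal ASCII PLY tetrahedron (4 vertices, 4 triangular faces)."""
    verts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    faces = [(0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3)]
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(verts)}",
        "property float x", "property float y", "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{x} {y} {z}" for x, y, z in verts]
    lines += [f"3 {a} {b} {c}" for a, b, c in faces]
    path.write_text("\n".join(lines) + "\n")
    return verts, faces
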