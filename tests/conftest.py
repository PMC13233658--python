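import numpy as np
import pytest

from ventromech.mesh_core import SurfaceMesh
from ventromech import synthetic


def make_unit_cube() -> SurfaceMesh:
    """Axis-aligned unit cube with outward-wound triangles."""
    import trimesh
    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(tm.vertices) + 0.5, np.asarray(tm.faces))


def make_flat_grid(n: int = 7, spacing: float = 1.0) -> SurfaceMesh:
    """Open planar z=0 grid, triangles wound for +z normals."""
    xs = np.arange(n) * spacing
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            tris.append((a, b, a + 1))
            tris.append((a + 1, b, b + 1))
    return SurfaceMesh(verts, np.asarray(tris))


@pytest.fixture(scope="session")
def unit_cube() -> SurfaceMesh:
    return make_unit_cube()


@pytest.fixture(scope="session")
def flat_grid() -> SurfaceMesh:
    return make_flat_grid()


@pytest.fixture(scope="session")
def icosphere_r1_s4() -> SurfaceMesh:
    return synthetic.make_icosphere(1.0, 4)


@pytest.fixture(scope="session")
def icosphere_r10_s3() -> SurfaceMesh:
    return synthetic.make_icosphere(10.0, 3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
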