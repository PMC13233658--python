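import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventromech import synthetic
from ventromech.mechanomarkers import (
    PatchFit,
    compute_markers,
    curvature_change,
    fit_patch,
    mean_curvature_field,
    mesh_strain,
    principal_curvatures,
    smooth_to_vertices,
    triangle_local_frame,
    triangle_strain,
)
from ventromech.mesh_core import SurfaceMesh, vertex_normals

from conftest import make_flat_grid


def edge_length_strain_oracle(ref_tri, def_tri):
    """Principal strains from squared edge lengths only (metric pathway).

    With Gram matrices G = X^T X assembled from edge lengths, the principal
    strains are the eigenvalues of 1/2 (G_ref^{-1} G_def - I): an independent
    route that never forms the deformation gradient.
    """
    def gram(tri):
        p = np.asarray(tri, dtype=np.float64)
        d2, d3 = p[1] - p[0], p[2] - p[0]
        l2, l3 = d2 @ d2, d3 @ d3
        l23 = (d3 - d2) @ (d3 - d2)
        dot = 0.5 * (l2 + l3 - l23)
        return np.array([[l2, dot], [dot, l3]])

    M = 0.5 * (np.linalg.solve(gram(ref_tri), gram(def_tri)) - np.eye(2))
    return np.sort(np.linalg.eigvals(M).real)[::-1]


# ---------------------------------------------------------------------------
# patch fit and curvature
# ---------------------------------------------------------------------------

def test_fit_patch_flat(flat_grid):
    fit = fit_patch(flat_grid, 3 * 7 + 3)
    assert abs(fit.a) < 1e-9 and abs(fit.b) < 1e-9 and abs(fit.c) < 1e-9


def test_fit_patch_sphere_coefficients():
    sph = synthetic.make_icosphere(2.0, 4)
    fit = fit_patch(sph, 100)
    assert fit.a == pytest.approx(0.25, rel=0.05)
    assert fit.c == pytest.approx(0.25, rel=0.05)
    assert abs(fit.b) < 0.05 * 0.25 + 0.01


def test_fit_patch_cylinder():
    # open cylinder grid of radius 1, axis along y: curvatures (1, 0)
    n = 15
    theta = np.linspace(-0.6, 0.6, n)
    ys = np.linspace(-0.6, 0.6, n)
    tt, yy = np.meshgrid(theta, ys, indexing="ij")
    verts = np.column_stack([np.sin(tt).ravel(), yy.ravel(), np.cos(tt).ravel()])
    grid = make_flat_grid(n)
    cyl = SurfaceMesh(verts, grid.triangles)
    center = (n // 2) * n + n // 2
    fit = fit_patch(cyl, center)
    k1, k2 = principal_curvatures(fit)
    assert k1 == pytest.approx(1.0, rel=0.05)
    assert abs(k2) < 0.05


@pytest.mark.parametrize(
    "a, b, c, expected",
    [
        (0.5, 0.0, 0.5, (1.0, 1.0)),
        (1.0, 0.0, 0.0, (2.0, 0.0)),
        (0.0, 0.5, 0.0, (1.0, -1.0)),
    ],
)
def test_principal_curvatures_closed_form(a, b, c, expected):
    fit = PatchFit(a=a, b=b, c=c, residual_rms=0.0, n_neighbors=6, ring_used=1)
    k1, k2 = principal_curvatures(fit)
    assert (k1, k2) == pytest.approx(expected, abs=1e-12)
    # oracle: eigenvalues of the patch Hessian [[2a, 2b], [2b, 2c]]
    eig = np.sort(np.linalg.eigvalsh(np.array([[2 * a, 2 * b], [2 * b, 2 * c]])))[::-1]
    assert (k1, k2) == pytest.approx(tuple(eig), abs=1e-12)


@pytest.mark.parametrize("radius", [1.0, 2.0])
def test_mean_curvature_sphere(radius):
    sph = synthetic.make_icosphere(radius, 4)
    M = mean_curvature_field(sph)
    assert np.median(M) == pytest.approx(1.0 / radius, rel=0.02)


def test_mean_curvature_flat(flat_grid):
    M = mean_curvature_field(flat_grid)
    interior = [i * 7 + j for i in range(2, 5) for j in range(2, 5)]
    assert np.max(np.abs(M[interior])) < 1e-8


def test_curvature_convergence_with_refinement():
    errs = []
    for s in (2, 3, 4):
        sph = synthetic.make_icosphere(1.0, s)
        errs.append(abs(np.median(mean_curvature_field(sph)) - 1.0))
    assert errs[0] > errs[1] > errs[2]


def test_curvature_change_inflation():
    sph = synthetic.make_icosphere(1.0, 4)
    deformed, _ = synthetic.deform(sph, synthetic.UniformInflation(1.1))
    dM = curvature_change(sph, deformed)
    assert np.median(dM) == pytest.approx(1.0 / 1.1 - 1.0, rel=0.03)


def test_curvature_change_rigid_is_null(rng):
    sph = synthetic.make_icosphere(1.0, 3)
    motion = synthetic.RigidMotion.random(rng)
    moved = sph.with_vertices(motion.map(sph.vertices))
    assert np.max(np.abs(curvature_change(sph, moved))) < 1e-6


# ---------------------------------------------------------------------------
# strain
# ---------------------------------------------------------------------------

def test_triangle_local_frame():
    e1, e2 = triangle_local_frame((0, 0, 0), (1, 0, 0), (0, 1, 0))
    assert np.allclose(e1, [1, 0, 0]) and np.allclose(e2, [0, 1, 0])
    with pytest.raises(ValueError):
        triangle_local_frame((0, 0, 0), (1, 0, 0), (2, 0, 0))


def test_triangle_strain_identity_scaling_rotation(rng):
    ref = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.5, 1.5, 0.0]])
    s = triangle_strain(ref, ref)
    assert np.allclose(s.E, 0, atol=1e-14)
    assert s.area_stretch[0] == pytest.approx(1.0, abs=1e-12)

    s = triangle_strain(ref, ref * 1.1)
    assert s.area_stretch[0] == pytest.approx(1.21, abs=1e-9)
    assert np.allclose(s.principal[0], (1.1**2 - 1) / 2, atol=1e-9)

    motion = synthetic.RigidMotion.random(rng)
    s = triangle_strain(ref, motion.map(ref))
    assert np.max(np.abs(s.principal)) < 1e-9
    assert s.area_stretch[0] == pytest.approx(1.0, abs=1e-9)


def test_triangle_strain_uniaxial():
    ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    stretched = ref * np.array([1.2, 1.0, 1.0])
    s = triangle_strain(ref, stretched)
    assert s.principal[0] == pytest.approx((0.22, 0.0), abs=1e-12)
    assert s.area_stretch[0] == pytest.approx(1.2, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_strain_matches_edge_length_oracle(seed):
    rng = np.random.default_rng(seed)
    ref = rng.normal(size=(3, 3))
    dfm = rng.normal(size=(3, 3))
    # reject degenerate draws
    if np.linalg.norm(np.cross(ref[1] - ref[0], ref[2] - ref[0])) < 1e-3:
        return
    if np.linalg.norm(np.cross(dfm[1] - dfm[0], dfm[2] - dfm[0])) < 1e-3:
        return
    s = triangle_strain(ref, dfm)
    oracle = edge_length_strain_oracle(ref, dfm)
    assert np.allclose(s.principal[0], oracle, atol=1e-9)
    # det(F) equals the area stretch
    detF = np.linalg.det(s.F[0])
    assert abs(abs(detF) - s.area_stretch[0]) < 1e-9


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_strain_frame_independence_cyclic(seed):
    rng = np.random.default_rng(seed)
    ref = rng.normal(size=(3, 3))
    dfm = rng.normal(size=(3, 3))
    if np.linalg.norm(np.cross(ref[1] - ref[0], ref[2] - ref[0])) < 1e-3:
        return
    if np.linalg.norm(np.cross(dfm[1] - dfm[0], dfm[2] - dfm[0])) < 1e-3:
        return
    base = triangle_strain(ref, dfm)
    perm = [1, 2, 0]
    cyc = triangle_strain(ref[perm], dfm[perm])
    assert np.allclose(base.principal, cyc.principal, atol=1e-9)
    assert np.allclose(base.area_stretch, cyc.area_stretch, atol=1e-9)


def test_mesh_strain_affine_matches_metric_restriction(icosphere_r10_s3):
    A = np.array([[1.15, 0.05, 0.0], [0.0, 1.0, 0.02], [0.0, 0.0, 0.95]])
    d = synthetic.AffineDeformation(A)
    deformed, expected = synthetic.deform(icosphere_r10_s3, d)
    s = mesh_strain(icosphere_r10_s3, deformed)
    assert np.allclose(s.principal, expected["triangle_principal_strains"], atol=1e-9)


def test_smooth_to_vertices():
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    tris = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    mesh = SurfaceMesh(verts, tris)
    const = smooth_to_vertices(np.full(4, 3.7), mesh)
    assert np.allclose(const, 3.7)
    # hand case: vertex incident to areas {1, 3} and values {0, 4} -> 3.0
    v2 = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0], [0, -3, 0]], dtype=float)
    t2 = np.array([[0, 1, 2], [0, 3, 1]])  # areas 1 and 3
    open_mesh = SurfaceMesh(v2, t2)
    out = smooth_to_vertices(np.array([0.0, 4.0]), open_mesh)
    assert out[1] == pytest.approx(3.0)


def test_compute_markers_identity_and_translation(icosphere_r10_s3):
    ms = compute_markers(icosphere_r10_s3, icosphere_r10_s3)
    assert np.allclose(ms.displacement_magnitude, 0)
    assert np.allclose(ms.curvature_change, 0, atol=1e-12)
    assert np.allclose(ms.area_stretch, 1, atol=1e-12)
    assert np.allclose(ms.max_principal_strain, 0, atol=1e-12)
    assert ms.volume_change_percent == pytest.approx(0.0)

    shifted = icosphere_r10_s3.with_vertices(icosphere_r10_s3.vertices + [5, 0, 0])
    ms = compute_markers(icosphere_r10_s3, shifted)
    assert np.allclose(ms.displacement_magnitude, 5.0)
    assert np.allclose(ms.area_stretch, 1, atol=1e-9)
    assert np.max(np.abs(ms.max_principal_strain)) < 1e-9


def test_compute_markers_similarity_laws():
    sph = synthetic.make_icosphere(10.0, 3)
    lam = 1.066
    deformed, _ = synthetic.deform(sph, synthetic.UniformInflation(lam))
    ms = compute_markers(sph, deformed)
    assert ms.volume_followup / ms.volume_baseline == pytest.approx(lam**3, abs=1e-6)
    assert ms.area_followup / ms.area_baseline == pytest.approx(lam**2, abs=1e-6)
    assert np.allclose(ms.area_stretch, lam**2, atol=1e-9)


def test_topology_mismatch_raises(icosphere_r10_s3):
    other = synthetic.make_icosphere(10.0, 2)
    with pytest.raises(ValueError, match="topology"):
        compute_markers(icosphere_r10_s3, other)
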