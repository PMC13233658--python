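"""Mechanical loading markers of a deforming surface.

Given a baseline mesh and a topology-identical deformed (follow-up) mesh,
this module computes the four node-wise mechanomarkers

* displacement magnitude  ||x_fu - x_bl||          [mm]
* mean-curvature change   dM = M_fu - M_bl          [1/mm]
* area stretch            lambda_A = A_def / A_ref  [-]
* maximum principal wall strain: largest eigenvalue of the Green-Lagrange
  membrane strain tensor E = 1/2 (F^T F - I)        [-]

plus scalar volume and surface-area change. Curvature is estimated by
least-squares fitting a quadratic height patch S(u,v) = a u^2 + 2 b u v
+ c v^2 to the k-ring neighbourhood of each vertex in its tangent frame;
the principal curvatures follow from the patch coefficients. Membrane
strain is computed per triangle from the 2x2 deformation gradient mapping
the reference edge matrix to the deformed one, each expressed in an
in-plane orthonormal frame, which makes rigid motions exactly strain-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import (
    SurfaceMesh,
    surface_area,
    enclosed_volume,
    triangle_areas,
    vertex_adjacency,
    vertex_neighbors,
    vertex_normals,
)

__all__ = [
    "PatchFit",
    "CurvatureResult",
    "TriangleStrain",
    "MarkerSet",
    "fit_patch",
    "principal_curvatures",
    "mean_curvature_field",
    "curvature_change",
    "triangle_local_frame",
    "triangle_strain",
    "mesh_strain",
    "smooth_to_vertices",
    "compute_markers",
]

DEFAULT_RING = 1
MAX_RING = 3
MIN_NEIGHBORS = 5  # expand the ring below this; 3 unknowns need >= 3 rows


@dataclass(frozen=True)
class PatchFit:
    """Quadratic height-patch coefficients at one vertex (units 1/mm)."""
    a: float
    b: float
    c: float
    residual_rms: float
    n_neighbors: int
    ring_used: int


@dataclass(frozen=True)
class CurvatureResult:
    """Per-vertex principal curvatures (k1 >= k2) and mean curvature M."""
    k1: np.ndarray
    k2: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.k1 + self.k2)


@dataclass(frozen=True)
class TriangleStrain:
    """Per-triangle membrane kinematics.

    F : (m, 2, 2) deformation gradient in the local frames
    E : (m, 2, 2) Green-Lagrange strain, symmetric
    principal : (m, 2) eigenvalues of E, descending
    area_stretch : (m,) deformed/reference triangle area ratio
    """
    F: np.ndarray
    E: np.ndarray
    principal: np.ndarray
    area_stretch: np.ndarray

    @property
    def max_principal(self) -> np.ndarray:
        return self.principal[:, 0]


@dataclass(frozen=True)
class MarkerSet:
    """All node-wise markers plus configuration scalars for one subject."""
    mesh: SurfaceMesh
    displacement_magnitude: np.ndarray  # mm, per vertex
    curvature_change: np.ndarray        # 1/mm, per vertex
    area_stretch: np.ndarray            # -, per vertex (area-weight smoothed)
    max_principal_strain: np.ndarray    # -, per vertex (area-weight smoothed)
    volume_baseline: float              # cm^3
    volume_followup: float              # cm^3
    area_baseline: float                # cm^2
    area_followup: float                # cm^2

    @property
    def volume_change_percent(self) -> float:
        return 100.0 * (self.volume_followup / self.volume_baseline - 1.0)

    @property
    def area_change_percent(self) -> float:
        return 100.0 * (self.area_followup / self.area_baseline - 1.0)

    def as_table(self) -> dict[str, np.ndarray]:
        return {
            "displacement_magnitude": self.displacement_magnitude,
            "curvature_change": self.curvature_change,
            "area_stretch": self.area_stretch,
            "max_principal_strain": self.max_principal_strain,
        }

    def summary(self) -> dict[str, float]:
        out = {
            "volume_baseline_cm3": self.volume_baseline,
            "volume_followup_cm3": self.volume_followup,
            "volume_change_percent": self.volume_change_percent,
            "area_baseline_cm2": self.area_baseline,
            "area_followup_cm2": self.area_followup,
            "area_change_percent": self.area_change_percent,
        }
        for k, v in self.as_table().items():
            out[f"{k}_mean"] = float(np.mean(v))
            out[f"{k}_sd"] = float(np.std(v, ddof=1))
        return out


# ---------------------------------------------------------------------------
# curvature by quadratic patch fitting
# ---------------------------------------------------------------------------

def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Any orthonormal tangent pair (t1, t2) with t1 x t2 = normal."""
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(a, normal)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def fit_patch(
    mesh: SurfaceMesh,
    vertex: int,
    normals: np.ndarray | None = None,
    ring: int = DEFAULT_RING,
    adjacency: list[list[int]] | None = None,
) -> PatchFit:
    """Least-squares quadratic patch at one vertex.

    Neighbour offsets d are projected onto the tangent frame, u = d.t1,
    v = d.t2, and the height w = -d.n is measured along the *inward* normal
    so a convex outward-bulging surface gets positive curvature. The ring is
    expanded (up to MAX_RING) while fewer than MIN_NEIGHBORS usable
    neighbours are available or the system is rank-deficient.
    """
    if normals is None:
        normals = vertex_normals(mesh)
    n = normals[vertex]
    t1, t2 = _tangent_frame(n)
    last_err = None
    for r in range(ring, MAX_RING + 1):
        nbrs = vertex_neighbors(mesh, r, adjacency=adjacency)[vertex] \
            if adjacency is not None else vertex_neighbors(mesh, r)[vertex]
        fit = _solve_patch(mesh.vertices, vertex, nbrs, t1, t2, n, r)
        if fit is not None:
            if fit.n_neighbors >= MIN_NEIGHBORS or r == MAX_RING:
                return fit
            last_err = None
        else:
            last_err = f"rank-deficient patch system at vertex {vertex}, ring {r}"
    raise np.linalg.LinAlgError(
        last_err or f"patch fit failed at vertex {vertex} up to ring {MAX_RING}"
    )


def _solve_patch(vertices, vertex, nbrs, t1, t2, n, ring_used) -> PatchFit | None:
    d = vertices[nbrs] - vertices[vertex]
    u = d @ t1
    v = d @ t2
    w = -(d @ n)
    A = np.column_stack([u * u, 2.0 * u * v, v * v])
    if len(nbrs) < 3 or np.linalg.matrix_rank(A, tol=1e-10) < 3:
        return None
    coef, _, _, _ = np.linalg.lstsq(A, w, rcond=None)
    resid = A @ coef - w
    return PatchFit(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_neighbors=len(nbrs), ring_used=ring_used,
    )


def principal_curvatures(fit: PatchFit) -> tuple[float, float]:
    """Principal curvatures from the patch coefficients.

    k1 = a + c + sqrt((a - c)^2 + 4 b^2),  k2 = a + c - sqrt(...).
    These are the eigenvalues of the height-patch Hessian [[2a, 2b], [2b, 2c]].
    """
    s = np.sqrt((fit.a - fit.c) ** 2 + 4.0 * fit.b**2)
    return fit.a + fit.c + s, fit.a + fit.c - s


def curvature_field(mesh: SurfaceMesh, ring: int = DEFAULT_RING,
                    normals: np.ndarray | None = None) -> CurvatureResult:
    """Principal curvatures at every vertex."""
    if normals is None:
        normals = vertex_normals(mesh)
    adjacency = vertex_adjacency(mesh)
    # precompute all rings once instead of per vertex
    rings = {r: vertex_neighbors(mesh, r, adjacency=adjacency)
             for r in range(ring, MAX_RING + 1)}
    k1 = np.empty(mesh.n_vertices)
    k2 = np.empty(mesh.n_vertices)
    for i in range(mesh.n_vertices):
        n = normals[i]
        t1, t2 = _tangent_frame(n)
        fit = None
        for r in range(ring, MAX_RING + 1):
            fit = _solve_patch(mesh.vertices, i, rings[r][i], t1, t2, n, r)
            if fit is not None and (fit.n_neighbors >= MIN_NEIGHBORS or r == MAX_RING):
                break
            if fit is not None and r < MAX_RING:
                fit = None  # too few neighbours; expand
        if fit is None:
            raise np.linalg.LinAlgError(f"patch fit failed at vertex {i}")
        k1[i], k2[i] = principal_curvatures(fit)
    return CurvatureResult(k1=k1, k2=k2)


def mean_curvature_field(mesh: SurfaceMesh, ring: int = DEFAULT_RING,
                         normals: np.ndarray | None = None) -> np.ndarray:
    """Per-vertex mean curvature M = (k1 + k2)/2 = a + c  [1/mm]."""
    return curvature_field(mesh, ring=ring, normals=normals).mean


def curvature_change(baseline: SurfaceMesh, followup: SurfaceMesh,
                     ring: int = DEFAULT_RING) -> np.ndarray:
    """dM = M_followup - M_baseline per vertex; negative means flattening."""
    _check_same_topology(baseline, followup)
    return mean_curvature_field(followup, ring=ring) - mean_curvature_field(
        baseline, ring=ring
    )


# ---------------------------------------------------------------------------
# membrane strain
# ---------------------------------------------------------------------------

def triangle_local_frame(p1, p2, p3) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal in-plane basis: e1 along p2-p1, e2 = n x e1."""
    p1 = np.asarray(p1, dtype=np.float64)
    e1 = np.asarray(p2, dtype=np.float64) - p1
    n = np.cross(e1, np.asarray(p3, dtype=np.float64) - p1)
    nn = np.linalg.norm(n)
    if nn < 1e-14 or np.linalg.norm(e1) < 1e-14:
        raise ValueError("degenerate triangle")
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n / nn, e1)
    return e1, e2


def _edge_matrix_2d(p1, p2, p3) -> np.ndarray:
    """2x2 edge matrix [p2-p1, p3-p1] in the triangle's local frame."""
    e1, e2 = triangle_local_frame(p1, p2, p3)
    d2 = np.asarray(p2, dtype=np.float64) - p1
    d3 = np.asarray(p3, dtype=np.float64) - p1
    return np.array([[d2 @ e1, d3 @ e1], [d2 @ e2, d3 @ e2]])


def _eig2_sym_desc(E: np.ndarray) -> tuple[float, float]:
    """Closed-form eigenvalues of a symmetric 2x2, descending."""
    tr = E[0, 0] + E[1, 1]
    disc = np.sqrt(max((E[0, 0] - E[1, 1]) ** 2 + 4.0 * E[0, 1] ** 2, 0.0)) / 2.0
    return tr / 2.0 + disc, tr / 2.0 - disc


def triangle_strain(ref_tri, def_tri) -> TriangleStrain:
    """Green-Lagrange membrane strain of a single triangle.

    F = x . X^{-1} with X, x the 2x2 edge matrices in the reference and
    deformed in-plane frames; E = 1/2 (F^T F - I); principal strains are the
    eigenvalues of E, and the area stretch is det(F) (= area ratio for
    orientation-preserving maps).
    """
    ref_tri = np.asarray(ref_tri, dtype=np.float64)
    def_tri = np.asarray(def_tri, dtype=np.float64)
    X = _edge_matrix_2d(*ref_tri)
    x = _edge_matrix_2d(*def_tri)
    detX = X[0, 0] * X[1, 1] - X[0, 1] * X[1, 0]
    if abs(detX) < 1e-14:
        raise ValueError("singular reference edge matrix (degenerate triangle)")
    F = x @ np.linalg.inv(X)
    E = 0.5 * (F.T @ F - np.eye(2))
    lam = _eig2_sym_desc(E)
    lam_A = abs(F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0])
    return TriangleStrain(
        F=F[None], E=E[None],
        principal=np.array([lam]), area_stretch=np.array([lam_A]),
    )


def mesh_strain(baseline: SurfaceMesh, followup: SurfaceMesh) -> TriangleStrain:
    """Vectorised per-triangle strain for a topology-identical mesh pair."""
    _check_same_topology(baseline, followup)
    X = _all_edge_matrices(baseline)
    x = _all_edge_matrices(followup)
    detX = X[:, 0, 0] * X[:, 1, 1] - X[:, 0, 1] * X[:, 1, 0]
    if np.any(np.abs(detX) < 1e-14):
        bad = np.nonzero(np.abs(detX) < 1e-14)[0]
        raise ValueError(f"degenerate reference triangles: {bad[:10].tolist()}")
    Xinv = np.empty_like(X)
    Xinv[:, 0, 0] = X[:, 1, 1]
    Xinv[:, 1, 1] = X[:, 0, 0]
    Xinv[:, 0, 1] = -X[:, 0, 1]
    Xinv[:, 1, 0] = -X[:, 1, 0]
    Xinv /= detX[:, None, None]
    F = x @ Xinv
    E = 0.5 * (np.transpose(F, (0, 2, 1)) @ F - np.eye(2))
    tr = E[:, 0, 0] + E[:, 1, 1]
    disc = 0.5 * np.sqrt(np.maximum((E[:, 0, 0] - E[:, 1, 1]) ** 2
                                    + 4.0 * E[:, 0, 1] ** 2, 0.0))
    principal = np.stack([tr / 2.0 + disc, tr / 2.0 - disc], axis=1)
    lam_A = np.abs(F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0])
    return TriangleStrain(F=F, E=E, principal=principal, area_stretch=lam_A)


def _all_edge_matrices(mesh: SurfaceMesh) -> np.ndarray:
    v = mesh.vertices[mesh.triangles]
    d2 = v[:, 1] - v[:, 0]
    d3 = v[:, 2] - v[:, 0]
    n = np.cross(d2, d3)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    e1 = d2 / np.linalg.norm(d2, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    X = np.empty((len(v), 2, 2))
    X[:, 0, 0] = np.einsum("ij,ij->i", d2, e1)
    X[:, 0, 1] = np.einsum("ij,ij->i", d3, e1)
    X[:, 1, 0] = np.einsum("ij,ij->i", d2, e2)
    X[:, 1, 1] = np.einsum("ij,ij->i", d3, e2)
    return X


def smooth_to_vertices(elem_field: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted average of an element field onto vertices.

    Weights are the *undeformed* triangle areas of ``mesh`` (the reference
    configuration), consistent with strain measures referred to it.
    """
    elem_field = np.asarray(elem_field, dtype=np.float64)
    if len(elem_field) != mesh.n_triangles:
        raise ValueError("element field length does not match mesh")
    areas = triangle_areas(mesh)
    num = np.zeros(mesh.n_vertices)
    den = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(num, mesh.triangles[:, k], areas * elem_field)
        np.add.at(den, mesh.triangles[:, k], areas)
    return num / den


def compute_markers(baseline: SurfaceMesh, followup: SurfaceMesh,
                    ring: int = DEFAULT_RING) -> MarkerSet:
    """Assemble the full marker set for one baseline/follow-up mesh pair."""
    _check_same_topology(baseline, followup)
    disp = np.linalg.norm(followup.vertices - baseline.vertices, axis=1)
    dM = curvature_change(baseline, followup, ring=ring)
    strain = mesh_strain(baseline, followup)
    return MarkerSet(
        mesh=baseline,
        displacement_magnitude=disp,
        curvature_change=dM,
        area_stretch=smooth_to_vertices(strain.area_stretch, baseline),
        max_principal_strain=smooth_to_vertices(strain.max_principal, baseline),
        volume_baseline=enclosed_volume(baseline) / 1000.0,
        volume_followup=enclosed_volume(followup) / 1000.0,
        area_baseline=surface_area(baseline) / 100.0,
        area_followup=surface_area(followup) / 100.0,
    )


def _check_same_topology(a: SurfaceMesh, b: SurfaceMesh) -> None:
    if a.n_vertices != b.n_vertices or not np.array_equal(a.triangles, b.triangles):
        raise ValueError("meshes do not share topology")
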