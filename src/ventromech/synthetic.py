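"""Synthetic surfaces, deformations, volumes, and cohorts with closed-form
expected marker values.

Every other module is testable against these generators without any imaging
data: analytic deformations (uniform inflation, affine, rigid, radial bump)
of spheres and ellipsoids have closed-form displacement, area stretch,
membrane strain, and curvature change; deformations can be rasterised into
displacement volumes that emulate registration warp fields; bright-cap
intensity volumes emulate periventricular FLAIR hyperintensities; and
multi-subject cohorts with random expansion factors emulate the longitudinal
study structure (balanced female/male groups, expansions of a few percent
producing ~1 mm wall displacements on a ventricle-scale shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_core import SurfaceMesh
from .imagefield import DisplacementVolume, ScalarVolume

__all__ = [
    "UniformInflation",
    "AffineDeformation",
    "RigidMotion",
    "RadialBump",
    "SubjectRecord",
    "SyntheticCohort",
    "make_icosphere",
    "make_ellipsoid",
    "make_ventricle_like",
    "deform",
    "default_grid",
    "rasterize_displacement",
    "make_flair_like",
    "make_cohort",
]

# Cohort defaults: a ~11.5 cm^3 sphere of radius 14 mm expanded by a factor
# drawn around 1.066 gives ~+21% volume and ~0.9 mm wall displacement with a
# ~0.45 mm spread, matching the magnitudes the markers are designed for.
DEFAULT_RADIUS_MM = 14.0
DEFAULT_LAMBDA_MEAN = 1.066
DEFAULT_LAMBDA_SD = 0.03      # SD of ln(lambda)
DEFAULT_NOISE_SD = 0.05       # mm, per-vertex displacement noise


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def make_icosphere(radius: float = 1.0, subdivisions: int = 3,
                   center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Subdivided icosahedron: 10 * 4**s + 2 vertices, all at distance R."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in 0..6")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices) + np.asarray(center, dtype=np.float64),
                       np.asarray(tm.faces))


def make_ellipsoid(a: float, b: float, c: float, subdivisions: int = 3,
                   center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Icosphere scaled anisotropically to semi-axes (a, b, c)."""
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    sph = make_icosphere(1.0, subdivisions)
    v = sph.vertices * np.array([a, b, c]) + np.asarray(center, dtype=np.float64)
    return sph.with_vertices(v)


def make_ventricle_like(seed: int = 0, subdivisions: int = 3) -> tuple[SurfaceMesh, dict]:
    """A bent elongated closed surface with labelled anatomical-style regions.

    An ellipsoid with semi-axes (8, 20, 6) mm is bent along its long axis so
    the +y cap stands in for the anterior horn and the -y cap for the atrium;
    the tight caps have markedly higher mean curvature than the flat body,
    which is what horn-vs-body marker contrasts exercise. Labels
    {anterior_horn, atrium, edge, body_superior, body_inferior} partition the
    vertices. The seed jitters vertex positions by a fraction of the edge
    length so repeated meshes are not bit-identical surfaces.
    """
    rng = np.random.default_rng(seed)
    ell = make_ellipsoid(8.0, 20.0, 6.0, subdivisions)
    v = ell.vertices.copy()
    # gentle bend of the long axis: x offset quadratic in y
    v[:, 0] += 0.01 * v[:, 1] ** 2
    v += rng.normal(0.0, 0.02, size=v.shape)
    mesh = ell.with_vertices(v).validate()
    y = v[:, 1]
    xc = v[:, 0] - 0.01 * y**2
    labels = {}
    horn = y > 15.0
    atrium = y < -15.0
    edge = (~horn) & (~atrium) & (np.abs(xc) > 6.0)
    body_sup = (~horn) & (~atrium) & (~edge) & (v[:, 2] >= 0)
    body_inf = (~horn) & (~atrium) & (~edge) & (v[:, 2] < 0)
    labels["anterior_horn"] = np.nonzero(horn)[0]
    labels["atrium"] = np.nonzero(atrium)[0]
    labels["edge"] = np.nonzero(edge)[0]
    labels["body_superior"] = np.nonzero(body_sup)[0]
    labels["body_inferior"] = np.nonzero(body_inf)[0]
    return mesh, labels


# ---------------------------------------------------------------------------
# analytic deformations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformInflation:
    """x -> center + lambda (x - center); isotropic expansion."""
    lambda_: float
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")

    def map(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=np.float64)
        return c + self.lambda_ * (np.asarray(points, dtype=np.float64) - c)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return self.map(points) - np.asarray(points, dtype=np.float64)


@dataclass(frozen=True)
class AffineDeformation:
    """x -> A x + t."""
    matrix: np.ndarray
    translation: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("matrix must be an invertible 3x3")
        object.__setattr__(self, "matrix", m)

    def map(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) @ self.matrix.T
                + np.asarray(self.translation, dtype=np.float64))

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return self.map(points) - np.asarray(points, dtype=np.float64)


@dataclass(frozen=True)
class RigidMotion(AffineDeformation):
    """x -> R x + t with R a proper rotation; all markers are null."""

    def __post_init__(self):
        super().__post_init__()
        R = self.matrix
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")

    @staticmethod
    def random(rng: np.random.Generator, max_translation: float = 10.0) -> "RigidMotion":
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, 3)
        return RigidMotion(matrix=R, translation=tuple(t))


@dataclass(frozen=True)
class RadialBump:
    """Localised Gaussian radial expansion around a centre point.

    x -> x + amplitude * exp(-|x - c|^2 / (2 width^2)) * (x - c)/|x - c|
    """
    center: tuple
    amplitude: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        d = p - np.asarray(self.center, dtype=np.float64)
        r = np.linalg.norm(d, axis=-1, keepdims=True)
        safe = np.where(r > 1e-12, r, 1.0)
        return self.amplitude * np.exp(-(r**2) / (2.0 * self.width**2)) * d / safe

    def map(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) + self.displacement(points)


def _sphere_radius(mesh: SurfaceMesh, center) -> float | None:
    r = np.linalg.norm(mesh.vertices - np.asarray(center, dtype=np.float64), axis=1)
    if np.ptp(r) < 1e-6 * r.mean():
        return float(r.mean())
    return None


def deform(mesh: SurfaceMesh, deformation) -> tuple[SurfaceMesh, dict]:
    """Apply an analytic deformation; return the deformed mesh and the
    closed-form expected marker values where they exist.

    Uniform inflation by lambda: area stretch lambda^2, max principal strain
    (lambda^2 - 1)/2, volume ratio lambda^3 on any shape; on a sphere of
    radius R about the inflation centre additionally displacement
    (lambda - 1) R and curvature change (1/lambda - 1)/R. Rigid motions have
    all markers null. Affine maps A have per-triangle Green-Lagrange strain
    equal to the restriction of 1/2 (A^T A - I) to each triangle plane; the
    expected per-triangle principal strains are computed here from the
    *metric* (first fundamental form), independently of the deformation-
    gradient pathway used by the marker code.
    """
    deformed = mesh.with_vertices(deformation.map(mesh.vertices))
    expected: dict = {}
    if isinstance(deformation, RigidMotion):
        expected = {
            "displacement": None,  # rigid translation/rotation dependent
            "area_stretch": 1.0,
            "max_principal_strain": 0.0,
            "curvature_change": 0.0,
            "volume_ratio": 1.0,
            "area_ratio": 1.0,
        }
    elif isinstance(deformation, UniformInflation):
        lam = deformation.lambda_
        expected = {
            "area_stretch": lam**2,
            "max_principal_strain": (lam**2 - 1.0) / 2.0,
            "volume_ratio": lam**3,
            "area_ratio": lam**2,
        }
        R = _sphere_radius(mesh, deformation.center)
        if R is not None:
            expected["displacement"] = abs(lam - 1.0) * R
            expected["curvature_change"] = (1.0 / lam - 1.0) / R
    elif isinstance(deformation, AffineDeformation):
        expected = {
            "volume_ratio": abs(float(np.linalg.det(deformation.matrix))),
            "triangle_principal_strains": _affine_triangle_strains(
                mesh, deformation.matrix),
        }
    return deformed, expected


def _affine_triangle_strains(mesh: SurfaceMesh, A: np.ndarray) -> np.ndarray:
    """Per-triangle principal strains of x -> A x from the surface metric.

    For a tangent basis (t1, t2) of the triangle plane, the restricted
    right Cauchy-Green tensor is C_ab = t_a^T (A^T A) t_b and the membrane
    strain is 1/2 (C - I); eigenvalues are returned descending.
    """
    v = mesh.vertices[mesh.triangles]
    d2 = v[:, 1] - v[:, 0]
    d3 = v[:, 2] - v[:, 0]
    n = np.cross(d2, d3)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    t1 = d2 / np.linalg.norm(d2, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    AtA = A.T @ A
    c11 = np.einsum("ij,jk,ik->i", t1, AtA, t1)
    c12 = np.einsum("ij,jk,ik->i", t1, AtA, t2)
    c22 = np.einsum("ij,jk,ik->i", t2, AtA, t2)
    e11 = 0.5 * (c11 - 1.0)
    e12 = 0.5 * c12
    e22 = 0.5 * (c22 - 1.0)
    tr = e11 + e22
    disc = 0.5 * np.sqrt(np.maximum((e11 - e22) ** 2 + 4.0 * e12**2, 0.0))
    return np.stack([tr / 2.0 + disc, tr / 2.0 - disc], axis=1)


# ---------------------------------------------------------------------------
# volume rasterisation
# ---------------------------------------------------------------------------

def default_grid(mesh: SurfaceMesh, spacing: float = 1.0,
                 margin: float = 5.0) -> tuple[tuple[int, int, int], np.ndarray]:
    """Axis-aligned voxel grid (shape, affine) covering a mesh with margin."""
    lo = mesh.vertices.min(axis=0) - margin
    hi = mesh.vertices.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = lo
    return shape, affine


def rasterize_displacement(deformation, shape, affine) -> DisplacementVolume:
    """Sample an analytic deformation's displacement at every voxel centre."""
    shape = tuple(int(s) for s in shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    affine = np.asarray(affine, dtype=np.float64)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    disp = deformation.displacement(world).reshape(*shape, 3)
    return DisplacementVolume(disp, affine)


def make_flair_like(mesh: SurfaceMesh, bright_vertices, contrast: float = 0.5,
                    noise_sd: float = 0.0, seed: int = 0,
                    spacing: float = 0.5, margin: float = 3.0,
                    background: float = 100.0) -> ScalarVolume:
    """Intensity volume with a bright periventricular shell at labelled vertices.

    The volume is ``background`` everywhere except in a one-voxel-thick shell
    (the 3x3x3 voxel neighbourhood) stamped around each bright vertex, which
    gets ``background * (1 + contrast)``. On a 0.5 mm grid the shell extends
    beyond the trilinear support of the stamped vertex, so with zero noise
    bright vertices sample exactly the bright value and — provided unlabelled
    vertices sit more than ~2 mm away — all other vertices sample exactly the
    background. Gaussian noise (SD ``noise_sd``) is added last, seeded.
    """
    shape, affine = default_grid(mesh, spacing=spacing, margin=margin)
    data = np.full(shape, background, dtype=np.float64)
    bright = np.asarray(sorted(set(int(i) for i in bright_vertices)), dtype=np.int64)
    inv = np.linalg.inv(affine)
    vox = np.round(mesh.vertices[bright] @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    value = background * (1.0 + contrast)
    for c in vox:
        lo = np.maximum(c - 1, 0)
        hi = np.minimum(c + 2, shape)
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = value
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return ScalarVolume(data, affine)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: shared-topology baseline and follow-up meshes."""
    subject_id: str
    sex: str                      # 'F' or 'M'
    lambda_: float                # expansion factor actually applied
    baseline: SurfaceMesh
    followup: SurfaceMesh
    seed: int


@dataclass(frozen=True)
class SyntheticCohort:
    """Reproducible multi-subject cohort of expansile deformations."""
    subjects: list
    master_seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def sexes(self) -> np.ndarray:
        return np.asarray([s.sex for s in self.subjects])


def _subject_rng(master_seed: int, index: int) -> np.random.Generator:
    # spawn-key derivation: subjects are independent and order-insensitive
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def make_cohort(n: int = 50,
                sex_effect: float = 0.0,
                lambda_mean: float = DEFAULT_LAMBDA_MEAN,
                lambda_sd: float = DEFAULT_LAMBDA_SD,
                noise_sd: float = DEFAULT_NOISE_SD,
                master_seed: int = 0,
                radius: float = DEFAULT_RADIUS_MM,
                subdivisions: int = 3,
                baseline: SurfaceMesh | None = None) -> SyntheticCohort:
    """Generate a balanced female/male cohort of random uniform expansions.

    Per subject, the expansion factor is lognormal,
    lambda ~ exp(N(ln lambda_mean, lambda_sd)), plus an additive
    ``sex_effect`` on lambda for male subjects; follow-up vertices get
    i.i.d. Gaussian displacement noise (SD ``noise_sd`` mm). All subjects
    share the baseline mesh topology. Reproducible from ``master_seed`` via
    per-subject spawn keys.
    """
    if n % 2 != 0:
        raise ValueError("n must be even for balanced sexes")
    if lambda_mean <= 0 or lambda_sd < 0 or noise_sd < 0:
        raise ValueError("invalid distribution parameters")
    if baseline is None:
        baseline = make_icosphere(radius, subdivisions)
    subjects = []
    for i in range(n):
        rng = _subject_rng(master_seed, i)
        sex = "F" if i < n // 2 else "M"
        lam = float(np.exp(rng.normal(np.log(lambda_mean), lambda_sd)))
        if sex == "M":
            lam += sex_effect
        fu = baseline.vertices * lam
        if noise_sd > 0:
            fu = fu + rng.normal(0.0, noise_sd, size=fu.shape)
        subjects.append(SubjectRecord(
            subject_id=f"S{i:03d}", sex=sex, lambda_=lam,
            baseline=baseline, followup=baseline.with_vertices(fu),
            seed=i,
        ))
    return SyntheticCohort(
        subjects=subjects, master_seed=master_seed,
        params={"n": n, "sex_effect": sex_effect, "lambda_mean": lambda_mean,
                "lambda_sd": lambda_sd, "noise_sd": noise_sd,
                "radius": radius, "subdivisions": subdivisions},
    )
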