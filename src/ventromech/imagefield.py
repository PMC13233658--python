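"""Volumetric images, warp-field sampling of meshes, and comparison metrics.

Volumes are NIfTI-style: a 3-D (scalar) or 4-D with last axis 3
(displacement, mm in the world frame) data grid plus a 4x4 voxel-to-world
affine; world coordinates are RAS millimetres. A displacement volume maps a
baseline point p to its follow-up position p + d(p), which is how nonlinear
registration warp fields are consumed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree

from .mesh_core import SurfaceMesh

__all__ = [
    "ScalarVolume",
    "DisplacementVolume",
    "BinaryMask",
    "OutOfBoundsError",
    "sample",
    "warp_mesh",
    "apply_affine",
    "dice",
    "hausdorff",
    "assd",
    "transfer_field",
    "nrmse",
]


class OutOfBoundsError(ValueError):
    """A sample point fell outside the volume's voxel grid."""

    def __init__(self, indices):
        self.indices = np.asarray(indices)
        super().__init__(
            f"{len(self.indices)} point(s) outside volume domain, "
            f"first indices: {self.indices[:10].tolist()}"
        )


@dataclass(frozen=True)
class _Volume:
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=np.float64)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if min(self.data.shape[:3]) < 2:
            raise ValueError("grid must have at least 2 voxels per axis")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "data", np.asarray(self.data))

    @property
    def shape(self):
        return self.data.shape[:3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass(frozen=True)
class ScalarVolume(_Volume):
    """3-D scalar grid with voxel-to-world affine (world = RAS mm)."""

    def __post_init__(self):
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError("ScalarVolume data must be 3-D")

    @classmethod
    def load(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine)


@dataclass(frozen=True)
class DisplacementVolume(_Volume):
    """3-D grid of world-frame displacement 3-vectors (mm)."""

    def __post_init__(self):
        super().__post_init__()
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("DisplacementVolume data must be (i, j, k, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement components must be finite")

    @classmethod
    def load(cls, path) -> "DisplacementVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        data = np.squeeze(data)  # tolerate FSL-style (i,j,k,1,3)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError("expected a 4-D NIfTI with last dimension 3")
        return cls(data, img.affine)


@dataclass(frozen=True)
class BinaryMask(_Volume):
    """3-D boolean grid with voxel-to-world affine."""

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data).astype(bool))
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError("BinaryMask data must be 3-D")

    @classmethod
    def load(cls, path) -> "BinaryMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0.5, img.affine)


# ---------------------------------------------------------------------------
# sampling and warping
# ---------------------------------------------------------------------------

def sample(volume: ScalarVolume | DisplacementVolume, points,
           out_of_bounds: str = "raise") -> np.ndarray:
    """Trilinear interpolation of a volume at world-mm points.

    Points are mapped through the inverse affine into voxel space; vector
    volumes are interpolated component-wise. ``out_of_bounds`` is ``raise``
    (default) or ``clamp`` (nearest-edge).
    """
    if out_of_bounds not in ("raise", "clamp"):
        raise ValueError("out_of_bounds must be 'raise' or 'clamp'")
    vox = volume.world_to_voxel(points)
    shape = np.asarray(volume.shape, dtype=np.float64)
    oob = np.any((vox < -1e-9) | (vox > shape - 1 + 1e-9), axis=1)
    if np.any(oob):
        if out_of_bounds == "raise":
            raise OutOfBoundsError(np.nonzero(oob)[0])
    coords = np.clip(vox, 0.0, shape - 1).T
    if volume.data.ndim == 3:
        return ndimage.map_coordinates(volume.data, coords, order=1, mode="nearest")
    out = np.empty((len(vox), volume.data.shape[3]))
    for k in range(volume.data.shape[3]):
        out[:, k] = ndimage.map_coordinates(volume.data[..., k], coords,
                                            order=1, mode="nearest")
    return out


def warp_mesh(mesh: SurfaceMesh, warp: DisplacementVolume,
              out_of_bounds: str = "raise") -> tuple[SurfaceMesh, np.ndarray]:
    """Deform a mesh by a registration warp field.

    Each vertex is moved by the trilinearly sampled displacement; returns
    both the deformed mesh and the per-vertex displacement field (mm).
    """
    disp = sample(warp, mesh.vertices, out_of_bounds=out_of_bounds)
    return mesh.with_vertices(mesh.vertices + disp), disp


def apply_affine(mesh: SurfaceMesh, matrix: np.ndarray) -> SurfaceMesh:
    """Homogeneous 4x4 transform of mesh vertices."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape != (4, 4) or abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
        raise ValueError("matrix must be an invertible 4x4 affine")
    return mesh.with_vertices(mesh.vertices @ matrix[:3, :3].T + matrix[:3, 3])


# ---------------------------------------------------------------------------
# segmentation-comparison metrics
# ---------------------------------------------------------------------------

def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape or not np.allclose(a.affine, b.affine):
        raise ValueError("masks must share grid shape and affine")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|)."""
    _check_same_grid(a, b)
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


_SIX = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _boundary_points(mask: BinaryMask) -> np.ndarray:
    """World-mm centres of mask voxels with a 6-connected background neighbour."""
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    interior = ndimage.binary_erosion(m, structure=_SIX, border_value=0)
    boundary = m & ~interior
    return mask.voxel_to_world(np.argwhere(boundary))


def _directed_nn(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(b_pts).query(a_pts)
    return d


def hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance (mm) between boundary-voxel centres."""
    _check_same_grid(a, b)
    pa, pb = _boundary_points(a), _boundary_points(b)
    return max(float(_directed_nn(pa, pb).max()), float(_directed_nn(pb, pa).max()))


def assd(a: BinaryMask, b: BinaryMask) -> float:
    """Average symmetric surface distance (mm): mean over both directions'
    pooled nearest-neighbour boundary distances."""
    _check_same_grid(a, b)
    pa, pb = _boundary_points(a), _boundary_points(b)
    d_ab = _directed_nn(pa, pb)
    d_ba = _directed_nn(pb, pa)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


# ---------------------------------------------------------------------------
# cross-resolution field transfer and error
# ---------------------------------------------------------------------------

def transfer_field(src_mesh: SurfaceMesh, src_field: np.ndarray,
                   dst_mesh: SurfaceMesh) -> np.ndarray:
    """Resample a vertex field from one mesh onto another.

    Scattered linear (Delaunay-based) interpolation of the source vertex
    values at the destination vertex positions, with a nearest-neighbour
    fallback outside the source convex hull.
    """
    src_field = np.asarray(src_field, dtype=np.float64)
    if len(src_field) != src_mesh.n_vertices:
        raise ValueError("source field length does not match source mesh")
    if src_mesh.n_vertices == 0:
        raise ValueError("empty source mesh")
    pts = src_mesh.vertices
    out = LinearNDInterpolator(pts, src_field)(dst_mesh.vertices)
    missing = ~np.isfinite(out) if out.ndim == 1 else ~np.isfinite(out).all(axis=1)
    if np.any(missing):
        nn = NearestNDInterpolator(pts, src_field)
        out[missing] = nn(dst_mesh.vertices[missing])
    return out


def nrmse(ref_field: np.ndarray, test_field: np.ndarray) -> float:
    """Root-mean-square error normalised by the reference field's range."""
    ref = np.asarray(ref_field, dtype=np.float64)
    test = np.asarray(test_field, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError("fields must have the same shape")
    rng = float(ref.max() - ref.min())
    if rng == 0.0:
        raise ValueError("reference field has zero range")
    return float(np.sqrt(np.mean((test - ref) ** 2)) / rng)
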