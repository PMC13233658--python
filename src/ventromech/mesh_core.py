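"""Triangle-mesh data model, geometry primitives, and mesh/field I/O.

All coordinates are world millimetres in the RAS convention (x increases to
the subject's right, y anterior, z superior). Meshes are closed, consistently
oriented 2-manifolds with outward-pointing normals; the same vertex/triangle
topology is shared between the baseline and follow-up configurations so that
fields can be compared node-wise.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "MeshValidationError",
    "triangle_area",
    "tetra_volume",
    "surface_area",
    "enclosed_volume",
    "vertex_normals",
    "vertex_neighbors",
    "apply_displacement",
    "read_mesh",
    "write_mesh",
    "read_field",
    "write_field",
]

#: triangles below this area (mm^2) are considered degenerate
DEGENERATE_AREA = 1e-12


class MeshValidationError(ValueError):
    """Raised when a mesh violates the closed-manifold contract."""


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm, RAS world coordinates.
    triangles : (m, 3) int array of 0-based vertex indices with consistent
        winding (counter-clockwise seen from outside for outward normals).
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if t.ndim != 2 or t.shape[1] != 3:
            raise MeshValidationError(f"triangles must be (m, 3), got {t.shape}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same topology with replaced coordinates."""
        vertices = np.asarray(vertices, dtype=np.float64)
        if vertices.shape != self.vertices.shape:
            raise ValueError("replacement vertices must match shape")
        return replace(self, vertices=vertices)

    def validate(self, require_closed: bool = True) -> "SurfaceMesh":
        """Check the closed-oriented-2-manifold invariants; return self.

        Raises
        ------
        MeshValidationError
            On out-of-range indices, degenerate triangles, boundary or
            non-manifold edges, or inconsistent winding.
        """
        t = self.triangles
        if t.size and (t.min() < 0 or t.max() >= self.n_vertices):
            raise MeshValidationError("triangle index out of range")
        areas = triangle_areas(self)
        if np.any(areas <= DEGENERATE_AREA):
            bad = np.nonzero(areas <= DEGENERATE_AREA)[0]
            raise MeshValidationError(f"degenerate triangles: {bad[:10].tolist()}")
        # directed-edge census: a closed oriented manifold has every directed
        # edge exactly once and its reverse exactly once
        directed = defaultdict(int)
        for tri in t:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                directed[(int(a), int(b))] += 1
        for (a, b), cnt in directed.items():
            if cnt > 1:
                raise MeshValidationError(f"non-manifold / repeated directed edge ({a},{b})")
            rev = directed.get((b, a), 0)
            if rev == 0:
                if require_closed:
                    raise MeshValidationError(
                        f"boundary or inconsistently wound edge ({a},{b})"
                    )
        return self

    def is_closed(self) -> bool:
        try:
            self.validate(require_closed=True)
            return True
        except MeshValidationError:
            return False


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def triangle_area(p1, p2, p3) -> float:
    """Area of one triangle: half the cross-product norm of its edge vectors."""
    p1 = np.asarray(p1, dtype=np.float64)
    e1 = np.asarray(p2, dtype=np.float64) - p1
    e2 = np.asarray(p3, dtype=np.float64) - p1
    return 0.5 * float(np.linalg.norm(np.cross(e1, e2)))


def tetra_volume(a, b, c, d) -> float:
    """Unsigned tetrahedron volume from the scalar triple product / 6."""
    a = np.asarray(a, dtype=np.float64)
    ab = np.asarray(b, dtype=np.float64) - a
    ac = np.asarray(c, dtype=np.float64) - a
    ad = np.asarray(d, dtype=np.float64) - a
    return abs(float(np.dot(ad, np.cross(ab, ac)))) / 6.0


def _edges(mesh: SurfaceMesh):
    v = mesh.vertices[mesh.triangles]
    return v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]


def triangle_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-triangle areas (mm^2)."""
    e1, e2 = _edges(mesh)
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def surface_area(mesh: SurfaceMesh) -> float:
    """Total surface area (mm^2): sum of triangle areas."""
    return float(triangle_areas(mesh).sum())


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Volume (mm^3) enclosed by a closed oriented surface.

    Sums signed tetrahedra formed by every triangle with the vertex centroid
    (divergence-theorem decomposition) and takes the absolute value, so the
    result is orientation-independent and exact for non-convex surfaces.
    """
    mesh.validate(require_closed=True)
    origin = mesh.vertices.mean(axis=0)
    v = mesh.vertices[mesh.triangles] - origin
    signed = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0
    return abs(float(signed.sum()))


def face_normals(mesh: SurfaceMesh, unit: bool = True) -> np.ndarray:
    """Per-triangle normals; the raw cross product has norm 2*area."""
    e1, e2 = _edges(mesh)
    n = np.cross(e1, e2)
    if unit:
        n = n / np.linalg.norm(n, axis=1, keepdims=True)
    return n


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Unit vertex normals: area-weighted average of incident face normals.

    The un-normalised face cross product equals (unit normal) * 2 * area, so
    accumulating it per vertex implements the area weighting directly.
    """
    cross = face_normals(mesh, unit=False)
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.triangles[:, k], cross)
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms < 1e-12):
        bad = np.nonzero(norms < 1e-12)[0]
        raise MeshValidationError(f"degenerate normal fan at vertices {bad[:10].tolist()}")
    return acc / norms[:, None]


def vertex_adjacency(mesh: SurfaceMesh) -> list[list[int]]:
    """Edge-connected neighbours per vertex, ascending index order."""
    adj = [set() for _ in range(mesh.n_vertices)]
    for tri in mesh.triangles:
        a, b, c = (int(x) for x in tri)
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return [sorted(s) for s in adj]


def vertex_neighbors(mesh: SurfaceMesh, ring: int = 1,
                     adjacency: list[list[int]] | None = None) -> list[list[int]]:
    """k-ring neighbourhoods by breadth-first traversal of the edge graph.

    The centre vertex is excluded; ordering is deterministic (ascending
    vertex index within the full neighbourhood).
    """
    if ring < 1:
        raise ValueError("ring must be >= 1")
    adj = adjacency if adjacency is not None else vertex_adjacency(mesh)
    if ring == 1:
        return [list(a) for a in adj]
    out = []
    for v in range(mesh.n_vertices):
        seen = {v}
        frontier = [v]
        for _ in range(ring):
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
            frontier = nxt
        seen.discard(v)
        out.append(sorted(seen))
    return out


def apply_displacement(mesh: SurfaceMesh, displacement: np.ndarray) -> SurfaceMesh:
    """Translate each vertex by a per-vertex 3-vector field; topology unchanged."""
    displacement = np.asarray(displacement, dtype=np.float64)
    if displacement.shape != mesh.vertices.shape:
        raise ValueError(
            f"displacement shape {displacement.shape} does not match mesh "
            f"{mesh.vertices.shape}"
        )
    return mesh.with_vertices(mesh.vertices + displacement)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRIMESH_EXT = {".ply", ".off", ".stl"}


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices equal after rounding to 1e-6 mm (STL duplicates them)."""
    rounded = np.round(vertices / 1e-6).astype(np.int64)
    _, first, inverse = np.unique(rounded, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def read_mesh(path) -> SurfaceMesh:
    """Read PLY / OFF / STL / legacy-VTK-polydata into a SurfaceMesh.

    STL stores one vertex record per face corner; records identical to
    1e-6 mm are merged so the closed-manifold invariant is restored.
    """
    path = str(path)
    ext = path[path.rfind("."):].lower()
    if ext == ".vtk":
        return _read_vtk(path)
    if ext not in _TRIMESH_EXT:
        raise ValueError(f"unsupported mesh format: {ext}")
    tm = trimesh.load(path, process=False, force="mesh")
    faces = np.asarray(tm.faces)
    if faces.shape[1] != 3:
        raise ValueError("only triangle meshes are supported")
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    if ext == ".stl":
        vertices, faces = _merge_duplicate_vertices(vertices, faces)
    return SurfaceMesh(vertices, faces)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write PLY (ascii), OFF, STL, or legacy-VTK polydata."""
    path = str(path)
    ext = path[path.rfind("."):].lower()
    if ext == ".vtk":
        _write_vtk(mesh, path)
        return
    if ext not in _TRIMESH_EXT:
        raise ValueError(f"unsupported mesh format: {ext}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(path)


def _read_vtk(path: str) -> SurfaceMesh:
    # legacy ASCII VTK polydata: POINTS n float / POLYGONS m size (or
    # CONNECTIVITY/OFFSETS in the 5.1 dialect)
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.strip()
            if line.startswith("#") or not line:
                continue
            tokens.extend(line.split())
    tok = iter(range(len(tokens)))

    def find(keyword, start=0):
        for i in range(start, len(tokens)):
            if tokens[i].upper() == keyword:
                return i
        return -1

    ip = find("POINTS")
    if ip < 0:
        raise ValueError("malformed VTK file: no POINTS section")
    n = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3: ip + 3 + 3 * n], dtype=np.float64).reshape(n, 3)
    ig = find("POLYGONS")
    if ig < 0:
        raise ValueError("malformed VTK file: no POLYGONS section")
    m = int(tokens[ig + 1])
    total = int(tokens[ig + 2])
    body_start = ig + 3
    if tokens[body_start].upper() == "OFFSETS":
        # VTK 5.1 layout: OFFSETS dtype, m values, CONNECTIVITY dtype, values
        offsets = np.array(tokens[body_start + 2: body_start + 2 + m], dtype=np.int64)
        ic = find("CONNECTIVITY", body_start)
        conn = np.array(tokens[ic + 2: ic + 2 + total], dtype=np.int64)
        faces = []
        for i in range(m - 1):
            a, b = offsets[i], offsets[i + 1]
            if b - a != 3:
                raise ValueError("non-triangle face in VTK file")
            faces.append(conn[a:b])
    else:
        flat = np.array(tokens[body_start: body_start + total], dtype=np.int64)
        faces, i = [], 0
        for _ in range(m):
            k = int(flat[i])
            if k != 3:
                raise ValueError("non-triangle face in VTK file")
            faces.append(flat[i + 1: i + 4])
            i += k + 1
    return SurfaceMesh(coords, np.asarray(faces))


def _write_vtk(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nventromech surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        m = mesh.n_triangles
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def write_field(values: np.ndarray, path, name: str = "value", units: str = "-") -> None:
    """Write a per-vertex/per-triangle field as CSV: index, value columns.

    Vector fields get one column per component (name_x, name_y, name_z).
    The header row names the marker and its units.
    """
    values = np.asarray(values)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if values.ndim == 1:
            w.writerow(["index", f"{name} [{units}]"])
            for i, v in enumerate(values):
                w.writerow([i, repr(float(v))])
        else:
            w.writerow(["index"] + [f"{name}_{ax} [{units}]" for ax in "xyz"[: values.shape[1]]])
            for i, row in enumerate(values):
                w.writerow([i] + [repr(float(v)) for v in row])


def read_field(path) -> np.ndarray:
    """Read a CSV field written by :func:`write_field` (or compatible)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise ValueError("empty field file")
    data = np.array([[float(x) for x in r[1:]] for r in rows[1:]], dtype=np.float64)
    idx = np.array([int(float(r[0])) for r in rows[1:]])
    out = np.empty_like(data)
    out[idx] = data
    return out[:, 0] if out.shape[1] == 1 else out
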