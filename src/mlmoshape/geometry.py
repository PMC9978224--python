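"""Triangle-mesh containers, I/O and surface queries.

All coordinates are millimetres. Meshes are treated as triangle soups for
distance queries; watertightness is recommended but not enforced. PLY, STL
and OBJ files go through :mod:`trimesh`; legacy ascii VTK POLYDATA is read
and written directly (it is a ten-line format).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "MultiOrganSubject",
    "read_mesh",
    "write_mesh",
    "nearest_point_on_surface",
    "closest_points",
    "tangent_project",
    "center_ensemble",
]


@dataclass
class SurfaceMesh:
    """A triangulated organ surface.

    Parameters
    ----------
    vertices : (V, 3) float array, millimetres.
    faces : (F, 3) int array of 0-based vertex indices.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _face_normals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices must be finite")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        if len(self.faces) and self.faces.min() < 0:
            raise ValueError("negative face index")

    # -- derived geometry -------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates."""
        if "triangles" not in self._cache:
            self._cache["triangles"] = self.vertices[self.faces]
        return self._cache["triangles"]

    @property
    def face_normals(self) -> np.ndarray:
        if self._face_normals is None:
            t = self.triangles
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._face_normals = n / norm
        return self._face_normals

    @property
    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def centroid(self) -> np.ndarray:
        """Vertex centroid (mean vertex position)."""
        return self.vertices.mean(axis=0)

    @property
    def bbox_diagonal(self) -> float:
        if len(self.vertices) == 0:
            return 0.0
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def translated(self, t: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(t, dtype=float), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class MultiOrganSubject:
    """One subject: K organ surfaces in a common coordinate frame."""

    subject_id: str
    organs: list  # list[SurfaceMesh]
    organ_labels: list  # list[str]

    def __post_init__(self) -> None:
        if len(self.organs) != len(self.organ_labels):
            raise ValueError("one label per organ required")

    @property
    def n_organs(self) -> int:
        return len(self.organs)

    @property
    def global_centroid(self) -> np.ndarray:
        """Centroid of all vertices of the whole multi-organ complex."""
        return np.concatenate([o.vertices for o in self.organs]).mean(axis=0)

    def translated(self, t: np.ndarray) -> "MultiOrganSubject":
        return MultiOrganSubject(
            self.subject_id, [o.translated(t) for o in self.organs], list(self.organ_labels)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRIMESH_FORMATS = {"ply", "stl", "obj"}


def _format_from_path(path: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in _TRIMESH_FORMATS | {"vtk"}:
        return ext
    raise ValueError(f"cannot infer mesh format from path {path!r}")


def read_mesh(path: str, format: str = "auto") -> SurfaceMesh:
    """Read and clean a triangle mesh.

    Duplicate vertices are merged, degenerate (zero-area) faces dropped and
    quads triangulated. Raises ``FileNotFoundError`` for a missing path and
    ``ValueError`` for unparseable or non-surface content.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = _format_from_path(path, format)
    if fmt == "vtk":
        vertices, faces = _read_vtk_polydata(path)
        tm = trimesh.Trimesh(vertices, faces, process=True)
    else:
        try:
            tm = trimesh.load_mesh(path, file_type=fmt, process=True)
        except Exception as exc:  # noqa: BLE001 - normalize loader errors
            raise ValueError(f"cannot read mesh file {path!r}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise ValueError(f"no surface content in {path!r}")
        tm = trimesh.util.concatenate(geoms)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"file {path!r} does not contain a triangle surface")
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    if len(tm.faces) == 0:
        raise ValueError(f"mesh in {path!r} has only degenerate faces")
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


def write_mesh(mesh: SurfaceMesh, path: str, format: str = "auto") -> None:
    """Write ``mesh`` to ``path``; format inferred from the extension."""
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    fmt = _format_from_path(path, format)
    if fmt == "vtk":
        _write_vtk_polydata(mesh, path)
        return
    mesh.to_trimesh().export(path, file_type=fmt)


def _read_vtk_polydata(path: str):
    """Minimal legacy ascii VTK POLYDATA reader (POINTS + POLYGONS)."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens.append(line.split())
    flat = [t for row in tokens for t in row]
    upper = [t.upper() for t in flat]
    if "POLYDATA" not in upper:
        raise ValueError(f"{path!r}: not a VTK POLYDATA file")
    try:
        ip = upper.index("POINTS")
        n_pts = int(flat[ip + 1])
        coords = np.array(flat[ip + 3 : ip + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
        if_ = upper.index("POLYGONS")
        n_poly = int(flat[if_ + 1])
        size = int(flat[if_ + 2])
        data = np.array(flat[if_ + 3 : if_ + 3 + size], dtype=np.int64)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path!r}: malformed VTK POLYDATA ({exc})") from exc
    faces = []
    i = 0
    for _ in range(n_poly):
        n = int(data[i])
        poly = data[i + 1 : i + 1 + n]
        for j in range(1, n - 1):  # fan-triangulate
            faces.append((poly[0], poly[j], poly[j + 1]))
        i += n + 1
    return coords, np.array(faces, dtype=np.int64)


def _write_vtk_polydata(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmlmoshape surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# Surface queries
# ---------------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query point.

    ``p`` and ``triangles[..., i, :]`` must broadcast against each other
    (e.g. p (P,1,3) with triangles (1,F,3,3), or p (P,1,3) with per-point
    candidates (P,L,3,3)). Fully vectorized barycentric-region case
    analysis (Ericson's algorithm).
    """
    a = triangles[..., 0, :]
    b = triangles[..., 1, :]
    c = triangles[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    q = a + ab * v[..., None] + ac * w[..., None]  # interior (default)

    # edge BC
    mask = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    t = (d4 - d3) / np.where(mask, (d4 - d3) + (d5 - d6), 1.0)
    q = np.where(mask[..., None], b + (c - b) * t[..., None], q)
    # edge AC
    mask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = d2 / np.where(mask, d2 - d6, 1.0)
    q = np.where(mask[..., None], a + ac * t[..., None], q)
    # edge AB
    mask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = d1 / np.where(mask, d1 - d3, 1.0)
    q = np.where(mask[..., None], a + ab * t[..., None], q)
    # vertices
    q = np.where(((d6 >= 0) & (d5 <= d6))[..., None], np.broadcast_to(c, q.shape), q)
    q = np.where(((d3 >= 0) & (d4 <= d3))[..., None], np.broadcast_to(b, q.shape), q)
    q = np.where(((d1 <= 0) & (d2 <= 0))[..., None], np.broadcast_to(a, q.shape), q)
    return q


def _closest_points_brute(mesh: SurfaceMesh, points: np.ndarray):
    """Exact closest surface points by brute force over all faces."""
    tris = mesh.triangles
    # chunk queries to bound memory at ~(chunk * F * 3) doubles
    chunk = max(1, int(4_000_000 / max(len(tris), 1)))
    qs, fids, ds = [], [], []
    for s in range(0, len(points), chunk):
        blk = points[s : s + chunk]
        cand = _closest_on_triangles(blk[:, None, :], tris[None])  # (p, F, 3)
        d2 = np.einsum("pfi,pfi->pf", cand - blk[:, None, :], cand - blk[:, None, :])
        idx = np.argmin(d2, axis=1)
        rows = np.arange(len(blk))
        qs.append(cand[rows, idx])
        fids.append(idx)
        ds.append(np.sqrt(d2[rows, idx]))
    return np.concatenate(qs), np.concatenate(fids), np.concatenate(ds)


def _face_lookup(mesh: SurfaceMesh):
    """Cached KD-tree over face centroids plus the largest
    centroid-to-vertex radius (the pruning safety margin)."""
    if "face_tree" not in mesh._cache:
        tris = mesh.triangles
        centroids = tris.mean(axis=1)
        radius = float(np.linalg.norm(tris - centroids[:, None, :], axis=-1).max())
        mesh._cache["face_tree"] = (cKDTree(centroids), radius)
    return mesh._cache["face_tree"]


def closest_points(mesh: SurfaceMesh, points: np.ndarray):
    """Exact closest surface points: ``(q, face_ids, distances)``.

    Candidate faces come from a KD-tree over face centroids; a point falls
    back to brute force over all faces whenever the pruning bound (closest
    candidate distance vs. L-th centroid distance minus the largest face
    radius) cannot certify the candidate set, so the result always equals
    the brute-force answer. Distance ties resolve to the lowest face id.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(mesh.faces) == 0:
        raise ValueError("mesh has no faces")
    n_faces = len(mesh.faces)
    n_cand = 64
    if n_faces <= 2 * n_cand:
        return _closest_points_brute(mesh, points)
    tree, radius = _face_lookup(mesh)
    dc, idx = tree.query(points, k=n_cand)  # (P, L)
    cand = _closest_on_triangles(points[:, None, :], mesh.triangles[idx])
    d2 = np.einsum("pli,pli->pl", cand - points[:, None, :], cand - points[:, None, :])
    d = np.sqrt(d2)
    # lowest-face-id tie break inside the candidate set
    dmin = d.min(axis=1, keepdims=True)
    fid_masked = np.where(d <= dmin, idx, np.iinfo(np.int64).max)
    best_local = np.argmin(fid_masked, axis=1)
    rows = np.arange(len(points))
    q = cand[rows, best_local]
    fid = idx[rows, best_local]
    dist = d[rows, best_local]
    # certification: any face beyond the L-th centroid can be no closer
    # than dc[:, -1] - radius
    uncertified = dist > dc[:, -1] - radius
    if uncertified.any():
        qb, fb, db = _closest_points_brute(mesh, points[uncertified])
        q[uncertified] = qb
        fid[uncertified] = fb
        dist[uncertified] = db
    return q, fid, dist


def nearest_point_on_surface(mesh: SurfaceMesh, p: np.ndarray):
    """Closest point on the surface to ``p``: ``(q, face_id, distance)``."""
    q, fid, d = closest_points(mesh, np.asarray(p, dtype=float).reshape(1, 3))
    return q[0], int(fid[0]), float(d[0])


def tangent_project(mesh: SurfaceMesh, face_id: int, v: np.ndarray) -> np.ndarray:
    """Remove the component of ``v`` along the normal of face ``face_id``."""
    n = mesh.face_normals[face_id]
    v = np.asarray(v, dtype=float)
    return v - np.dot(v, n) * n


def tangent_project_batch(normals: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Project rows of ``vecs`` onto planes orthogonal to unit ``normals``."""
    return vecs - np.einsum("ij,ij->i", vecs, normals)[:, None] * normals


# ---------------------------------------------------------------------------
# Ensemble alignment
# ---------------------------------------------------------------------------

def center_ensemble(subjects):
    """Translate each subject so its whole-complex vertex centroid is at 0.

    Relative organ poses within a subject are untouched (translation only —
    inter-organ alignment is signal, not nuisance). Returns the centered
    subjects and the per-subject translations that were applied.
    """
    if not subjects:
        raise ValueError("empty subject list")
    centered, translations = [], []
    for s in subjects:
        t = -s.global_centroid
        centered.append(s.translated(t))
        translations.append(t)
    return centered, np.array(translations)


def warn_if_not_watertight(mesh: SurfaceMesh) -> None:
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        warnings.warn("mesh is not watertight; distance queries treat it as a soup")
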