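"""STL input/output and vertex welding.

STL stores a *triangle soup*: every facet carries its own three vertex
coordinates, so shared-vertex connectivity (needed for one-ring curvature)
has to be recovered by welding coincident vertices.  All coordinates are
treated as millimetres.

Binary dialect: 80-byte header, little-endian uint32 facet count, then
50-byte records (normal 3xf4, vertices 9xf4, uint16 attribute byte count,
ignored on read, written as 0).  ASCII dialect: detected when the file
begins with ``solid`` and a ``facet`` token appears within the first
1024 bytes; stored facet normals are never trusted on either path.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, MeshFormatError

log = logging.getLogger("dentalign")

DEFAULT_WELD_TOL = 1e-6  # mm
DEGENERATE_AREA_TOL = 1e-12  # mm^2; faces smaller than this are dropped

_BINARY_RECORD = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


@dataclass
class TriangleMesh:
    """Indexed triangle surface mesh in mm.

    Fresh from :func:`read_stl` the mesh is an unwelded soup
    (``welded == False``, no adjacency).  After :func:`weld_vertices` the
    mesh carries per-vertex one-ring adjacency (``vertex_faces``) and a
    boundary flag per vertex (true iff some incident edge belongs to
    exactly one face).
    """

    vertices: np.ndarray  # (N, 3) float64
    faces: np.ndarray  # (M, 3) int64
    welded: bool = False
    vertex_faces: list[np.ndarray] | None = field(default=None, repr=False)
    boundary: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit normals (zero for degenerate faces) and areas, from CCW order."""
        v = self.vertices[self.faces]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        normals = np.zeros_like(cross)
        ok = norm > 0
        normals[ok] = cross[ok] / norm[ok, None]
        return normals, 0.5 * norm

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident-face normals, unit length."""
        normals, areas = self.face_normals_areas()
        acc = np.zeros_like(self.vertices)
        w = normals * areas[:, None]
        for k in range(3):
            np.add.at(acc, self.faces[:, k], w)
        n = np.linalg.norm(acc, axis=1)
        acc[n > 0] /= n[n > 0, None]
        return acc

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces


def _finalize(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Build a welded mesh with one-ring adjacency and boundary flags."""
    vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.ascontiguousarray(faces, dtype=np.int64).reshape(-1, 3)
    n = len(vertices)
    # incident faces per vertex
    order = np.argsort(faces.ravel(), kind="stable")
    vid = faces.ravel()[order]
    fid = order // 3
    splits = np.searchsorted(vid, np.arange(1, n))
    vertex_faces = np.split(fid, splits)
    # boundary: edges belonging to exactly one face
    boundary = np.zeros(n, dtype=bool)
    if len(faces):
        edges = np.sort(faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary[np.unique(uniq[counts == 1])] = True
    return TriangleMesh(vertices, faces, True, vertex_faces, boundary)


def mesh_from_arrays(vertices, faces) -> TriangleMesh:
    """Welded mesh directly from index arrays (vertices assumed distinct)."""
    return _finalize(np.asarray(vertices, float), np.asarray(faces))


# ---------------------------------------------------------------- reading


def _looks_ascii(data: bytes) -> bool:
    return data.lstrip()[:5].lower() == b"solid" and b"facet" in data[:1024]


def read_stl(path) -> TriangleMesh:
    """Read binary or ASCII STL (auto-detected) into an unwelded soup mesh.

    The result has ``3 * facet_count`` vertices and ``facet_count`` faces;
    stored normals are discarded and recomputed on demand.
    """
    path = Path(path)
    data = path.read_bytes()
    if _looks_ascii(data):
        return _read_ascii(data, path)
    return _read_binary(data, path)


def _read_binary(data: bytes, path: Path) -> TriangleMesh:
    if len(data) < 84:
        raise MeshFormatError(
            f"{path}: truncated binary STL header — file ends at byte "
            f"{len(data)}, need at least 84"
        )
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) != expected:
        raise MeshFormatError(
            f"{path}: facet count mismatch — header at byte 80 declares "
            f"{count} facets ({expected} bytes total) but file has "
            f"{len(data)} bytes"
        )
    records = np.frombuffer(data, dtype=_BINARY_RECORD, count=count, offset=84)
    vertices = records["vertices"].astype(np.float64).reshape(-1, 3)
    faces = np.arange(3 * count, dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(vertices, faces, welded=False)


def _read_ascii(data: bytes, path: Path) -> TriangleMesh:
    coords: list[list[float]] = []
    for lineno, raw in enumerate(data.decode("ascii", errors="replace").splitlines(), 1):
        tokens = raw.split()
        if not tokens:
            continue
        if tokens[0].lower() == "vertex":
            if len(tokens) != 4:
                raise MeshFormatError(
                    f"{path}: line {lineno}: malformed vertex line {raw!r}"
                )
            try:
                coords.append([float(t) for t in tokens[1:]])
            except ValueError as exc:
                raise MeshFormatError(
                    f"{path}: line {lineno}: non-numeric vertex coordinate"
                ) from exc
    if len(coords) % 3:
        raise MeshFormatError(
            f"{path}: ASCII STL holds {len(coords)} vertex lines, "
            "not a multiple of 3"
        )
    vertices = np.array(coords, dtype=np.float64).reshape(-1, 3)
    faces = np.arange(len(coords), dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(vertices, faces, welded=False)


# ---------------------------------------------------------------- welding


def weld_vertices(mesh: TriangleMesh, tol: float = DEFAULT_WELD_TOL) -> TriangleMesh:
    """Merge vertices within ``tol`` (mm) and recover connectivity.

    Faces are reindexed; faces degenerate after merging (repeated index or
    area below :data:`DEGENERATE_AREA_TOL`) are dropped with a logged count;
    unreferenced vertices are removed.  Representative coordinates are taken
    from the first occurrence, so welding is idempotent and exact for the
    binary round-trip.
    """
    if tol < 0:
        raise ValueError("weld tolerance must be >= 0")
    V, F = mesh.vertices, mesh.faces
    if len(V) == 0:
        return _finalize(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))

    parent = np.arange(len(V))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tol > 0:
        pairs = cKDTree(V).query_pairs(tol, output_type="ndarray")
        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    else:
        _, inverse = np.unique(V, axis=0, return_inverse=True)
        first = {}
        for i, g in enumerate(inverse):
            if g in first:
                parent[i] = first[g]
            else:
                first[g] = i
    roots = np.array([find(i) for i in range(len(V))])
    kept_roots, new_index = np.unique(roots, return_inverse=True)
    new_V = V[kept_roots]
    new_F = new_index[F] if len(F) else F

    if len(new_F):
        distinct = (
            (new_F[:, 0] != new_F[:, 1])
            & (new_F[:, 1] != new_F[:, 2])
            & (new_F[:, 0] != new_F[:, 2])
        )
        v = new_V[new_F]
        area = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )
        keep = distinct & (area >= DEGENERATE_AREA_TOL)
        dropped = int(len(new_F) - keep.sum())
        if dropped:
            log.info("weld_vertices: dropped %d degenerate face(s)", dropped)
        new_F = new_F[keep]

    # drop vertices no longer referenced by any face
    if len(new_F):
        used = np.unique(new_F)
        remap = -np.ones(len(new_V), dtype=np.int64)
        remap[used] = np.arange(len(used))
        new_V, new_F = new_V[used], remap[new_F]
    elif len(new_V):
        new_V = np.empty((0, 3))
    return _finalize(new_V, new_F)


# ---------------------------------------------------------------- writing


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write the mesh as STL; facet normals are recomputed from CCW order."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    path = Path(path)
    normals, _ = mesh.face_normals_areas()
    tri = mesh.vertices[mesh.faces] if len(mesh.faces) else np.empty((0, 3, 3))
    if dialect == "binary":
        records = np.zeros(len(tri), dtype=_BINARY_RECORD)
        records["normal"] = normals.astype(np.float32)
        records["vertices"] = tri.astype(np.float32)
        header = b"dentalign binary STL".ljust(80, b" ")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tri)))
            fh.write(records.tobytes())
    else:
        lines = ["solid dentalign"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.17g} {n[1]:.17g} {n[2]:.17g}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid dentalign")
        path.write_text("\n".join(lines) + "\n")


def require_welded(mesh: TriangleMesh) -> TriangleMesh:
    if not mesh.welded or mesh.vertex_faces is None:
        raise DegenerateGeometryError(
            "operation requires a welded mesh; call weld_vertices() first"
        )
    return mesh
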