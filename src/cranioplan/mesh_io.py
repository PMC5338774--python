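"""Indexed triangle meshes and STL reading/writing.

STL files store one independent triangle per facet ("triangle soup"); this
module welds duplicated corners into an indexed mesh on read and unrolls it
again on write.  Stored facet normals are never trusted — orientation comes
from the vertex winding (counter-clockwise seen from outside), because many
exporters write garbage normals.  Coordinates are always millimetres: STL
itself is unitless but CT-derived skull surfaces are exported in mm.

Binary STL layout: 80-byte header, uint32 facet count, then per facet
12 little-endian float32 (normal + 3 vertices) and a uint16 attribute,
50 bytes each.  ASCII STL follows the ``solid``/``facet``/``vertex`` grammar.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError

__all__ = ["TriangleMesh", "read_stl", "write_stl", "weld_vertices"]

_BINARY_DTYPE = np.dtype(
    [("normal", "<f4", (3,)), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
)

DEFAULT_WELD_TOL = 1e-6  # mm


@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm.

    ``vertices`` is an (n, 3) float64 array, ``faces`` an (m, 3) int array of
    vertex indices with counter-clockwise (outward) winding.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.size and not np.isfinite(self.vertices).all():
            raise ParameterError("mesh vertices contain non-finite coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ParameterError("face index out of range")

    # -- basic measures -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array [min; max] of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                n = np.where(norms > 0, n / norms, 0.0)
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalize=False), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals."""
        fn = self.face_normals(normalize=False)  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(norms > 0, vn / norms, 0.0)

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward-wound closed surfaces."""
        tri = self.triangles()
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


# ---------------------------------------------------------------------------
# welding


def weld_vertices(mesh: TriangleMesh, tol: float = DEFAULT_WELD_TOL) -> TriangleMesh:
    """Merge vertices that coincide after rounding to ``tol``.

    Rounding to a fixed grid (rather than spatial search) makes the result
    deterministic and independent of vertex order.  Faces are reindexed and
    faces collapsed by the merge (repeated vertex index) are dropped.
    """
    if tol < 0:
        raise ParameterError("weld tolerance must be >= 0")
    if mesh.n_vertices == 0:
        return mesh.copy()
    if tol > 0:
        keys = np.round(mesh.vertices / tol).astype(np.int64)
    else:
        keys = mesh.vertices
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # keep the first-occurrence coordinates, not the rounded grid point
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = mesh.vertices[np.sort(first)]
    new_faces = rank[inverse][mesh.faces] if mesh.faces.size else mesh.faces
    if new_faces.size:
        ok = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        new_faces = new_faces[ok]
    return TriangleMesh(new_vertices, new_faces)


def compact_vertices(mesh: TriangleMesh) -> TriangleMesh:
    """Drop vertices not referenced by any face and reindex."""
    if mesh.n_faces == 0:
        return TriangleMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))
    used = np.unique(mesh.faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[mesh.faces])


# ---------------------------------------------------------------------------
# reading


def read_stl(path: str | Path, weld_tol: float = DEFAULT_WELD_TOL) -> TriangleMesh:
    """Read a binary or ASCII STL file into a welded indexed mesh."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) == 0:
        raise FormatError(f"{path}: empty file is not a valid STL")
    if _looks_ascii(data):
        corners = _parse_ascii(data, path)
    else:
        corners = _parse_binary(data, path)
    n_facets = len(corners) // 3
    soup = TriangleMesh(
        corners, np.arange(3 * n_facets, dtype=np.int64).reshape(-1, 3)
    )
    return weld_vertices(soup, weld_tol)


def _looks_ascii(data: bytes) -> bool:
    head = data[:512].lstrip()
    return head.startswith(b"solid") and b"facet" in data


def _parse_binary(data: bytes, path: Path) -> np.ndarray:
    if len(data) < 84:
        raise FormatError(f"{path}: binary STL shorter than 84-byte preamble")
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) != expected:
        raise FormatError(
            f"{path}: binary STL facet count {count} implies {expected} bytes, "
            f"file has {len(data)} (truncated record or count mismatch)"
        )
    if count == 0:
        raise FormatError(f"{path}: binary STL declares zero facets")
    records = np.frombuffer(data, dtype=_BINARY_DTYPE, count=count, offset=84)
    corners = records["verts"].astype(np.float64).reshape(-1, 3)
    if not np.isfinite(corners).all():
        raise FormatError(f"{path}: non-finite coordinates in binary STL")
    return corners


_VERTEX_RE = re.compile(
    rb"vertex\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)"
)


def _parse_ascii(data: bytes, path: Path) -> np.ndarray:
    n_facets = len(re.findall(rb"\bfacet\b", data)) - len(
        re.findall(rb"\bendfacet\b", data)
    )
    matches = _VERTEX_RE.findall(data)
    if not matches:
        raise FormatError(f"{path}: ASCII STL contains no vertices")
    if len(matches) % 3 != 0 or n_facets != 0:
        raise FormatError(
            f"{path}: malformed ASCII STL (vertex count {len(matches)} not a "
            "multiple of 3 or unbalanced facet/endfacet)"
        )
    try:
        corners = np.array(matches, dtype=np.float64)
    except ValueError as exc:  # pragma: no cover - regex keeps this rare
        raise FormatError(f"{path}: unparseable coordinate ({exc})") from exc
    if not np.isfinite(corners).all():
        raise FormatError(f"{path}: non-finite coordinates in ASCII STL")
    return corners


# ---------------------------------------------------------------------------
# writing


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> Path:
    """Write ``mesh`` as STL; ``dialect`` is ``"binary"`` or ``"ascii"``.

    Facet normals are recomputed from winding.  Binary output is byte-exactly
    reproducible: 84 + 50·n_faces bytes, zero attribute words.
    """
    path = Path(path)
    if mesh.n_faces == 0:
        raise ParameterError("refusing to write an empty mesh")
    if dialect == "binary":
        _write_binary(mesh, path)
    elif dialect == "ascii":
        _write_ascii(mesh, path)
    else:
        raise ParameterError(f"unknown STL dialect {dialect!r}")
    return path


def _write_binary(mesh: TriangleMesh, path: Path) -> None:
    records = np.zeros(mesh.n_faces, dtype=_BINARY_DTYPE)
    records["normal"] = mesh.face_normals().astype(np.float32)
    records["verts"] = mesh.triangles().astype(np.float32)
    header = b"cranioplan binary STL".ljust(80, b" ")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", mesh.n_faces))
        fh.write(records.tobytes())


def _write_ascii(mesh: TriangleMesh, path: Path) -> None:
    tri = mesh.triangles()
    normals = mesh.face_normals()
    lines = ["solid cranioplan"]
    for f in range(mesh.n_faces):
        n = normals[f]
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in tri[f]:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid cranioplan")
    path.write_text("\n".join(lines) + "\n", encoding="ascii")
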