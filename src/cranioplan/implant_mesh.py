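"""Delaunay tetrahedralization of the marker cloud, alpha filtering and
boundary-surface extraction.

The implant solid is built volumetrically: the (deduplicated) marker
positions are tetrahedralized (Delaunay, empty-circumsphere property), tets
whose circumradius exceeds the alpha threshold are discarded — carving the
concave inner side out of the convex hull — and the boundary triangles of
the surviving tet complex form the printable implant surface.  Alpha acts on
tetrahedra only (vtkDelaunay3D-like); stray faces/edges/points are never
retained, so the output is always the boundary of a solid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import DegenerateInputError, EmptyResultError, ParameterError
from .mesh_io import TriangleMesh, weld_vertices

__all__ = [
    "TetMesh",
    "delaunay_tetrahedralize",
    "alpha_filter",
    "extract_boundary_surface",
    "keep_largest_component",
    "repair_pinched_edges",
    "tet_volumes",
]

_JITTER_SEED = 20170306  # fixed: deterministic degeneracy jitter
_JITTER_MM = 1e-9


@dataclass
class TetMesh:
    """Tetrahedral complex: points (mm), 4-index tets (positively oriented)
    and per-tet circumradii (mm)."""

    points: np.ndarray
    tets: np.ndarray
    circumradii: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.circumradii = np.ascontiguousarray(self.circumradii, dtype=np.float64).reshape(-1)
        if len(self.tets) != len(self.circumradii):
            raise ParameterError("one circumradius per tetrahedron required")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.points)):
            raise ParameterError("tet index out of range")

    @property
    def n_tets(self) -> int:
        return len(self.tets)


def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes det(b-a, c-a, d-a)/6."""
    p = points[tets]
    return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0


def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumsphere radii, solving 2 (p_k - p_0)·c = |p_k|² - |p_0|²."""
    p = points[tets]
    a = 2.0 * (p[:, 1:] - p[:, :1])
    b = (p[:, 1:] ** 2).sum(axis=2) - (p[:, :1] ** 2).sum(axis=2)
    try:
        centers = np.linalg.solve(a, b[..., None])[..., 0]
    except np.linalg.LinAlgError:  # singular tet slipped through: per-tet fallback
        centers = np.empty((len(tets), 3))
        for i in range(len(tets)):
            try:
                centers[i] = np.linalg.solve(a[i], b[i])
            except np.linalg.LinAlgError:
                centers[i] = np.inf
    return np.linalg.norm(centers - p[:, 0], axis=1)


def _dedupe(points: np.ndarray, tol: float) -> np.ndarray:
    if tol < 0:
        raise ParameterError("dedupe tolerance must be >= 0")
    if tol == 0:
        keys = points
    else:
        keys = np.round(points / tol).astype(np.int64)
    _, first = np.unique(keys, axis=0, return_index=True)
    return points[np.sort(first)]


def delaunay_tetrahedralize(points: np.ndarray, dedupe_tol: float = 1e-6) -> TetMesh:
    """Delaunay tetrahedralization of a 3D point cloud.

    Points are deduplicated at ``dedupe_tol`` first.  The union of tets is
    the convex hull of the points and every tet satisfies the
    empty-circumsphere property (up to tie-breaking of cospherical sets,
    which is resolved by a deterministic 1e-9 mm jitter retry).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if not np.isfinite(points).all():
        raise ParameterError("points must be finite")
    points = _dedupe(points, dedupe_tol)
    if len(points) < 4:
        raise ParameterError(f"need at least 4 distinct points, got {len(points)}")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateInputError("points are coplanar/collinear; no 3D tetrahedralization")
    try:
        tri = Delaunay(points)
        used = points
    except QhullError:
        rng = np.random.default_rng(_JITTER_SEED)
        used = points + rng.normal(scale=_JITTER_MM, size=points.shape)
        try:
            tri = Delaunay(used)
        except QhullError as exc:
            raise DegenerateInputError(f"Delaunay backend failed: {exc}") from exc
    tets = tri.simplices.astype(np.int64)
    vols = tet_volumes(points, tets)
    # orient positively, drop exactly-degenerate slivers
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    scale = max(float(np.abs(points).max()), 1.0)
    keep = np.abs(vols) > 1e-12 * scale**3
    tets = tets[keep]
    if len(tets) == 0:
        raise DegenerateInputError("all tetrahedra degenerate")
    return TetMesh(points, tets, _circumradii(points, tets))


def alpha_filter(tets: TetMesh, alpha: float | None) -> TetMesh:
    """Keep tetrahedra with circumradius <= ``alpha`` mm; ``None`` keeps all."""
    if alpha is None:
        return TetMesh(tets.points, tets.tets.copy(), tets.circumradii.copy())
    if not alpha > 0:
        raise ParameterError("alpha must be > 0 (or None to disable filtering)")
    keep = tets.circumradii <= alpha
    if not keep.any():
        rmin = float(tets.circumradii.min())
        raise EmptyResultError(
            f"alpha={alpha:g} mm removes every tetrahedron "
            f"(minimum circumradius is {rmin:.6g} mm)",
            min_circumradius=rmin,
        )
    return TetMesh(tets.points, tets.tets[keep], tets.circumradii[keep])


_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


def _tet_face_table(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (4m, 3) faces and the owning tet index of each."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    owners = np.repeat(np.arange(len(tets)), 4)
    return faces, owners


def extract_boundary_surface(tets: TetMesh) -> TriangleMesh:
    """Boundary triangles of the tet complex, wound outward.

    A triangle is on the boundary iff it is incident to exactly one kept
    tetrahedron; its winding is chosen so the normal points away from the
    owning tet's centroid.  The result is a welded indexed mesh.
    """
    if tets.n_tets == 0:
        raise ParameterError("empty tetrahedral mesh")
    faces, owners = _tet_face_table(tets.tets)
    keys = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inverse] == 1
    bfaces = faces[on_boundary]
    bowners = owners[on_boundary]
    tri = tets.points[bfaces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    tet_centroids = tets.points[tets.tets[bowners]].mean(axis=1)
    outward = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - tet_centroids) >= 0
    bfaces = np.where(outward[:, None], bfaces, bfaces[:, ::-1])
    mesh = TriangleMesh(tets.points, bfaces)
    from .mesh_io import compact_vertices

    return weld_vertices(compact_vertices(mesh), 0.0)


def repair_pinched_edges(tets: TetMesh, max_passes: int = 100) -> TetMesh:
    """Remove tets until the boundary surface is edge-manifold.

    Alpha filtering can leave an edge whose surrounding tet ring is only
    partially kept, so four boundary triangles meet there (a "pinch") and the
    surface is no longer a printable 2-manifold.  Each pass finds every such
    edge and discards, per edge, the incident boundary tet with the largest
    circumradius — the most alpha-marginal one — which is deterministic and
    monotone, so the loop terminates.
    """
    current = tets
    for _ in range(max_passes):
        faces, owners = _tet_face_table(current.tets)
        keys = np.sort(faces, axis=1)
        _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
        on_boundary = counts[inverse] == 1
        bfaces = keys[on_boundary]
        bowners = owners[on_boundary]
        edges = np.concatenate(
            [bfaces[:, [0, 1]], bfaces[:, [0, 2]], bfaces[:, [1, 2]]]
        )
        eowners = np.tile(bowners, 3)
        uedges, einv, ecounts = np.unique(edges, axis=0, return_inverse=True, return_counts=True)
        bad = ecounts[einv] > 2
        if not bad.any():
            return current
        drop = set()
        for eid in np.unique(einv[bad]):
            incident = eowners[einv == eid]
            radii = current.circumradii[incident]
            drop.add(int(incident[np.lexsort((incident, radii))[-1]]))
        keep = np.ones(current.n_tets, dtype=bool)
        keep[list(drop)] = False
        if not keep.any():
            raise EmptyResultError(
                "pinch repair removed every tetrahedron",
                min_circumradius=float(tets.circumradii.min()),
            )
        current = TetMesh(current.points, current.tets[keep], current.circumradii[keep])
    raise ParameterError("pinch repair did not converge; mesh too fragmented")


def keep_largest_component(tets: TetMesh) -> TetMesh:
    """Restrict to the face-connected tet component of largest total volume.

    Alpha filtering can leave isolated sliver tets floating next to the main
    solid; a printable implant is a single body.
    """
    if tets.n_tets == 0:
        raise ParameterError("empty tetrahedral mesh")
    faces, owners = _tet_face_table(tets.tets)
    keys = np.sort(faces, axis=1)
    order = np.lexsort(keys.T[::-1])
    sk, so = keys[order], owners[order]
    same = (sk[1:] == sk[:-1]).all(axis=1)
    pairs = np.stack([so[:-1][same], so[1:][same]], axis=1)
    # union-find over shared faces
    parent = np.arange(tets.n_tets)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(tets.n_tets)])
    vols = np.abs(tet_volumes(tets.points, tets.tets))
    best = max(np.unique(roots), key=lambda r: vols[roots == r].sum())
    keep = roots == best
    return TetMesh(tets.points, tets.tets[keep], tets.circumradii[keep])
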