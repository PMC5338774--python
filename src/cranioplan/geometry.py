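"""Mesh preparation geometry: centering, mirroring, clipping, landmark
registration and defect-rim detection.

The mirror template workflow needs only rigid maps and one reflection: the
defect skull is centered, duplicated, and reflected across the midsagittal
plane so the intact side covers the defect.  With the default plane (x = 0
through the origin) the reflection is the diagonal matrix diag(-1, 1, 1).
All coordinates are world millimetres, right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError, TopologyError
from .mesh_io import TriangleMesh, compact_vertices

__all__ = [
    "Plane",
    "RigidTransform",
    "center_mesh",
    "reflect_mesh",
    "reflect_points",
    "clip_mesh",
    "rigid_register",
    "boundary_loops",
    "plane_from_landmarks",
]


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normal: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ParameterError("plane normal must be a unit vector (|n| = 1 within 1e-9)")
        if not np.isfinite(self.point).all() or not np.isfinite(n).all():
            raise ParameterError("plane parameters must be finite")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.point, dtype=np.float64)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=np.float64)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.p) @ self.n

    def flipped(self) -> "Plane":
        return Plane(self.point, tuple(-c for c in self.normal))


MIDSAGITTAL = Plane()  # x = 0 through the origin, after centering


def plane_from_landmarks(a, b, c) -> Plane:
    """Plane through three non-collinear landmark points."""
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise DegenerateInputError("landmarks are collinear; no unique plane")
    return Plane(tuple(a), tuple(n / norm))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ParameterError("rotation must be orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ParameterError("rotation determinant must be +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return TriangleMesh(self.apply(mesh.vertices), mesh.faces.copy())

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def center_mesh(mesh: TriangleMesh) -> tuple[TriangleMesh, np.ndarray]:
    """Translate so the bounding-box center sits at the origin.

    Returns the centered mesh and the removed offset (original = centered +
    offset), so the operation is invertible.
    """
    if mesh.n_vertices == 0:
        raise ParameterError("cannot center an empty mesh")
    offset = mesh.bounds.mean(axis=0)
    return TriangleMesh(mesh.vertices - offset, mesh.faces.copy()), offset


def reflect_points(points: np.ndarray, plane: Plane) -> np.ndarray:
    """Householder reflection v -> v - 2((v - p)·n) n."""
    points = np.asarray(points, dtype=np.float64)
    d = (points - plane.p) @ plane.n
    return points - 2.0 * d[:, None] * plane.n[None, :]


def reflect_mesh(mesh: TriangleMesh, plane: Plane = MIDSAGITTAL) -> TriangleMesh:
    """Mirror a mesh across ``plane``; face winding is reversed so normals
    stay outward.  For the default plane this is diag(-1, 1, 1)."""
    return TriangleMesh(reflect_points(mesh.vertices, plane), mesh.faces[:, ::-1].copy())


def clip_mesh(mesh: TriangleMesh, plane: Plane) -> TriangleMesh:
    """Keep faces entirely on the non-negative side of ``plane``.

    Faces straddling the plane are dropped, not split — clipping is a
    marker-candidate / inspection aid, never part of the implant geometry.
    """
    keep_vertex = plane.signed_distance(mesh.vertices) >= 0.0
    keep_face = keep_vertex[mesh.faces].all(axis=1)
    return compact_vertices(TriangleMesh(mesh.vertices, mesh.faces[keep_face]))


def rigid_register(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid alignment of corresponding landmarks
    (orthogonal Procrustes / Kabsch).

    Requires >= 3 non-collinear pairs; applying the result to the source
    minimizes the summed squared distance to the target.
    """
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    dst = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ParameterError("source and target landmark lists differ in shape")
    if len(src) < 3:
        raise DegenerateInputError("rigid registration needs at least 3 point pairs")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    s = np.linalg.svd(src_c, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateInputError("landmarks are collinear; rotation is not unique")
    H = src_c.T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def boundary_loops(mesh: TriangleMesh) -> list[np.ndarray]:
    """Ordered vertex loops along edges used by exactly one face.

    Each loop is a closed cycle following the owning faces' winding, returned
    as an array of vertex indices.  Loops are sorted by descending polyline
    length (mm).  A watertight mesh yields no loops.  Edges shared by more
    than two faces raise :class:`TopologyError`.
    """
    if mesh.n_faces == 0:
        return []
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    if counts.max() > 2:
        raise TopologyError("non-manifold edge: shared by more than two faces")
    boundary = directed[counts[inverse] == 1]
    if len(boundary) == 0:
        return []
    # successor map along winding; a vertex can start several loops if two
    # rims touch, so keep lists and consume edges as we walk
    succ: dict[int, list[int]] = {}
    for a, b in boundary:
        succ.setdefault(int(a), []).append(int(b))
    for v in succ.values():
        v.sort(reverse=True)  # pop() yields the smallest, deterministically
    loops: list[np.ndarray] = []
    starts = sorted(succ)
    for start in starts:
        while succ.get(start):
            loop = [start]
            cur = succ[start].pop()
            while cur != start:
                loop.append(cur)
                nxts = succ.get(cur)
                if not nxts:
                    raise TopologyError("boundary edge chain does not close into a loop")
                cur = nxts.pop()
            loops.append(np.asarray(loop, dtype=np.int64))

    def _length(loop: np.ndarray) -> float:
        pts = mesh.vertices[loop]
        return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())

    loops.sort(key=lambda lp: (-_length(lp), int(lp[0])))
    return loops
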