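"""Volumetric agreement metrics between planned implants.

Surfaces are voxelized on an isotropic grid (default 0.5 mm) by testing the
containment of every voxel center with parity ray casting along +x: a center
is inside iff the ray crosses the surface an odd number of times.  Two
volumes under comparison must share one grid, so Dice overlap and Hausdorff
distances are computed voxel-by-voxel; the Hausdorff distance is reported in
voxel units over the occupied-voxel center sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    GridMismatchError,
    ParameterError,
    TopologyError,
    UndefinedMetricError,
)
from .geometry import boundary_loops
from .mesh_io import TriangleMesh

__all__ = [
    "VoxelGrid",
    "bounding_grid",
    "voxelize",
    "dice_coefficient",
    "hausdorff_voxels",
    "volume_report",
]

DEFAULT_SPACING = 0.5  # mm
# deterministic ray-origin offsets; incommensurate in y and z so a ray can
# never track a mesh edge (e.g. the diagonal of a quad split into triangles)
_RAY_OFFSET_Y = 1.0e-7  # mm
_RAY_OFFSET_Z = 1.6180339887e-7  # mm


@dataclass
class VoxelGrid:
    """Binary occupancy on an isotropic grid.

    Voxel (i, j, k) has its center at ``origin + (index + 0.5) * spacing``.
    """

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.shape = tuple(int(s) for s in self.shape)
        if self.spacing <= 0:
            raise ParameterError("voxel spacing must be > 0")
        if any(s <= 0 for s in self.shape):
            raise ParameterError("grid shape must be positive")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.shape:
            raise ParameterError("occupancy array does not match grid shape")

    @classmethod
    def empty(cls, origin, spacing: float, shape) -> "VoxelGrid":
        shape = tuple(int(s) for s in shape)
        return cls(origin, spacing, shape, np.zeros(shape, dtype=bool))

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.spacing**3

    def occupied_centers(self) -> np.ndarray:
        idx = np.argwhere(self.occupancy)
        return self.origin + (idx + 0.5) * self.spacing

    def same_grid(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) < 1e-12
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


def bounding_grid(
    meshes: Sequence[TriangleMesh], spacing: float = DEFAULT_SPACING, pad: int = 1
) -> VoxelGrid:
    """Empty grid covering the joint bounding box of ``meshes``, padded by
    ``pad`` voxels on every side — the shared frame for comparisons."""
    if not meshes:
        raise ParameterError("need at least one mesh")
    if spacing <= 0:
        raise ParameterError("voxel spacing must be > 0")
    lo = np.min([m.bounds[0] for m in meshes], axis=0)
    hi = np.max([m.bounds[1] for m in meshes], axis=0)
    origin = lo - pad * spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 2 * pad
    return VoxelGrid.empty(origin, spacing, shape)


def voxelize(
    mesh: TriangleMesh,
    spacing: float = DEFAULT_SPACING,
    grid: VoxelGrid | None = None,
) -> VoxelGrid:
    """Voxelize a watertight mesh by center-containment parity ray casting.

    If ``grid`` is given its origin/spacing/shape are reused (occupancy is
    recomputed), which is how two meshes are brought onto one shared grid;
    otherwise a grid covering the mesh bbox padded by one voxel is built.
    A mesh with boundary loops cannot bound a volume and is rejected.
    """
    if boundary_loops(mesh):
        raise TopologyError("mesh is not watertight; containment is undefined")
    if grid is None:
        grid = bounding_grid([mesh], spacing)
    out = VoxelGrid.empty(grid.origin, grid.spacing, grid.shape)
    out.occupancy = _parity_occupancy(mesh, out)
    return out


def _parity_occupancy(mesh: TriangleMesh, grid: VoxelGrid) -> np.ndarray:
    nx, ny, nz = grid.shape
    s = grid.spacing
    ox, oy, oz = grid.origin
    tri = mesh.triangles()
    # project on (y, z); rays run along +x through column centers
    ay, az = tri[:, 0, 1], tri[:, 0, 2]
    by, bz = tri[:, 1, 1], tri[:, 1, 2]
    cy, cz = tri[:, 2, 1], tri[:, 2, 2]
    # candidate columns per triangle from the (y, z) bbox; column centers are
    # offset by _RAY_OFFSET so rays never graze vertices/edges exactly
    ymin = np.minimum.reduce([ay, by, cy])
    ymax = np.maximum.reduce([ay, by, cy])
    zmin = np.minimum.reduce([az, bz, cz])
    zmax = np.maximum.reduce([az, bz, cz])

    def _lo(vmin, o, off):
        return np.maximum(np.ceil((vmin - o - off) / s - 0.5).astype(np.int64), 0)

    def _hi(vmax, o, n, off):
        return np.minimum(np.floor((vmax - o - off) / s - 0.5).astype(np.int64), n - 1)

    j_lo, j_hi = _lo(ymin, oy, _RAY_OFFSET_Y), _hi(ymax, oy, ny, _RAY_OFFSET_Y)
    k_lo, k_hi = _lo(zmin, oz, _RAY_OFFSET_Z), _hi(zmax, oz, nz, _RAY_OFFSET_Z)
    wj = j_hi - j_lo + 1
    wk = k_hi - k_lo + 1
    valid = (wj > 0) & (wk > 0)
    counts = np.where(valid, wj * wk, 0)
    total = int(counts.sum())
    occupancy = np.zeros(grid.shape, dtype=bool)
    if total == 0:
        return occupancy
    tri_idx = np.repeat(np.arange(len(tri)), counts)
    local = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    j = j_lo[tri_idx] + local // wk[tri_idx]
    k = k_lo[tri_idx] + local % wk[tri_idx]
    py = oy + (j + 0.5) * s + _RAY_OFFSET_Y
    pz = oz + (k + 0.5) * s + _RAY_OFFSET_Z
    # 2D barycentric test in the (y, z) projection
    d = (by - ay)[tri_idx] * (cz - az)[tri_idx] - (cy - ay)[tri_idx] * (bz - az)[tri_idx]
    good = np.abs(d) > 1e-12  # edge-on triangles (projected area ~0) are skipped
    l1 = ((py - ay[tri_idx]) * (cz - az)[tri_idx] - (cy - ay)[tri_idx] * (pz - az[tri_idx]))
    l2 = ((by - ay)[tri_idx] * (pz - az[tri_idx]) - (py - ay[tri_idx]) * (bz - az)[tri_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = np.where(good, l1 / d, np.nan)
        l2 = np.where(good, l2 / d, np.nan)
    inside = good & (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)
    if not inside.any():
        return occupancy
    tri_idx, j, k, l1, l2 = tri_idx[inside], j[inside], k[inside], l1[inside], l2[inside]
    ax_ = tri[:, 0, 0]
    x_hit = (
        (1.0 - l1 - l2) * ax_[tri_idx] + l1 * tri[tri_idx, 1, 0] + l2 * tri[tri_idx, 2, 0]
    )
    # voxel i is inside iff an odd number of crossings lie below its center:
    # toggle at the first center above each crossing, then cumulative parity
    i_first = np.floor((x_hit - ox) / s + 0.5).astype(np.int64)
    keep = i_first < nx
    i_first = np.clip(i_first[keep], 0, nx - 1)
    toggles = np.zeros(grid.shape, dtype=np.int64)
    np.add.at(toggles, (i_first, j[keep], k[keep]), 1)
    occupancy = (np.cumsum(toggles, axis=0) % 2).astype(bool)
    return occupancy


def _check_pair(a: VoxelGrid, b: VoxelGrid) -> None:
    if not a.same_grid(b):
        raise GridMismatchError("voxel grids differ; re-voxelize on a shared grid")


def dice_coefficient(a: VoxelGrid, b: VoxelGrid) -> float:
    """Dice Similarity Coefficient 2|A∩B| / (|A|+|B|) in percent (2 decimals)."""
    _check_pair(a, b)
    na, nb = a.count, b.count
    if na + nb == 0:
        raise UndefinedMetricError("DSC undefined: both occupancy sets are empty")
    inter = int((a.occupancy & b.occupancy).sum())
    return round(200.0 * inter / (na + nb), 2)


def hausdorff_voxels(a: VoxelGrid, b: VoxelGrid) -> float:
    """Symmetric Hausdorff distance between occupied-voxel center sets, in
    voxel units (mm distance divided by the spacing)."""
    _check_pair(a, b)
    if a.count == 0 or b.count == 0:
        raise UndefinedMetricError("Hausdorff distance undefined for an empty set")
    pa = a.occupied_centers()
    pb = b.occupied_centers()
    d_ab = cKDTree(pb).query(pa, k=1)[0].max()
    d_ba = cKDTree(pa).query(pb, k=1)[0].max()
    return float(max(d_ab, d_ba) / a.spacing)


def volume_report(a: VoxelGrid) -> tuple[int, float]:
    """(occupied voxel count, volume in mm³ = count × spacing³)."""
    return a.count, a.count * a.spacing**3
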