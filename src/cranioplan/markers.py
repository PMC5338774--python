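"""Typed landmark markers driving implant construction.

Four marker types, following the planning convention:

====  =============  ======  ======
type  meaning        layer   border
====  =============  ======  ======
0     outer edge     OUTER   yes
1     inner edge     INNER   yes
2     outer surface  OUTER   no
3     inner surface  INNER   no
====  =============  ======  ======

Edge (border) markers sit on the defect rim and are fixed during smoothing;
surface markers sample the mirrored template and are the ones smoothing
moves.  Layer and border flags are pure functions of the type.

Interactive clicking is replaced by two reproducible placement operations:
arc-length-uniform resampling of a detected rim loop, and seeded
area-weighted sampling of template faces inside a spherical region.
The on-disk format is CSV (``x,y,z,type``, one header line) or the
equivalent JSON list of ``{x, y, z, type}`` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyRegionError, FormatError, ParameterError
from .mesh_io import TriangleMesh

__all__ = [
    "Marker",
    "MarkerSet",
    "OUTER_TYPES",
    "INNER_TYPES",
    "BORDER_TYPES",
    "save_markers",
    "load_markers",
    "place_edge_markers",
    "place_surface_markers",
]

OUTER_TYPES = (0, 2)
INNER_TYPES = (1, 3)
BORDER_TYPES = (0, 1)

_FLOAT_FMT = "{:.12g}"  # >= 9 significant digits, stable under re-parsing


@dataclass(frozen=True)
class Marker:
    position: tuple[float, float, float]
    mtype: int

    def __post_init__(self) -> None:
        if self.mtype not in (0, 1, 2, 3):
            raise ParameterError(f"marker type must be 0..3, got {self.mtype}")
        if not np.isfinite(self.position).all():
            raise ParameterError("marker position must be finite")


class MarkerSet:
    """Ordered collection of markers; order survives save/load round trips."""

    def __init__(self, positions: np.ndarray, types: np.ndarray):
        self.positions = np.ascontiguousarray(positions, dtype=np.float64).reshape(-1, 3)
        self.types = np.ascontiguousarray(types, dtype=np.int64).reshape(-1)
        if len(self.positions) != len(self.types):
            raise ParameterError("positions and types differ in length")
        if self.types.size and not np.isin(self.types, [0, 1, 2, 3]).all():
            bad = self.types[~np.isin(self.types, [0, 1, 2, 3])][0]
            raise FormatError(f"marker type out of range: {bad}")
        if self.positions.size and not np.isfinite(self.positions).all():
            raise ParameterError("marker positions must be finite")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_markers(cls, markers: Sequence[Marker]) -> "MarkerSet":
        if not markers:
            return cls.empty()
        return cls(
            np.array([m.position for m in markers]),
            np.array([m.mtype for m in markers]),
        )

    @classmethod
    def empty(cls) -> "MarkerSet":
        return cls(np.empty((0, 3)), np.empty(0, dtype=np.int64))

    @classmethod
    def concatenate(cls, sets: Sequence["MarkerSet"]) -> "MarkerSet":
        return cls(
            np.concatenate([s.positions for s in sets]) if sets else np.empty((0, 3)),
            np.concatenate([s.types for s in sets]) if sets else np.empty(0, dtype=np.int64),
        )

    # -- derived attributes ---------------------------------------------

    @property
    def is_outer_layer(self) -> np.ndarray:
        return np.isin(self.types, OUTER_TYPES)

    @property
    def is_border(self) -> np.ndarray:
        return np.isin(self.types, BORDER_TYPES)

    @property
    def is_surface(self) -> np.ndarray:
        return ~self.is_border

    def __len__(self) -> int:
        return len(self.types)

    def __iter__(self) -> Iterator[Marker]:
        for p, t in zip(self.positions, self.types):
            yield Marker(tuple(p), int(t))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerSet):
            return NotImplemented
        return (
            self.positions.shape == other.positions.shape
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.types, other.types)
        )


# ---------------------------------------------------------------------------
# file format


def save_markers(markers: MarkerSet, path: str | Path) -> Path:
    """Write markers as CSV or JSON (chosen by file suffix)."""
    path = Path(path)
    if len(markers) == 0:
        raise ParameterError("refusing to save an empty marker set")
    if path.suffix.lower() == ".json":
        records = [
            {
                "x": float(p[0]),
                "y": float(p[1]),
                "z": float(p[2]),
                "type": int(t),
            }
            for p, t in zip(markers.positions, markers.types)
        ]
        path.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
    else:
        lines = ["x,y,z,type"]
        for p, t in zip(markers.positions, markers.types):
            coords = ",".join(_FLOAT_FMT.format(c) for c in p)
            lines.append(f"{coords},{int(t)}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_markers(path: str | Path) -> MarkerSet:
    """Read a CSV or JSON marker file; malformed rows report their line number."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            records = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
        positions, types = [], []
        for i, rec in enumerate(records):
            try:
                positions.append((float(rec["x"]), float(rec["y"]), float(rec["z"])))
                types.append(int(rec["type"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}: malformed record {i}: {exc}") from exc
        return _checked(positions, types, path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0].strip().lower().replace(" ", "") != "x,y,z,type":
        raise FormatError(f"{path}: expected header 'x,y,z,type'")
    positions, types = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise FormatError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
        try:
            positions.append(tuple(float(c) for c in parts[:3]))
            types.append(int(parts[3]))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        if types[-1] not in (0, 1, 2, 3):
            raise FormatError(f"{path}: line {lineno}: marker type out of range: {types[-1]}")
    return _checked(positions, types, path)


def _checked(positions, types, path) -> MarkerSet:
    if not positions:
        return MarkerSet.empty()
    try:
        return MarkerSet(np.array(positions), np.array(types))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# programmatic placement


def place_edge_markers(
    defect_mesh: TriangleMesh,
    loop: np.ndarray,
    n: int,
    mtype: int,
) -> MarkerSet:
    """``n`` markers at arc-length-uniform positions along a closed rim loop.

    ``loop`` is an ordered array of vertex indices as returned by
    :func:`cranioplan.geometry.boundary_loops`; sampling starts at the loop's
    first vertex and walks the closed polygon, so markers lie exactly on it.
    """
    if mtype not in BORDER_TYPES:
        raise ParameterError("edge markers must be type 0 (outer) or 1 (inner)")
    loop = np.asarray(loop, dtype=np.int64)
    if len(loop) < 3:
        raise ParameterError("loop must be a closed cycle of at least 3 vertices")
    if n < 3:
        raise ParameterError("need at least 3 edge markers")
    pts = defect_mesh.vertices[loop]
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    if perimeter <= 0:
        raise ParameterError("degenerate loop with zero perimeter")
    targets = np.arange(n) * (perimeter / n)
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    samples = closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])
    return MarkerSet(samples, np.full(n, mtype, dtype=np.int64))


def place_surface_markers(
    template_mesh: TriangleMesh,
    region_center: np.ndarray,
    region_radius: float,
    n: int,
    mtype: int,
    inward_offset: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> MarkerSet:
    """Sample ``n`` template-surface points inside a spherical region.

    Candidate faces are those whose centroid lies within ``region_radius`` of
    ``region_center``; points are drawn area-weighted and uniformly inside
    each chosen face, then moved ``inward_offset`` mm against the outward
    face normal (0 for outer-surface markers, the shell thickness for
    inner-surface ones).  The same seed always yields the same markers.
    """
    if mtype not in (2, 3):
        raise ParameterError("surface markers must be type 2 (outer) or 3 (inner)")
    if n < 1:
        raise ParameterError("need at least 1 surface marker")
    if region_radius <= 0:
        raise ParameterError("region radius must be > 0")
    if template_mesh.n_faces == 0:
        raise EmptyRegionError("template mesh has no faces")
    center = np.asarray(region_center, dtype=np.float64).reshape(3)
    dist = np.linalg.norm(template_mesh.face_centroids() - center, axis=1)
    in_region = np.flatnonzero(dist <= region_radius)
    if len(in_region) == 0:
        raise EmptyRegionError(
            f"no template faces within {region_radius:g} mm of the region center"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    areas = template_mesh.face_areas()[in_region]
    total = areas.sum()
    if total <= 0:
        raise EmptyRegionError("all faces in the region are degenerate")
    chosen = rng.choice(in_region, size=n, p=areas / total)
    tri = template_mesh.triangles()[chosen]
    # uniform barycentric sampling (square-root trick)
    r1 = rng.random(n)
    r2 = rng.random(n)
    s = np.sqrt(r1)
    bary = np.stack([1.0 - s, s * (1.0 - r2), s * r2], axis=1)
    points = np.einsum("fk,fkd->fd", bary, tri)
    normals = template_mesh.face_normals()[chosen]
    points = points - inward_offset * normals
    return MarkerSet(points, np.full(n, mtype, dtype=np.int64))
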