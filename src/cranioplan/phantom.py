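"""Synthetic skull phantom: a thin curved shell with a one-sided defect.

Clinical defect skulls are not required to exercise the planning pipeline;
everything it relies on — curvature, a two-table shell of roughly uniform
thickness, an open defect rim, optional left/right asymmetry — is emulated
by an ellipsoidal shell:

* the outer table is a subdivided icosphere scaled to the outer semiaxes
  (optionally made asymmetric by scaling the x-coordinate of the x > 0 half);
* the inner table is the outer surface offset inward along area-weighted
  vertex normals, so the shell thickness is locally uniform rather than a
  scaled copy;
* the defect removes the shell wedge whose outward direction lies within
  ``defect_angle`` of ``defect_axis``, leaving the rim open;
* the removed wedge, closed by a rim wall, is returned as the ground-truth
  patch so planned implants can be scored volumetrically (Dice/Hausdorff).

Construction is fully deterministic: the same spec always produces
byte-identical STL output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import trimesh

from .errors import ParameterError, TopologyError
from .geometry import boundary_loops
from .mesh_io import TriangleMesh, compact_vertices

__all__ = ["PhantomSpec", "PhantomResult", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic defect skull.

    Defaults approximate an adult cranium (mm) with a moderate lateral
    defect: outer semiaxes 75×95×70, two-table shell 4 mm thick, defect
    wedge of 25° half-angle about +x, icosphere subdivision 4.
    """

    outer_semiaxes: tuple[float, float, float] = (75.0, 95.0, 70.0)
    thickness: float = 4.0
    asymmetry: float = 1.0
    defect_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    defect_angle: float = 25.0
    subdivision: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.outer_semiaxes) <= 0:
            raise ParameterError("semiaxes must be positive")
        if not 0 < self.thickness < min(self.outer_semiaxes):
            raise ParameterError("thickness must be in (0, min semiaxis)")
        if not 0 < self.defect_angle < 90:
            raise ParameterError("defect_angle must be in (0, 90) degrees")
        if not self.asymmetry > 0:
            raise ParameterError("asymmetry factor must be > 0")
        if not (isinstance(self.subdivision, int) and self.subdivision >= 2):
            raise ParameterError("subdivision must be an integer >= 2")
        if np.linalg.norm(self.defect_axis) < 1e-12:
            raise ParameterError("defect_axis must be a nonzero vector")

    @property
    def axis_unit(self) -> np.ndarray:
        a = np.asarray(self.defect_axis, dtype=np.float64)
        return a / np.linalg.norm(a)


class PhantomResult(NamedTuple):
    defect_mesh: TriangleMesh
    intact_mesh: TriangleMesh
    truth_patch: TriangleMesh
    defect_closed: TriangleMesh  # defect-side shell closed at the rim (for volume audits)


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build (defect skull, intact skull, ground-truth patch, closed defect solid)."""
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivision, radius=1.0)
    outer = np.asarray(ico.vertices, dtype=np.float64) * np.asarray(spec.outer_semiaxes)
    faces = np.asarray(ico.faces, dtype=np.int64)
    if spec.asymmetry != 1.0:
        right = outer[:, 0] > 0
        outer = outer.copy()
        outer[right, 0] *= spec.asymmetry

    outer_mesh = TriangleMesh(outer, faces)
    normals = outer_mesh.vertex_normals()
    inner = outer - spec.thickness * normals
    nv = len(outer)
    verts = np.vstack([outer, inner])
    inner_faces = faces[:, ::-1] + nv  # flipped: normals point into the cavity

    intact = TriangleMesh(verts, np.vstack([faces, inner_faces]))

    # wedge selection on outward direction of outer-face centroids
    centroids = outer_mesh.face_centroids()
    u = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    cos_cut = np.cos(np.radians(spec.defect_angle))
    removed = u @ spec.axis_unit > cos_cut
    if not removed.any() or removed.all():
        raise ParameterError(
            "defect wedge removes no face or every face; adjust angle/subdivision"
        )

    kept = ~removed
    defect = compact_vertices(
        TriangleMesh(verts, np.vstack([faces[kept], inner_faces[kept]]))
    )

    # rim wall: walk the boundary loop of the removed outer cap and join each
    # directed edge (a -> b) to its inner twin with opposite traversal, which
    # keeps the closed wedge consistently outward-oriented
    cap_loops = boundary_loops(TriangleMesh(verts, faces[removed]))
    if len(cap_loops) != 1:
        raise TopologyError(
            f"defect cap has {len(cap_loops)} rim loops; expected exactly 1"
        )
    loop = cap_loops[0]
    a = loop
    b = np.roll(loop, -1)
    wall = np.concatenate(
        [
            np.stack([b, a, a + nv], axis=1),
            np.stack([b, a + nv, b + nv], axis=1),
        ]
    )
    truth = compact_vertices(
        TriangleMesh(verts, np.vstack([faces[removed], inner_faces[removed], wall]))
    )
    closed = compact_vertices(
        TriangleMesh(verts, np.vstack([faces[kept], inner_faces[kept], wall[:, ::-1]]))
    )
    return PhantomResult(defect, intact, truth, closed)
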