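"""End-to-end implant planning: one declarative config, one deterministic run.

The interactive planning loop (load, center, mirror, place markers, smooth,
triangulate, inspect, refine) collapses into a single function over a
:class:`PlanConfig`.  Refinement means editing the config and re-running.
Stages, in order:

1. ``load``       — read the defect-skull STL
2. ``center``     — bounding-box center to the origin
3. ``mirror``     — duplicate and reflect across the midsagittal plane to
                    obtain the curvature template
4. ``register``   — optional landmark-based rigid alignment of the template
5. ``markers``    — load a marker file, or place edge markers on detected rim
                    loops and seeded surface markers on the template
6. ``smooth``     — border-weighted Laplacian smoothing of the marker cloud
7. ``triangulate``— Delaunay + alpha filtering (+ largest-component cleanup)
8. ``extract``    — boundary surface of the kept tet complex
9. ``write``      — implant STL and a JSON report

A single top-level seed fans out to all stochastic substeps, so the same
config and seed give byte-identical output; on failure the stage name is
attached to the error and partial outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, implant_mesh, markers as markers_mod, mesh_io, smoother
from .errors import CranioplanError, ParameterError, PipelineError, TopologyError
from .geometry import Plane, boundary_loops
from .markers import MarkerSet
from .mesh_io import TriangleMesh
from .smoother import SmoothParams

__all__ = ["AutoMarkerParams", "PlanConfig", "PlanReport", "plan_implant", "auto_place_markers"]

STAGE_ORDER = (
    "load",
    "center",
    "mirror",
    "register",
    "markers",
    "smooth",
    "triangulate",
    "extract",
    "write",
)


@dataclass(frozen=True)
class AutoMarkerParams:
    """Programmatic marker placement.

    ``n_edge`` markers go on each detected rim loop (longest loop = outer
    rim, type 0; second = inner rim, type 1).  Surface markers sample the
    template's outer table inside a sphere centered on the outer-rim
    centroid; its radius is ``region_factor`` times the maximum
    center-to-rim distance, keeping samples inside the defect footprint.
    Inner-surface markers are outer samples pushed ``thickness`` mm inward.
    """

    n_edge: int = 24
    n_outer_surface: int = 40
    n_inner_surface: int = 40
    thickness: float = 4.0
    region_factor: float = 0.9

    def __post_init__(self) -> None:
        if self.n_edge < 3:
            raise ParameterError("n_edge must be >= 3")
        if self.n_outer_surface < 1 or self.n_inner_surface < 1:
            raise ParameterError("surface marker counts must be >= 1")
        if self.thickness <= 0:
            raise ParameterError("thickness must be > 0")
        if not 0 < self.region_factor <= 2:
            raise ParameterError("region_factor must be in (0, 2]")


@dataclass
class PlanConfig:
    """Declarative description of one planning run."""

    input_path: str | Path
    mirror_plane: Plane = field(default_factory=Plane)
    register_landmarks: tuple[np.ndarray, np.ndarray] | None = None  # (template pts, skull pts)
    markers_path: str | Path | None = None
    auto_markers: AutoMarkerParams = field(default_factory=AutoMarkerParams)
    smooth: SmoothParams = field(default_factory=SmoothParams)
    smooth_enabled: bool = True
    alpha: float | None = 20.0
    dedupe_tol: float = 1e-6
    keep_largest_component: bool = True
    implant_path: str | Path | None = None
    report_path: str | Path | None = None
    seed: int = 0


PlanReport = dict  # JSON-serializable per-stage record


def auto_place_markers(
    defect_mesh: TriangleMesh,
    template_mesh: TriangleMesh,
    params: AutoMarkerParams,
    seed: int = 0,
) -> MarkerSet:
    """Reproducible stand-in for interactive marker clicking.

    Edge markers are resampled from the defect's rim loops; surface markers
    are drawn from the template's outward-facing faces within the defect
    region (see :class:`AutoMarkerParams`).
    """
    loops = boundary_loops(defect_mesh)
    if not loops:
        raise TopologyError("defect mesh has no rim loops; cannot auto-place edge markers")
    sets = [markers_mod.place_edge_markers(defect_mesh, loops[0], params.n_edge, 0)]
    if len(loops) > 1:
        sets.append(markers_mod.place_edge_markers(defect_mesh, loops[1], params.n_edge, 1))

    rim = defect_mesh.vertices[loops[0]]
    center = rim.mean(axis=0)
    radius = params.region_factor * float(np.linalg.norm(rim - center, axis=1).max())

    # restrict sampling to the template's outer table: faces whose normal
    # points away from the bounding-box center (the inner table faces inward)
    box_center = template_mesh.bounds.mean(axis=0)
    outwardness = np.einsum(
        "ij,ij->i", template_mesh.face_normals(), template_mesh.face_centroids() - box_center
    )
    outer_faces = template_mesh.faces[outwardness > 0]
    outer_template = TriangleMesh(template_mesh.vertices, outer_faces)

    ss = np.random.SeedSequence(seed)
    seed_outer, seed_inner = (np.random.default_rng(c) for c in ss.spawn(2))
    sets.append(
        markers_mod.place_surface_markers(
            outer_template, center, radius, params.n_outer_surface, 2, 0.0, seed_outer
        )
    )
    sets.append(
        markers_mod.place_surface_markers(
            outer_template,
            center,
            radius,
            params.n_inner_surface,
            3,
            params.thickness,
            seed_inner,
        )
    )
    return MarkerSet.concatenate(sets)


def plan_implant(config: PlanConfig) -> tuple[TriangleMesh, PlanReport]:
    """Run the full planning pipeline; returns the implant surface and a
    per-stage report (counts, parameters, timings, output digests)."""
    report: PlanReport = {"stages": [], "seed": config.seed}
    outputs_written: list[Path] = []
    stage = "load"

    def record(name: str, t0: float, **info) -> None:
        report["stages"].append({"stage": name, "seconds": round(time.perf_counter() - t0, 4), **info})

    try:
        t0 = time.perf_counter()
        skull = mesh_io.read_stl(config.input_path)
        record(stage, t0, vertices=skull.n_vertices, faces=skull.n_faces,
               path=str(config.input_path))

        stage = "center"
        t0 = time.perf_counter()
        skull, offset = geometry.center_mesh(skull)
        record(stage, t0, offset=[float(c) for c in offset])

        stage = "mirror"
        t0 = time.perf_counter()
        # the mirror plane is specified in *input* coordinates (it is a
        # property of the patient); carry it through the centering shift.
        # Centering a defect skull by its bbox is biased toward the intact
        # side, so interpreting the plane in the centered frame would offset
        # the template by twice that bias.
        plane = Plane(
            tuple(np.asarray(config.mirror_plane.point, dtype=float) - offset),
            config.mirror_plane.normal,
        )
        template = geometry.reflect_mesh(skull, plane)
        record(stage, t0, plane_point=[float(c) for c in plane.point],
               plane_normal=list(plane.normal))

        stage = "register"
        t0 = time.perf_counter()
        if config.register_landmarks is not None:
            src, dst = (
                np.asarray(lm, dtype=float).reshape(-1, 3) - offset
                for lm in config.register_landmarks
            )
            xform = geometry.rigid_register(src, dst)
            template = xform.apply_mesh(template)
            record(stage, t0, applied=True, translation=[float(c) for c in xform.translation])
        else:
            record(stage, t0, applied=False)

        stage = "markers"
        t0 = time.perf_counter()
        if config.markers_path is not None:
            mset = markers_mod.load_markers(config.markers_path)
            source = str(config.markers_path)
        else:
            mset = auto_place_markers(skull, template, config.auto_markers, config.seed)
            source = "auto"
        counts = {f"type{t}": int((mset.types == t).sum()) for t in range(4)}
        record(stage, t0, source=source, total=len(mset), **counts)

        stage = "smooth"
        t0 = time.perf_counter()
        if config.smooth_enabled:
            mset = smoother.smooth_markers(mset, config.smooth)
            record(stage, t0, applied=True, radius_x=config.smooth.radius_x,
                   border_weight_y=config.smooth.border_weight_y,
                   iterations=config.smooth.iterations)
        else:
            record(stage, t0, applied=False)

        stage = "triangulate"
        t0 = time.perf_counter()
        tets = implant_mesh.delaunay_tetrahedralize(mset.positions, config.dedupe_tol)
        n_raw = tets.n_tets
        tets = implant_mesh.alpha_filter(tets, config.alpha)
        n_alpha = tets.n_tets
        if config.keep_largest_component:
            # component filter and pinch repair can enable each other; iterate
            prev = -1
            while tets.n_tets != prev:
                prev = tets.n_tets
                tets = implant_mesh.keep_largest_component(tets)
                tets = implant_mesh.repair_pinched_edges(tets)
        record(stage, t0, tetrahedra=n_raw, after_alpha=n_alpha,
               after_component_filter=tets.n_tets,
               alpha=config.alpha, dedupe_tol=config.dedupe_tol)

        stage = "extract"
        t0 = time.perf_counter()
        implant = implant_mesh.extract_boundary_surface(tets)
        record(stage, t0, vertices=implant.n_vertices, faces=implant.n_faces)

        stage = "write"
        t0 = time.perf_counter()
        digests = {}
        if config.implant_path is not None:
            path = Path(config.implant_path)
            mesh_io.write_stl(implant, path, "binary")
            outputs_written.append(path)
            digests[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()
        record(stage, t0, outputs=digests)
        if config.report_path is not None:
            rp = Path(config.report_path)
            rp.write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
            outputs_written.append(rp)
    except CranioplanError as exc:
        for path in outputs_written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
    return implant, report
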