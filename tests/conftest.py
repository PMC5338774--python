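"""Shared fixtures: small geometric meshes and one standard phantom plan.

The end-to-end plan is session-scoped because several tests (pipeline,
acceptance) score the same run; everything is generated programmatically.
"""

from __future__ import annotations

import numpy as np
import pytest

import cranioplan as cp

STANDARD_SEED = 0


@pytest.fixture(scope="session")
def unit_tetrahedron() -> cp.TriangleMesh:
    """Closed positively-oriented tetrahedron."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return cp.TriangleMesh(verts, faces)


@pytest.fixture(scope="session")
def unit_cube() -> cp.TriangleMesh:
    """Axis-aligned [0,1]^3 cube, 12 outward-wound triangles."""
    x, y, z = np.meshgrid([0.0, 1.0], [0.0, 1.0], [0.0, 1.0], indexing="ij")
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    # vertex index = 4*i + 2*j + k
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0, normal -x
            [4, 7, 5], [4, 6, 7],  # x = 1, normal +x
            [0, 5, 1], [0, 4, 5],  # y = 0, normal -y
            [2, 3, 7], [2, 7, 6],  # y = 1, normal +y
            [0, 2, 6], [0, 6, 4],  # z = 0, normal -z
            [1, 5, 7], [1, 7, 3],  # z = 1, normal +z
        ]
    )
    mesh = cp.TriangleMesh(verts, faces)
    assert abs(mesh.signed_volume() - 1.0) < 1e-12
    return mesh


@pytest.fixture(scope="session")
def default_phantom() -> cp.phantom.PhantomResult:
    return cp.generate_phantom(cp.PhantomSpec())


@pytest.fixture(scope="session")
def standard_plan(tmp_path_factory, default_phantom):
    """One full planning run on the symmetric default phantom.

    Returns a dict with the implant, the report, the ground-truth patch in
    the implant's (centered) frame and the file paths used.
    """
    tmp = tmp_path_factory.mktemp("plan")
    defect_path = tmp / "defect.stl"
    cp.write_stl(default_phantom.defect_mesh, defect_path)
    config = cp.PlanConfig(
        input_path=defect_path,
        implant_path=tmp / "implant.stl",
        report_path=tmp / "report.json",
        seed=STANDARD_SEED,
    )
    implant, report = cp.plan_implant(config)
    _, offset = cp.center_mesh(cp.read_stl(defect_path))
    truth = cp.TriangleMesh(
        default_phantom.truth_patch.vertices - offset,
        default_phantom.truth_patch.faces,
    )
    return {
        "implant": implant,
        "report": report,
        "truth": truth,
        "config": config,
        "tmp": tmp,
        "defect_path": defect_path,
    }
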