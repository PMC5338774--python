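"""Centering, reflection, clipping, Procrustes registration, rim loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cranioplan as cp
from cranioplan.errors import DegenerateInputError, ParameterError, TopologyError

finite_coord = st.floats(-100, 100, allow_nan=False, allow_infinity=False)


def _rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestCenter:
    def test_two_point_example(self):
        mesh = cp.TriangleMesh(np.array([[0.0, 0, 0], [2, 2, 2]]), np.empty((0, 3), int))
        centered, offset = cp.center_mesh(mesh)
        np.testing.assert_allclose(centered.vertices, [[-1, -1, -1], [1, 1, 1]])
        np.testing.assert_allclose(offset, [1, 1, 1])

    def test_idempotent(self, unit_tetrahedron):
        once, _ = cp.center_mesh(unit_tetrahedron)
        twice, offset = cp.center_mesh(once)
        np.testing.assert_allclose(offset, 0, atol=1e-12)
        np.testing.assert_allclose(once.vertices, twice.vertices)

    def test_bbox_symmetric_after(self, default_phantom):
        centered, _ = cp.center_mesh(default_phantom.defect_mesh)
        np.testing.assert_allclose(centered.bounds[0], -centered.bounds[1], atol=1e-9)


class TestReflect:
    def test_default_plane_inverts_x(self):
        mesh = cp.TriangleMesh(np.array([[1.0, 2, 3]]), np.empty((0, 3), int))
        np.testing.assert_allclose(cp.reflect_mesh(mesh).vertices, [[-1, 2, 3]])

    def test_householder_offset_plane(self):
        # plane through (1,0,0), normal (1,0,0): hand-computed Householder map
        plane = cp.Plane((1, 0, 0), (1, 0, 0))
        mesh = cp.TriangleMesh(np.array([[3.0, 5, 7]]), np.empty((0, 3), int))
        np.testing.assert_allclose(cp.reflect_mesh(mesh, plane).vertices, [[-1, 5, 7]])

    @settings(deadline=None, max_examples=25)
    @given(
        pts=st.lists(st.tuples(finite_coord, finite_coord, finite_coord), min_size=3, max_size=8),
        normal=st.sampled_from([(1.0, 0, 0), (0, 1.0, 0), (0.6, 0.8, 0.0)]),
        point=st.tuples(finite_coord, finite_coord, finite_coord),
    )
    def test_involution_and_isometry(self, pts, normal, point):
        plane = cp.Plane(point, normal)
        mesh = cp.TriangleMesh(np.array(pts), np.empty((0, 3), int))
        refl = cp.reflect_mesh(mesh, plane)
        back = cp.reflect_mesh(refl, plane)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-9)
        d0 = np.linalg.norm(mesh.vertices[:, None] - mesh.vertices[None], axis=-1)
        d1 = np.linalg.norm(refl.vertices[:, None] - refl.vertices[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_area_preserved_and_winding_outward(self, unit_tetrahedron):
        refl = cp.reflect_mesh(unit_tetrahedron, cp.Plane((0, 0, 0), (0, 0, 1.0)))
        assert refl.face_areas().sum() == pytest.approx(
            unit_tetrahedron.face_areas().sum(), rel=1e-12
        )
        # closed surface stays positively oriented (outward) after reflection
        assert refl.signed_volume() == pytest.approx(
            unit_tetrahedron.signed_volume(), rel=1e-12
        )

    def test_unit_normal_required(self):
        with pytest.raises(ParameterError):
            cp.Plane((0, 0, 0), (1, 1, 0))


class TestClip:
    def test_keep_drop_straddle(self, unit_cube):
        plane = cp.Plane((0.5, 0, 0), (1.0, 0, 0))
        kept = cp.clip_mesh(unit_cube, plane)
        # only the x=1 face (2 triangles) lies fully on the kept side;
        # straddling side faces are dropped
        assert kept.n_faces == 2
        assert (kept.vertices[:, 0] == 1).all()
        other = cp.clip_mesh(unit_cube, plane.flipped())
        assert other.n_faces == 2  # x=0 face; all side faces straddle and vanish
        assert kept.n_faces + other.n_faces <= unit_cube.n_faces

    def test_partition_subset(self, unit_tetrahedron):
        plane = cp.Plane((0.2, 0, 0), (1.0, 0, 0))
        total = cp.clip_mesh(unit_tetrahedron, plane).n_faces + cp.clip_mesh(
            unit_tetrahedron, plane.flipped()
        ).n_faces
        assert total <= unit_tetrahedron.n_faces


class TestRigidRegister:
    def test_pure_translation(self):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        xf = cp.rigid_register(src, src + [5.0, 0, 0])
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(xf.translation, [5, 0, 0], atol=1e-9)

    def test_identity(self):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        xf = cp.rigid_register(src, src)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(xf.translation, 0, atol=1e-9)

    @pytest.mark.parametrize("angle", [np.pi / 2, 0.3, 2.0])
    def test_recovers_known_transform(self, angle):
        rng = np.random.default_rng(11)
        src = rng.normal(size=(6, 3)) * 10
        R = _rotation([1, 2, 3], angle)
        t = np.array([4.0, -2.0, 7.0])
        xf = cp.rigid_register(src, src @ R.T + t)
        assert np.linalg.norm(xf.rotation - R) < 1e-6
        assert np.linalg.norm(xf.translation - t) < 1e-6

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            cp.rigid_register(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateInputError):
            cp.rigid_register(line, line)


class TestBoundaryLoops:
    def test_closed_surface_has_none(self, unit_tetrahedron, unit_cube):
        assert cp.boundary_loops(unit_tetrahedron) == []
        assert cp.boundary_loops(unit_cube) == []

    def test_tetrahedron_minus_face(self, unit_tetrahedron):
        opened = cp.TriangleMesh(unit_tetrahedron.vertices, unit_tetrahedron.faces[:-1])
        loops = cp.boundary_loops(opened)
        assert len(loops) == 1
        assert sorted(loops[0]) == [1, 2, 3]

    def test_flat_square(self):
        square = cp.TriangleMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        loops = cp.boundary_loops(square)
        assert len(loops) == 1
        assert len(loops[0]) == 4
        # ordered cycle along the rim, not a zig-zag
        loop = list(loops[0])
        edges = {tuple(sorted(e)) for e in zip(loop, loop[1:] + loop[:1])}
        assert edges == {(0, 1), (1, 2), (2, 3), (0, 3)}

    def test_nonmanifold_edge_raises(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]])
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge (0,1) in 3 faces
        with pytest.raises(TopologyError):
            cp.boundary_loops(cp.TriangleMesh(verts, faces))

    def test_sorted_by_descending_length(self, default_phantom):
        loops = cp.boundary_loops(default_phantom.defect_mesh)
        assert len(loops) == 2  # outer rim and inner rim

        def length(loop):
            pts = default_phantom.defect_mesh.vertices[loop]
            return np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum()

        assert length(loops[0]) >= length(loops[1])


def test_plane_from_landmarks():
    plane = cp.plane_from_landmarks([0, 0, 0], [1, 0, 0], [0, 1, 0])
    np.testing.assert_allclose(np.abs(plane.n), [0, 0, 1])
    with pytest.raises(DegenerateInputError):
        cp.plane_from_landmarks([0, 0, 0], [1, 0, 0], [2, 0, 0])
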