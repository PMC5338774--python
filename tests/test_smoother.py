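"""Constrained Laplacian smoothing of the marker cloud."""

import numpy as np
import pytest
from scipy.optimize import linprog

import cranioplan as cp
from cranioplan.errors import ParameterError, SmoothingDismissedError


def _mset(rows):
    """rows: list of (x, y, z, type)."""
    arr = np.array(rows, dtype=float)
    return cp.MarkerSet(arr[:, :3], arr[:, 3].astype(int))


def brute_force_layer_mean(markers: cp.MarkerSet) -> np.ndarray:
    """Independent oracle: plain mean over all *other* same-layer markers
    (all weights 1, infinite radius), surface markers only."""
    out = markers.positions.copy()
    for i in range(len(markers)):
        if markers.is_border[i]:
            continue
        acc, n = np.zeros(3), 0
        for j in range(len(markers)):
            if j == i:
                continue
            if markers.is_outer_layer[i] != markers.is_outer_layer[j]:
                continue
            acc += markers.positions[j]
            n += 1
        if n:
            out[i] = acc / n
    return out


def in_convex_hull(point, vertices, tol=1e-9) -> bool:
    """Feasibility LP: point = sum(lam * v), lam >= 0, sum(lam) = 1."""
    n = len(vertices)
    res = linprog(
        c=np.zeros(n),
        A_eq=np.vstack([vertices.T, np.ones(n)]),
        b_eq=np.append(point, 1.0),
        bounds=[(0, None)] * n,
        method="highs",
    )
    return res.status == 0 and res.fun is not None


class TestNeighbors:
    def test_layers_never_mix(self):
        ms = _mset([(0, 0, 0, 2), (1, 0, 0, 3), (2, 0, 0, 2)])
        assert list(cp.neighbors_within_radius(ms, 0, 10.0)) == [2]

    def test_radius_inclusive(self):
        ms = _mset([(0, 0, 0, 2), (10.0, 0, 0, 2), (10.1, 0, 0, 2)])
        assert list(cp.neighbors_within_radius(ms, 0, 10.0)) == [1]

    def test_border_markers_are_neighbors(self):
        ms = _mset([(0, 0, 0, 2), (1, 0, 0, 0), (2, 0, 0, 1)])
        # outer-layer marker sees the outer edge marker, not the inner one
        assert list(cp.neighbors_within_radius(ms, 0, 10.0)) == [1]


class TestSmoothExamples:
    def test_plain_mean_of_two_neighbors(self):
        ms = _mset([(1, 1, 0, 2), (0, 0, 0, 2), (2, 0, 0, 2)])
        out = cp.smooth_markers(ms, cp.SmoothParams(10.0, 1.0, 1))
        np.testing.assert_allclose(out.positions[0], [1, 0, 0], atol=1e-12)

    def test_edge_markers_bitwise_fixed(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(20, 3)) * 10
        types = np.array([0, 1] * 5 + [2, 3] * 5)
        ms = cp.MarkerSet(pos, types)
        for iters in (1, 3, 7):
            out = cp.smooth_markers(ms, cp.SmoothParams(50.0, 3.0, iters))
            border = ms.is_border
            assert np.array_equal(out.positions[border], ms.positions[border])

    def test_weighted_border_mean(self):
        # neighbors: edge marker at origin with weight 2, surface at (3,0,0):
        # (2*(0,0,0) + 1*(3,0,0)) / 3 = (1,0,0)
        ms = _mset([(9, 9, 9, 2), (0, 0, 0, 0), (3, 0, 0, 2)])
        out = cp.smooth_markers(ms, cp.SmoothParams(100.0, 2.0, 1))
        np.testing.assert_allclose(out.positions[0], [1, 0, 0], atol=1e-12)

    def test_isolated_surface_marker_unchanged(self):
        ms = _mset([(100, 100, 100, 2), (0, 0, 0, 2), (1, 0, 0, 2)])
        out = cp.smooth_markers(ms, cp.SmoothParams(5.0, 1.0, 1))
        np.testing.assert_allclose(out.positions[0], [100, 100, 100])

    def test_dismissed_below_three_markers(self):
        ms = _mset([(0, 0, 0, 2), (1, 0, 0, 2)])
        with pytest.raises(SmoothingDismissedError):
            cp.smooth_markers(ms, cp.SmoothParams())

    @pytest.mark.parametrize(
        "kwargs",
        [dict(radius_x=0.0), dict(radius_x=-1.0), dict(border_weight_y=0.5), dict(iterations=0)],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ParameterError):
            cp.SmoothParams(**{**dict(radius_x=1.0, border_weight_y=1.0, iterations=1), **kwargs})


class TestSmoothProperties:
    @pytest.mark.parametrize("trial", range(50))
    def test_matches_brute_force_oracle_at_infinite_radius(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = rng.integers(3, 15)
        ms = cp.MarkerSet(rng.normal(size=(n, 3)) * 30, rng.integers(0, 4, n))
        out = cp.smooth_markers(ms, cp.SmoothParams(1e9, 1.0, 1))
        np.testing.assert_allclose(out.positions, brute_force_layer_mean(ms), atol=1e-9)

    def test_update_stays_in_neighbor_hull(self):
        rng = np.random.default_rng(42)
        ms = cp.MarkerSet(rng.normal(size=(25, 3)) * 20, rng.integers(0, 4, 25))
        params = cp.SmoothParams(25.0, 2.0, 1)
        out = cp.smooth_markers(ms, params)
        for i in range(len(ms)):
            if ms.is_border[i]:
                continue
            nb = cp.neighbors_within_radius(ms, i, params.radius_x)
            if len(nb) == 0:
                continue
            assert in_convex_hull(out.positions[i], ms.positions[nb])

    def test_order_independence_within_layer(self):
        rng = np.random.default_rng(5)
        ms = cp.MarkerSet(rng.normal(size=(16, 3)) * 10, rng.integers(0, 4, 16))
        perm = rng.permutation(16)
        params = cp.SmoothParams(12.0, 2.0, 2)
        out = cp.smooth_markers(ms, params)
        out_perm = cp.smooth_markers(
            cp.MarkerSet(ms.positions[perm], ms.types[perm]), params
        )
        np.testing.assert_allclose(out_perm.positions, out.positions[perm], atol=1e-12)

    def test_counts_types_layers_conserved(self):
        rng = np.random.default_rng(6)
        ms = cp.MarkerSet(rng.normal(size=(12, 3)), rng.integers(0, 4, 12))
        out = cp.smooth_markers(ms, cp.SmoothParams(3.0, 1.5, 4))
        assert len(out) == len(ms)
        np.testing.assert_array_equal(out.types, ms.types)

    def test_chain_displacement_non_increasing(self):
        # 1D chain: fixed edge markers at the ends, surface markers between
        x = np.linspace(0, 10, 12)
        y = np.array([0.0] + list(np.sin(np.arange(10))) + [0.0])
        pos = np.stack([x, y, np.zeros(12)], axis=1)
        types = np.array([0] + [2] * 10 + [0])
        ms = cp.MarkerSet(pos, types)
        params = cp.SmoothParams(1.2, 1.0, 1)
        disps = []
        cur = ms
        for _ in range(8):
            nxt = cp.smooth_markers(cur, params)
            disps.append(np.linalg.norm(nxt.positions - cur.positions, axis=1).max())
            cur = nxt
        for a, b in zip(disps[1:], disps[2:]):
            assert b <= a + 1e-12


def test_roughness_decreases_after_smoothing():
    rng = np.random.default_rng(8)
    base = np.stack([np.repeat(np.arange(6), 6), np.tile(np.arange(6), 6)], axis=1) * 4.0
    pos = np.column_stack([base, rng.normal(scale=1.0, size=36)])
    ms = cp.MarkerSet(pos, np.full(36, 2))
    out = cp.smooth_markers(ms, cp.SmoothParams(6.0, 1.0, 1))
    assert cp.marker_roughness(out, 6.0) < cp.marker_roughness(ms, 6.0)
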