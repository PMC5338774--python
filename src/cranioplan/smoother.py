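"""Radius-limited, layer-respecting, border-weighted Laplacian smoothing of
the marker cloud.

Plain Laplacian smoothing moves every point to the arithmetic mean of its
neighbors,

    x_i  =  (1/N) * sum_j x_j ,

where the N neighbors of marker i are the *other* markers of the same layer
(outer {0, 2} vs inner {1, 3}) within the neighborhood radius ``radius_x``.
Two constraints adapt this to implant planning:

* Edge (border) markers, types 0 and 1, were placed on the defect rim and
  are "true" positions: they never move, which anchors the implant to the
  bone and counters the shrinkage Laplacian smoothing otherwise causes.
* Edge markers may be up-weighted by ``border_weight_y`` >= 1, pulling the
  free surface markers toward the rim.  The update becomes the weighted
  mean sum(w_j x_j) / sum(w_j) with w_j = border_weight_y for edge
  neighbors and 1 otherwise; at border_weight_y = 1 this is exactly the
  plain mean above.

Updates are simultaneous (Jacobi) within an iteration, so the result does
not depend on marker order.  A surface marker with no neighbor in radius
keeps its position.  The operation is dismissed outright for fewer than
three markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SmoothingDismissedError
from .markers import MarkerSet

__all__ = ["SmoothParams", "neighbors_within_radius", "smooth_markers", "marker_roughness"]


@dataclass(frozen=True)
class SmoothParams:
    """Smoothing knobs: neighborhood radius (mm), border-marker weight
    (dimensionless, >= 1) and iteration count."""

    radius_x: float = 6.0
    border_weight_y: float = 2.0
    iterations: int = 1

    def __post_init__(self) -> None:
        if not self.radius_x > 0:
            raise ParameterError("radius_x must be more than zero")
        if not self.border_weight_y >= 1:
            raise ParameterError("border_weight_y must be at least one")
        if not (isinstance(self.iterations, int) and self.iterations >= 1):
            raise ParameterError("iterations must be a positive integer")


def _neighbor_matrix(markers: MarkerSet, radius: float) -> np.ndarray:
    """Boolean (n, n) adjacency: same layer, distance <= radius, j != i."""
    d = cdist(markers.positions, markers.positions)
    same_layer = markers.is_outer_layer[:, None] == markers.is_outer_layer[None, :]
    adj = same_layer & (d <= radius)
    np.fill_diagonal(adj, False)
    return adj


def neighbors_within_radius(markers: MarkerSet, i: int, radius_x: float) -> np.ndarray:
    """Indices of markers adjacent to marker ``i``: same layer and within
    ``radius_x`` (inclusive).  Border markers of the layer count as neighbors."""
    if not 0 <= i < len(markers):
        raise ParameterError(f"marker index {i} out of range")
    if not radius_x > 0:
        raise ParameterError("radius_x must be more than zero")
    return np.flatnonzero(_neighbor_matrix(markers, radius_x)[i])


def smooth_markers(markers: MarkerSet, params: SmoothParams) -> MarkerSet:
    """Return a smoothed copy of ``markers``; order and types are preserved.

    Each iteration recomputes neighborhoods from the current positions and
    replaces every surface marker (types 2, 3) by the border-weighted mean of
    its neighbors simultaneously.  Edge markers are returned bit-identical.
    """
    if len(markers) < 3:
        raise SmoothingDismissedError(
            "smoothing dismissed: the list consists of less than three markers"
        )
    pos = markers.positions.copy()
    movable = markers.is_surface
    weights = np.where(markers.is_border, float(params.border_weight_y), 1.0)
    for _ in range(params.iterations):
        work = MarkerSet(pos, markers.types)
        adj = _neighbor_matrix(work, params.radius_x)
        w = adj * weights[None, :]  # (i, j) weight of neighbor j for marker i
        wsum = w.sum(axis=1)
        has_neighbors = movable & (wsum > 0)
        new_pos = pos.copy()
        new_pos[has_neighbors] = (w[has_neighbors] @ pos) / wsum[has_neighbors, None]
        pos = new_pos
    return MarkerSet(pos, markers.types.copy())


def marker_roughness(markers: MarkerSet, radius: float) -> float:
    """Mean Laplacian residual of the surface markers (mm).

    For every surface marker with at least one neighbor in ``radius`` this is
    the distance between the marker and the unweighted mean of its neighbors,
    averaged — the quantity one smoothing pass with weight 1 drives down, and
    a simple roughness score for before/after comparisons.
    """
    if len(markers) == 0:
        raise ParameterError("empty marker set")
    adj = _neighbor_matrix(markers, radius)
    counts = adj.sum(axis=1)
    mask = markers.is_surface & (counts > 0)
    if not mask.any():
        return 0.0
    means = (adj[mask] @ markers.positions) / counts[mask, None]
    return float(np.linalg.norm(markers.positions[mask] - means, axis=1).mean())
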