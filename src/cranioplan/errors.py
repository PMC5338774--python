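"""Exception hierarchy.

Every failure mode the planning pipeline can hit maps to one of these, so
callers (and the CLI) can distinguish bad files from bad parameters from
genuinely degenerate geometry.
"""


class CranioplanError(Exception):
    """Base class for all package errors."""


class FormatError(CranioplanError, ValueError):
    """A file does not conform to its declared format (STL, marker CSV/JSON...)."""


class ParameterError(CranioplanError, ValueError):
    """A user-supplied parameter violates its contract."""


class DegenerateInputError(CranioplanError):
    """Input geometry carries too little information (collinear landmarks,
    coplanar point cloud, ...)."""


class TopologyError(CranioplanError):
    """Mesh connectivity violates a required property (non-manifold edge,
    open surface where a watertight one is needed)."""


class EmptyRegionError(CranioplanError):
    """A spatial query region contains no candidate faces."""


class EmptyResultError(CranioplanError):
    """A filter removed everything; carries diagnostic context."""

    def __init__(self, message: str, min_circumradius: float | None = None):
        super().__init__(message)
        self.min_circumradius = min_circumradius


class GridMismatchError(CranioplanError):
    """Two voxel grids that must be identical are not."""


class UndefinedMetricError(CranioplanError):
    """A metric is mathematically undefined for the given inputs (e.g. both
    occupancy sets empty)."""


class SmoothingDismissedError(CranioplanError):
    """Smoothing refused to run: fewer than three markers."""


class PipelineError(CranioplanError):
    """A pipeline stage failed; remembers which one."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
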