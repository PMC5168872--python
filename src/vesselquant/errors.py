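"""Exception hierarchy for vesselquant.

Every stage raises a subclass of :class:`VesselQuantError` so the pipeline can
abort with the stage name and branch label attached.
"""


class VesselQuantError(Exception):
    """Base class for all vesselquant errors."""


class DegenerateBranchError(VesselQuantError):
    """Fewer than 2 distinct skeleton points."""


class AlignmentError(VesselQuantError):
    """Per-point attributes (radii) do not align with the points."""


class InsufficientPointsError(VesselQuantError):
    """Not enough points for the requested spline degree."""


class RankDeficientError(VesselQuantError):
    """Normal equations of the least-squares fit are singular."""


class ParameterRangeError(VesselQuantError):
    """Curve parameter outside [0, 1]."""


class SingularParameterizationError(VesselQuantError):
    """First derivative vanishes; curvature undefined."""


class DegenerateAngleError(VesselQuantError):
    """Zero-length vector in an included-angle computation."""


class EnvelopeDegenerateError(VesselQuantError):
    """Radius grows at least as fast as arc length; no real tangency circle."""


class NoRadiusSplineError(VesselQuantError):
    """Operation requires a fitted radius spline."""


class InvalidSampleCountError(VesselQuantError):
    """Sample count below the minimum for the operation."""


class SkeletonNotConnectedError(VesselQuantError):
    """Skeleton graph has more than one connected component."""


class InvalidRootError(VesselQuantError):
    """BFS root is not a node of the graph."""


class LabelCollisionError(VesselQuantError):
    """Two branches mapped to the same anatomic label."""


class InvalidPhantomError(VesselQuantError):
    """Phantom parameters are non-physical."""


class UnsupportedFormatError(VesselQuantError):
    """File format not recognised by the reader."""


class MalformedInputError(VesselQuantError):
    """Input file violates its declared format."""
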