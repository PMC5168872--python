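"""Core domain types shared by every stage of the pipeline.

All coordinates are physical millimetres (voxel index times spacing when a
point set originates from a volume), 0-based indexing, x-fastest axis order
for volumes. These containers validate their invariants on construction and
round-trip losslessly through ``to_dict`` / ``from_dict``; all computation
lives in the other modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, DegenerateBranchError


@dataclass
class SkeletonPointSet:
    """Ordered raw skeleton points of one vessel branch.

    Parameters
    ----------
    points
        (n, 3) array of 3D coordinates in mm, ordered along the branch.
    radii
        Optional (n,) array of nonnegative per-point radii in mm.
    branch_label
        Optional anatomic name, e.g. ``"ACo"`` or ``"PCAr"``.
    source_spacing
        Optional (3,) voxel spacing in mm of the volume the skeleton came
        from; informational only.
    """

    points: np.ndarray
    radii: Optional[np.ndarray] = None
    branch_label: Optional[str] = None
    source_spacing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise DegenerateBranchError("points must be an (n, 3) array")
        if len(self.points) < 2:
            raise DegenerateBranchError(
                "degenerate branch: fewer than 2 points")
        diffs = np.diff(self.points, axis=0)
        if np.any(np.all(diffs == 0.0, axis=1)):
            raise DegenerateBranchError(
                "degenerate branch: consecutive duplicate points "
                "(use validate_point_set to collapse them)")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (len(self.points),):
                raise AlignmentError(
                    f"alignment error: {len(self.radii)} radii for "
                    f"{len(self.points)} points")
            if np.any(~np.isfinite(self.radii)) or np.any(self.radii < 0):
                raise AlignmentError(
                    "alignment error: radii must be finite and >= 0")
        if self.source_spacing is not None:
            self.source_spacing = np.asarray(self.source_spacing, dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def chord_lengths(self) -> np.ndarray:
        """Consecutive chord lengths in mm, shape (n-1,)."""
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def total_chord_length(self) -> float:
        return float(self.chord_lengths.sum())

    def to_dict(self) -> dict:
        d = {"points": self.points.tolist()}
        if self.radii is not None:
            d["radii"] = self.radii.tolist()
        if self.branch_label is not None:
            d["branch_label"] = self.branch_label
        if self.source_spacing is not None:
            d["source_spacing"] = self.source_spacing.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonPointSet":
        return cls(
            points=np.asarray(d["points"], dtype=float),
            radii=np.asarray(d["radii"], dtype=float) if "radii" in d else None,
            branch_label=d.get("branch_label"),
            source_spacing=(np.asarray(d["source_spacing"], dtype=float)
                            if "source_spacing" in d else None),
        )


def validate_point_set(
    points: Sequence,
    radii: Optional[Sequence] = None,
    branch_label: Optional[str] = None,
    source_spacing: Optional[Sequence] = None,
) -> SkeletonPointSet:
    """Validate a raw point list into a :class:`SkeletonPointSet`.

    Consecutive duplicate points are collapsed (keeping the first occurrence
    and its radius); the original order is otherwise preserved.

    Raises
    ------
    DegenerateBranchError
        Fewer than 2 distinct points remain.
    AlignmentError
        ``radii`` is present but does not align 1:1 with ``points`` or
        contains non-finite / negative entries.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        if pts.ndim == 1 and pts.size == 3:
            pts = pts.reshape(1, 3)
        else:
            raise DegenerateBranchError("points must be an (n, 3) array")
    r = None
    if radii is not None:
        r = np.asarray(radii, dtype=float)
        if r.shape != (len(pts),):
            raise AlignmentError(
                f"alignment error: {r.size} radii for {len(pts)} points")
    if len(pts) < 2:
        raise DegenerateBranchError("degenerate branch: fewer than 2 points")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if r is not None:
        r = r[keep]
    if len(pts) < 2:
        raise DegenerateBranchError(
            "degenerate branch: fewer than 2 distinct points")
    return SkeletonPointSet(points=pts, radii=r, branch_label=branch_label,
                            source_spacing=source_spacing)


@dataclass
class FittedVessel:
    """A clamped B-spline centerline p(u) = sum_i N_{i,k}(u) p_i on [0, 1].

    Optionally carries a scalar radius spline r(u) = sum_i N_{i,k}(u) r_i on
    the same knot vector.
    """

    degree: int
    knots: np.ndarray
    ctrl_points: np.ndarray
    ctrl_radii: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.ctrl_points = np.asarray(self.ctrl_points, dtype=float)
        k, t, c = self.degree, self.knots, self.ctrl_points
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("ctrl_points must be (m, 3)")
        if len(t) != len(c) + k + 1:
            raise ValueError(
                f"knot count {len(t)} != n_ctrl {len(c)} + degree {k} + 1")
        if np.any(np.diff(t) < 0):
            raise ValueError("knots must be nondecreasing")
        if not (np.allclose(t[:k + 1], t[0]) and np.allclose(t[-k - 1:], t[-1])):
            raise ValueError("knot vector must be clamped "
                             "(end multiplicities degree+1)")
        if self.ctrl_radii is not None:
            self.ctrl_radii = np.asarray(self.ctrl_radii, dtype=float)
            if self.ctrl_radii.shape != (len(c),):
                raise ValueError("ctrl_radii must align with ctrl_points")

    @property
    def n_ctrl(self) -> int:
        return len(self.ctrl_points)

    @property
    def param_domain(self) -> tuple:
        return (float(self.knots[self.degree]),
                float(self.knots[-self.degree - 1]))

    def to_dict(self) -> dict:
        d = {
            "degree": int(self.degree),
            "knots": self.knots.tolist(),
            "ctrl_points": self.ctrl_points.tolist(),
        }
        if self.ctrl_radii is not None:
            d["ctrl_radii"] = self.ctrl_radii.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedVessel":
        return cls(
            degree=int(d["degree"]),
            knots=np.asarray(d["knots"], dtype=float),
            ctrl_points=np.asarray(d["ctrl_points"], dtype=float),
            ctrl_radii=(np.asarray(d["ctrl_radii"], dtype=float)
                        if "ctrl_radii" in d else None),
        )


@dataclass
class GeometryProfile:
    """Uniform-arc-length samples of one fitted branch.

    ``n_samples`` points are placed at equal arc-length increments from one
    end of the curve to the other (default 20). Curvature and torsion are in
    1/mm, radii in mm, angles in radians. Torsion and envelope radius may be
    NaN at samples where the quantity is numerically undefined (locally
    straight curve, degenerate envelope); ``angle`` is NaN at the two
    endpoints, where the included angle is not defined.
    """

    params: np.ndarray
    arc_positions: np.ndarray
    curvature: np.ndarray
    torsion: np.ndarray
    total_length: float
    radius: Optional[np.ndarray] = None
    angle: Optional[np.ndarray] = None
    branch_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        self.torsion = np.asarray(self.torsion, dtype=float)
        n = len(self.params)
        if n < 2:
            raise ValueError("profile needs at least 2 samples")
        gaps = np.diff(self.arc_positions)
        if np.any(gaps <= 0):
            raise ValueError("arc_positions must be strictly increasing")
        if not np.allclose(gaps, gaps[0], rtol=1e-6):
            raise ValueError("arc gaps not uniform within 1e-6 relative")
        with np.errstate(invalid="ignore"):
            if np.any(self.curvature < 0):
                raise ValueError("curvature must be nonnegative")
        for name in ("radius", "angle"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.params)

    def to_dict(self) -> dict:
        d = {
            "params": self.params.tolist(),
            "arc_positions": self.arc_positions.tolist(),
            "curvature": self.curvature.tolist(),
            "torsion": self.torsion.tolist(),
            "total_length": float(self.total_length),
        }
        if self.radius is not None:
            d["radius"] = self.radius.tolist()
        if self.angle is not None:
            d["angle"] = self.angle.tolist()
        if self.branch_label is not None:
            d["branch_label"] = self.branch_label
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryProfile":
        return cls(
            params=np.asarray(d["params"], dtype=float),
            arc_positions=np.asarray(d["arc_positions"], dtype=float),
            curvature=np.asarray(d["curvature"], dtype=float),
            torsion=np.asarray(d["torsion"], dtype=float),
            total_length=float(d["total_length"]),
            radius=(np.asarray(d["radius"], dtype=float)
                    if "radius" in d else None),
            angle=(np.asarray(d["angle"], dtype=float)
                   if "angle" in d else None),
            branch_label=d.get("branch_label"),
        )


@dataclass
class BranchStatistics:
    """Per-branch summary row: length, per-quantity mean/variance, fit error.

    Variances are population variances (divide by the number of defined
    samples) unless computed otherwise upstream; NaN marks a quantity with no
    defined samples. ``torsion_undefined`` counts samples where torsion could
    not be evaluated (locally straight curve).
    """

    branch_label: str
    length: float
    curvature_mean: float
    curvature_var: float
    torsion_mean: float
    torsion_var: float
    radius_mean: float
    radius_var: float
    angle_mean: float
    angle_var: float
    error_sum: float
    error_mean: float
    error_var: float
    torsion_undefined: int = 0

    def to_dict(self) -> dict:
        return {
            "branch_label": self.branch_label,
            "length": self.length,
            "curvature_mean": self.curvature_mean,
            "curvature_var": self.curvature_var,
            "torsion_mean": self.torsion_mean,
            "torsion_var": self.torsion_var,
            "radius_mean": self.radius_mean,
            "radius_var": self.radius_var,
            "angle_mean": self.angle_mean,
            "angle_var": self.angle_var,
            "error_sum": self.error_sum,
            "error_mean": self.error_mean,
            "error_var": self.error_var,
            "torsion_undefined": self.torsion_undefined,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BranchStatistics":
        return cls(**d)


@dataclass
class VesselTree:
    """Skeleton graph: nodes are point ids, branches are junction-to-junction
    (or junction-to-terminal) paths whose interior nodes have degree 2.

    ``parent`` maps each non-root node to its BFS parent after orientation;
    ``labels`` maps branch index to an anatomic name.
    """

    node_points: np.ndarray
    edges: list = field(default_factory=list)
    branches: list = field(default_factory=list)
    branch_node_ids: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    terminals: list = field(default_factory=list)
    cycle_count: int = 0
    root: Optional[int] = None
    parent: Optional[dict] = None
    labels: dict = field(default_factory=dict)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branch_name(self, index: int) -> str:
        return self.labels.get(index, f"branch_{index}")

    def to_dict(self) -> dict:
        return {
            "node_points": self.node_points.tolist(),
            "edges": [list(map(int, e)) for e in self.edges],
            "branch_node_ids": [list(map(int, b))
                                for b in self.branch_node_ids],
            "junctions": list(map(int, self.junctions)),
            "terminals": list(map(int, self.terminals)),
            "cycle_count": int(self.cycle_count),
            "root": None if self.root is None else int(self.root),
            "labels": {str(k): v for k, v in self.labels.items()},
        }
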