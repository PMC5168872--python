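"""Vessel radius from the envelope-of-spheres (canal surface) model.

The vessel wall is modelled as the envelope of the one-parameter family of
spheres centered on the centerline p(u) with radius r(u). The envelope
touches each sphere along a circle: the intersection of the sphere
||x - p(u)|| = r(u) with the plane p'(u)·(x - p(u)) = -r(u) r'(u). The
center of that circle lies offset from the sphere center along the tangent
by |OP| = -r r' / ||p'||, and its radius — the measured vessel radius — is

    R(u) = sqrt(r(u)^2 - |OP|^2) = r(u) sqrt(1 - (dr/ds)^2).

R is real only while the radius grows slower than arc length (|dr/ds| < 1);
otherwise the sphere family has no real tangency circle and the sample is
degenerate.

Raw per-point radii (the data behind r(u)) are estimated as the distance
from each skeleton point to the segmentation boundary, given either a
binary volume (anisotropic Euclidean distance transform in physical mm) or
a triangle mesh (exact nearest-surface distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bspline import evaluate, evaluate_radius
from .errors import (
    EnvelopeDegenerateError,
    NoRadiusSplineError,
    SingularParameterizationError,
)
from .model import FittedVessel, GeometryProfile, SkeletonPointSet

#: relative margin below which r^2 - |OP|^2 is treated as degenerate
_DEGENERATE_RTOL = 1e-9


@dataclass
class EnvelopeSample:
    """Envelope geometry at one parameter: sphere radius r(u), signed
    tangential offset |OP| of the tangency-circle center, and the envelope
    (vessel) radius R <= r(u)."""

    u: float
    sphere_radius: float
    op_offset: float
    envelope_radius: float


def envelope_radius(vessel: FittedVessel, u: float) -> EnvelopeSample:
    """Envelope radius R at parameter u.

    With C = r(u), G = r'(u) and (D, E, F) = p'(u):

        offset = -C G / sqrt(D^2 + E^2 + F^2)      (signed along the tangent)
        R      = sqrt(C^2 - offset^2)

    Raises
    ------
    NoRadiusSplineError
        The vessel has no fitted radius spline.
    EnvelopeDegenerateError
        C^2 < offset^2 — the radius grows at least as fast as arc length, so
        no real tangency circle exists at u.
    SingularParameterizationError
        ||p'(u)|| vanishes.
    """
    if vessel.ctrl_radii is None:
        raise NoRadiusSplineError("no radius spline")
    C = float(evaluate_radius(vessel, u))
    G = float(evaluate_radius(vessel, u, 1))
    d1 = evaluate(vessel, u, 1)
    speed = float(np.linalg.norm(d1))
    if speed <= 1e-9:
        raise SingularParameterizationError(
            f"singular parameterization at u={u}")
    offset = -C * G / speed
    # degenerate when |dr/ds| >= 1 (up to fp noise): offset^2 >= C^2
    if offset != 0.0 and offset * offset >= C * C * (1.0 - _DEGENERATE_RTOL):
        raise EnvelopeDegenerateError(
            f"envelope degenerate at u={u}: |dr/ds| >= 1")
    rad2 = max(C * C - offset * offset, 0.0)
    return EnvelopeSample(u=float(u), sphere_radius=C, op_offset=offset,
                          envelope_radius=float(np.sqrt(rad2)))


def radius_profile(vessel: FittedVessel,
                   profile: GeometryProfile) -> np.ndarray:
    """Fill ``profile.radius`` with the envelope radius R at each sample.

    Degenerate samples (|dr/ds| >= 1) are marked NaN, counted, and excluded
    from downstream statistics. Returns the radius array.
    """
    if vessel.ctrl_radii is None:
        raise NoRadiusSplineError("no radius spline")
    out = np.full(profile.n_samples, np.nan)
    n_degenerate = 0
    for i, u in enumerate(profile.params):
        try:
            out[i] = envelope_radius(vessel, float(u)).envelope_radius
        except EnvelopeDegenerateError:
            n_degenerate += 1
    if n_degenerate:
        warnings.warn(f"{n_degenerate} of {profile.n_samples} samples have a "
                      "degenerate envelope (|dr/ds| >= 1)", stacklevel=2)
    profile.radius = out
    return out


def sphere_radius_profile(vessel: FittedVessel,
                          profile: GeometryProfile) -> np.ndarray:
    """Raw sphere radii r(u) at the profile samples (the fitted radius
    spline itself, without the envelope correction)."""
    if vessel.ctrl_radii is None:
        raise NoRadiusSplineError("no radius spline")
    return np.asarray(evaluate_radius(vessel, profile.params), dtype=float)


def estimate_point_radii(point_set: SkeletonPointSet, boundary,
                         spacing=None, origin=None) -> np.ndarray:
    """Initial per-point radius: distance from each skeleton point to the
    segmentation boundary, in mm.

    Parameters
    ----------
    point_set
        Skeleton points in physical mm.
    boundary
        Either a binary volume (3D numpy array, nonzero = lumen; requires
        ``spacing`` and optionally ``origin``) or a ``trimesh.Trimesh``
        surface mesh.
    spacing, origin
        Physical voxel spacing / volume origin (mm) when ``boundary`` is a
        volume. The distance transform is the exact Euclidean transform with
        anisotropic sampling, so 0.5 x 0.5 x 0.8 mm volumes are handled
        correctly. Volumes are indexed [x, y, z] (x-fastest axis order).

    Notes
    -----
    A skeleton point that falls outside the segmented lumen gets radius 0
    and triggers a "point outside lumen" warning.
    """
    pts = point_set.points
    if hasattr(boundary, "faces"):  # trimesh.Trimesh
        from trimesh.proximity import closest_point_naive
        _, dist, _ = closest_point_naive(boundary, pts)
        return np.asarray(dist, dtype=float)
    vol = np.asarray(boundary)
    if spacing is None:
        raise ValueError("spacing required for volume boundaries")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    from scipy.ndimage import distance_transform_edt, map_coordinates
    dt = distance_transform_edt(vol != 0, sampling=spacing)
    idx = ((pts - origin) / spacing).T  # (3, n), x-fastest order
    radii = map_coordinates(dt, idx, order=1, mode="constant", cval=0.0)
    inside = map_coordinates((vol != 0).astype(float), idx, order=0,
                             mode="constant", cval=0.0)
    if np.any(inside == 0.0):
        warnings.warn(f"{int(np.sum(inside == 0))} skeleton point(s) outside "
                      "lumen", stacklevel=2)
    return np.asarray(radii, dtype=float)
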