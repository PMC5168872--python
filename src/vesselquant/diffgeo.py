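"""Differential geometry of a fitted vessel centerline.

All descriptors are computed from the analytic B-spline derivatives:

    arc length      L = ∫ ||p'(u)|| du
    curvature       κ(u) = ||p'(u) × p''(u)|| / ||p'(u)||^3
    torsion         τ(u) = (p', p'', p''') / ||p' × p''||^2
    included angle  θ at sample B: the interior angle ∠(B→A, B→C) between the
                    branch endpoints A and C

κ is nonnegative with units 1/mm; τ is signed (chirality) with units 1/mm
and is undefined (NaN) where the curve is locally straight
(||p' × p''|| below a threshold) — reporting a value there would only
amplify numerical noise. Arc-length integrals of κ and τ serve as global
per-branch descriptors.

Quadrature is fixed Gauss–Legendre per knot span (16 nodes); the integrand
is piecewise-smooth on spans, so the rule is deterministic and accurate to
near machine precision on cubic splines.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .bspline import evaluate
from .errors import (
    DegenerateAngleError,
    InvalidSampleCountError,
    SingularParameterizationError,
)
from .model import FittedVessel, GeometryProfile

logger = logging.getLogger(__name__)

GAUSS_NODES, GAUSS_WEIGHTS = np.polynomial.legendre.leggauss(16)

#: below this ||p'(u)||, the parameterization is considered singular
EPS_SPEED = 1e-9
#: below this ||p' x p''||, torsion is reported as undefined (NaN)
EPS_TORSION = 1e-8


def _span_breaks(vessel: FittedVessel, u0: float, u1: float) -> np.ndarray:
    t = np.unique(vessel.knots)
    t = t[(t > u0) & (t < u1)]
    return np.concatenate([[u0], t, [u1]])


def _speed(vessel: FittedVessel, u: np.ndarray) -> np.ndarray:
    d1 = evaluate(vessel, u, 1)
    return np.linalg.norm(np.atleast_2d(d1), axis=1)


def _gauss_integral(vessel: FittedVessel, fn, u0: float, u1: float) -> float:
    """∫ fn(u) du over [u0, u1] by per-span 16-node Gauss–Legendre."""
    breaks = _span_breaks(vessel, u0, u1)
    a = breaks[:-1]
    b = breaks[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    # nodes: (n_spans, 16)
    nodes = mid[:, None] + half[:, None] * GAUSS_NODES[None, :]
    vals = fn(nodes.ravel()).reshape(nodes.shape)
    return float(np.sum(half * (vals @ GAUSS_WEIGHTS)))


def arc_length(vessel: FittedVessel, u0: float = 0.0, u1: float = 1.0) -> float:
    """Arc length ∫_{u0}^{u1} ||p'(u)|| du in mm."""
    if not (0.0 <= u0 <= u1 <= 1.0):
        raise ValueError("require 0 <= u0 <= u1 <= 1")
    if u0 == u1:
        return 0.0
    return _gauss_integral(vessel, lambda uu: _speed(vessel, uu), u0, u1)


def resample_uniform(vessel: FittedVessel,
                     n: int = 20) -> Tuple[np.ndarray, np.ndarray, float]:
    """Parameters of n samples at equal arc-length spacing.

    Returns (params, arc_positions, total_length); arc_positions are
    (j-1) * L / (n-1) for j = 1..n, endpoints included. Each parameter is
    found by monotone root finding on s(u) to ~1e-10 relative.
    """
    if n < 2:
        raise InvalidSampleCountError("invalid sample count: n must be >= 2")
    breaks = _span_breaks(vessel, 0.0, 1.0)
    span_lengths = np.array([
        _gauss_integral(vessel, lambda uu: _speed(vessel, uu), a, b)
        for a, b in zip(breaks[:-1], breaks[1:])
    ])
    cum = np.concatenate([[0.0], np.cumsum(span_lengths)])
    total = float(cum[-1])
    targets = np.linspace(0.0, total, n)
    params = np.empty(n)
    params[0], params[-1] = 0.0, 1.0
    for j in range(1, n - 1):
        s = targets[j]
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(span_lengths) - 1)
        a, b = breaks[i], breaks[i + 1]

        def f(uu: float) -> float:
            return cum[i] + arc_length(vessel, a, uu) - s

        params[j] = brentq(f, a, b, xtol=1e-13, rtol=1e-15)
    return params, targets, total


def curvature(vessel: FittedVessel, u, eps: float = EPS_SPEED):
    """Curvature κ(u) = ||p' × p''|| / ||p'||^3 in 1/mm (nonnegative).

    Raises :class:`SingularParameterizationError` if ||p'(u)|| <= eps at any
    requested parameter.
    """
    scalar = np.isscalar(u) or np.asarray(u).ndim == 0
    uu = np.atleast_1d(np.asarray(u, dtype=float))
    d1 = np.atleast_2d(evaluate(vessel, uu, 1))
    d2 = np.atleast_2d(evaluate(vessel, uu, 2))
    speed = np.linalg.norm(d1, axis=1)
    if np.any(speed <= eps):
        bad = uu[speed <= eps]
        raise SingularParameterizationError(
            f"singular parameterization at u={bad.tolist()}")
    num = np.linalg.norm(np.cross(d1, d2), axis=1)
    out = num / speed ** 3
    return float(out[0]) if scalar else out


def torsion(vessel: FittedVessel, u, eps: float = EPS_TORSION):
    """Torsion τ(u) = det(p', p'', p''') / ||p' × p''||^2 in 1/mm (signed).

    Where ||p' × p''|| <= eps the sample is locally straight (or the
    osculating plane is degenerate) and NaN is returned for it; callers
    treat NaN as the undefined-marker and exclude it from statistics.
    """
    scalar = np.isscalar(u) or np.asarray(u).ndim == 0
    uu = np.atleast_1d(np.asarray(u, dtype=float))
    d1 = np.atleast_2d(evaluate(vessel, uu, 1))
    d2 = np.atleast_2d(evaluate(vessel, uu, 2))
    d3 = np.atleast_2d(evaluate(vessel, uu, 3))
    cross = np.cross(d1, d2)
    V = np.linalg.norm(cross, axis=1)
    W = np.einsum("ij,ij->i", cross, d3)
    out = np.full(len(uu), np.nan)
    ok = V > eps
    out[ok] = W[ok] / V[ok] ** 2
    n_bad = int(np.sum(~ok))
    if n_bad:
        logger.info("torsion undefined at %d of %d samples "
                    "(locally straight)", n_bad, len(uu))
    return float(out[0]) if scalar else out


def included_angle(A, B, C, literal: bool = False) -> float:
    """Included angle θ at B given the branch endpoints A and C, in radians.

    Default is the interior angle between vectors B→A and B→C: π for
    collinear A–B–C (a straight vessel), shrinking as the vessel folds back.
    ``literal=True`` instead uses the angle between the directed vectors
    A→B and B→C (the raw scalar-product form), which is the supplement:
    0 for collinear points.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if literal:
        v1, v2 = B - A, C - B
    else:
        v1, v2 = A - B, C - B
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateAngleError("degenerate angle: zero-length vector")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(c))


def branch_angles(vessel: FittedVessel, params: np.ndarray,
                  literal: bool = False) -> np.ndarray:
    """Included angle at each interior sample of a profile.

    For samples at parameters u_1..u_n, A = p(u_1), C = p(u_n) and
    θ_j = included_angle(A, p(u_j), C) for j = 2..n-1. Endpoints carry NaN
    (the angle is undefined there).
    """
    params = np.asarray(params, dtype=float)
    if len(params) < 3:
        raise InvalidSampleCountError("too few samples for angles (need >=3)")
    pts = evaluate(vessel, params)
    out = np.full(len(params), np.nan)
    A, C = pts[0], pts[-1]
    for j in range(1, len(params) - 1):
        out[j] = included_angle(A, pts[j], C, literal=literal)
    return out


def curvature_integral(vessel: FittedVessel) -> float:
    """Arc-length integral ∫ κ ds over the whole branch (total turning)."""
    def fn(uu: np.ndarray) -> np.ndarray:
        return curvature(vessel, uu) * _speed(vessel, uu)

    return _gauss_integral(vessel, fn, 0.0, 1.0)


def torsion_integral(vessel: FittedVessel) -> float:
    """Arc-length integral ∫ τ ds (signed). Quadrature nodes where τ is
    undefined contribute zero (they form a measure-zero singular set)."""
    def fn(uu: np.ndarray) -> np.ndarray:
        tau = torsion(vessel, uu)
        tau = np.nan_to_num(tau, nan=0.0)
        return tau * _speed(vessel, uu)

    return _gauss_integral(vessel, fn, 0.0, 1.0)


def geometry_profile(vessel: FittedVessel, n: int = 20,
                     include_radius: bool = True,
                     branch_label: Optional[str] = None) -> GeometryProfile:
    """Full per-branch profile: n uniform-arc-length samples with s, κ, τ,
    θ, and — when a radius spline is fitted and ``include_radius`` — the
    envelope radius R."""
    params, arc_positions, total = resample_uniform(vessel, n)
    kappa = curvature(vessel, params)
    tau = torsion(vessel, params)
    angle = branch_angles(vessel, params) if n >= 3 else None
    profile = GeometryProfile(
        params=params, arc_positions=arc_positions, curvature=kappa,
        torsion=tau, total_length=total, angle=angle,
        branch_label=branch_label)
    if include_radius and vessel.ctrl_radii is not None:
        from .radius import radius_profile
        radius_profile(vessel, profile)
    return profile
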