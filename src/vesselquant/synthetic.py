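"""Analytic tubular phantoms with closed-form ground truth.

Every input the pipeline consumes can be emulated here: noisy samples of
parametric centerlines with known radii (skeleton point sets), voxelized
tubes (binary volumes), swept tube meshes, and multi-branch trees (a Y
bifurcation and a 10-branch one-cycle ring emulating the Circle of Willis
topology). Each phantom kind has closed-form length, curvature, torsion and
radius, so fitted descriptors can be checked against exact values.

Default dimensions are chosen at the scale of the cerebral arteries the
pipeline targets: branch lengths of 2–25 mm, radii of 1.5–3 mm, skeleton
noise at or below the half-voxel scale (~0.25 mm) of 0.5 mm MRA voxels.

Noise is isotropic Gaussian in mm (not voxel units), so phantom tests are
resolution-independent; the same seed reproduces bit-identical point sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidPhantomError
from .model import validate_point_set

KINDS = ("line", "circle_arc", "helix", "planar_sine", "cone_tube",
         "y_tree", "ring_tree")

_DEFAULTS = {
    "line": dict(start=(0.0, 0.0, 0.0), end=(20.0, 0.0, 0.0), r0=1.5),
    "circle_arc": dict(a=2.0, span=np.pi, r0=1.5),
    "helix": dict(a=1.0, b=0.5, span=4 * np.pi, r0=1.5),
    "planar_sine": dict(amplitude=2.0, omega=0.5, span=20.0, r0=1.5),
    "cone_tube": dict(length=20.0, r0=0.5, slope=0.25),
    "y_tree": dict(stem_length=20.0, arm_length=15.0,
                   arm_angle=np.pi / 4, bow=1.5, r0=1.5),
    "ring_tree": dict(ring_radius=10.0, n_junctions=5, spoke_length=8.0,
                      r0=1.5),
}

#: voxelize() refuses to allocate more than this many voxels
MAX_VOXELS = 40_000_000


@dataclass
class Phantom:
    """A parametric tubular phantom.

    ``params`` overrides the kind-specific defaults (helix radius ``a``,
    pitch ``b``, span; tube radius coefficients; tree dimensions).
    ``noise_sigma`` is the isotropic Gaussian displacement scale in mm
    applied to skeleton points; ``noise_sigma_r`` perturbs the radii.
    """

    kind: str
    params: dict = field(default_factory=dict)
    n_points: int = 100
    noise_sigma: float = 0.0
    noise_sigma_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidPhantomError(f"unknown phantom kind {self.kind!r}")
        merged = dict(_DEFAULTS[self.kind])
        merged.update(self.params)
        self.params = merged
        if self.n_points < 2:
            raise InvalidPhantomError("invalid phantom: n_points < 2")
        for key in ("a", "span", "length", "stem_length",
                    "arm_length", "ring_radius", "spoke_length"):
            if key in self.params and self.params[key] <= 0:
                raise InvalidPhantomError(
                    f"invalid phantom: {key}={self.params[key]} must be > 0")
        if self.params.get("r0", 1.0) < 0:
            raise InvalidPhantomError("invalid phantom: r0 must be >= 0")


def _centerline(phantom: Phantom):
    """(f(t) -> (len(t), 3), t0, t1, r(t)) for single-branch kinds."""
    p = phantom.params
    kind = phantom.kind
    if kind == "line":
        A = np.asarray(p["start"], dtype=float)
        B = np.asarray(p["end"], dtype=float)
        if np.allclose(A, B):
            raise InvalidPhantomError("invalid phantom: zero-length line")

        def f(t):
            t = np.atleast_1d(t)
            return A[None, :] + t[:, None] * (B - A)[None, :]

        return f, 0.0, 1.0, lambda t: np.full(np.atleast_1d(t).shape,
                                              p["r0"])
    if kind == "circle_arc":
        a = p["a"]

        def f(t):
            t = np.atleast_1d(t)
            return np.stack([a * np.cos(t), a * np.sin(t),
                             np.zeros_like(t)], axis=1)

        return f, 0.0, float(p["span"]), \
            lambda t: np.full(np.atleast_1d(t).shape, p["r0"])
    if kind == "helix":
        a, b = p["a"], p["b"]

        def f(t):
            t = np.atleast_1d(t)
            return np.stack([a * np.cos(t), a * np.sin(t), b * t], axis=1)

        return f, 0.0, float(p["span"]), \
            lambda t: np.full(np.atleast_1d(t).shape, p["r0"])
    if kind == "planar_sine":
        A, w = p["amplitude"], p["omega"]

        def f(t):
            t = np.atleast_1d(t)
            return np.stack([t, A * np.sin(w * t), np.zeros_like(t)], axis=1)

        return f, 0.0, float(p["span"]), \
            lambda t: np.full(np.atleast_1d(t).shape, p["r0"])
    if kind == "cone_tube":
        L = p["length"]

        def f(t):
            t = np.atleast_1d(t)
            return np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1)

        # unit-speed centerline: s == t, so r(s) = r0 + slope * s
        return f, 0.0, float(L), \
            lambda t: p["r0"] + p["slope"] * np.atleast_1d(t)
    raise InvalidPhantomError(f"{kind} is a tree kind; use generate()")


def _bowed_segment(p0, p1, bow, normal, n_points):
    """Planar arc-like segment from p0 to p1: straight chord plus a sine bump
    of height ``bow`` along ``normal`` (planar, hence zero torsion)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    normal = np.asarray(normal, dtype=float)
    t = np.linspace(0.0, 1.0, n_points)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    bump = np.sin(np.pi * t)
    bump[0] = bump[-1] = 0.0  # junctions must match bitwise across branches
    pts += bow * bump[:, None] * normal[None, :]
    return pts


def _tree_branches(phantom: Phantom):
    """Noise-free branch polylines for tree kinds, each sharing junction
    coordinates exactly with its neighbours."""
    p = phantom.params
    n = phantom.n_points
    if phantom.kind == "y_tree":
        junction = np.zeros(3)
        stem_start = np.array([0.0, 0.0, -p["stem_length"]])
        ang, La, bow = p["arm_angle"], p["arm_length"], p["bow"]
        arm1_end = La * np.array([np.sin(ang), 0.0, np.cos(ang)])
        arm2_end = La * np.array([-np.sin(ang), 0.0, np.cos(ang)])
        return [
            _bowed_segment(stem_start, junction, bow, (0.0, 1.0, 0.0), n),
            _bowed_segment(junction, arm1_end, bow, (0.0, 1.0, 0.0), n),
            _bowed_segment(junction, arm2_end, bow, (0.0, -1.0, 0.0), n),
        ]
    if phantom.kind == "ring_tree":
        R = p["ring_radius"]
        m = int(p["n_junctions"])
        if m < 3:
            raise InvalidPhantomError("invalid phantom: need >= 3 junctions")
        angles = 2 * np.pi * np.arange(m + 1) / m
        branches = []
        for k in range(m):  # ring arcs between consecutive junctions
            t = np.linspace(angles[k], angles[k + 1], n)
            branches.append(np.stack([R * np.cos(t), R * np.sin(t),
                                      np.zeros_like(t)], axis=1))
        for k in range(m):  # outward radial spokes, bowed out of plane
            a = angles[k]
            j = R * np.array([np.cos(a), np.sin(a), 0.0])
            tip = (R + p["spoke_length"]) * np.array(
                [np.cos(a), np.sin(a), 0.0])
            branches.append(
                _bowed_segment(j, tip, 0.1 * p["spoke_length"],
                               (0.0, 0.0, 1.0), n))
        return branches
    raise InvalidPhantomError(f"{phantom.kind} is not a tree kind")


def generate(phantom: Phantom):
    """Sample the phantom into skeleton point set(s).

    Single-branch kinds return one :class:`SkeletonPointSet` with radii;
    tree kinds (``y_tree``, ``ring_tree``) return a list of per-branch sets
    sharing junction coordinates exactly (junctions are never perturbed by
    noise, so branches still meet after perturbation). Points are sampled
    uniformly in the curve parameter; noise is isotropic Gaussian of scale
    ``noise_sigma`` (mm), driven by ``seed``.
    """
    rng = np.random.default_rng(phantom.seed)
    if phantom.kind in ("y_tree", "ring_tree"):
        out = []
        for k, pts in enumerate(_tree_branches(phantom)):
            noisy = pts.copy()
            if phantom.noise_sigma > 0:
                bump = rng.normal(0.0, phantom.noise_sigma, size=pts.shape)
                bump[0] = 0.0
                bump[-1] = 0.0
                noisy = pts + bump
            radii = np.full(len(pts), phantom.params["r0"])
            if phantom.noise_sigma_r > 0:
                radii = np.abs(radii + rng.normal(
                    0.0, phantom.noise_sigma_r, size=len(pts)))
            out.append(validate_point_set(noisy, radii,
                                          branch_label=f"branch_{k}"))
        return out
    f, t0, t1, rfn = _centerline(phantom)
    t = np.linspace(t0, t1, phantom.n_points)
    pts = f(t)
    if phantom.noise_sigma > 0:
        pts = pts + rng.normal(0.0, phantom.noise_sigma, size=pts.shape)
    radii = np.asarray(rfn(t), dtype=float)
    if phantom.noise_sigma_r > 0:
        radii = np.abs(radii + rng.normal(0.0, phantom.noise_sigma_r,
                                          size=len(radii)))
    return validate_point_set(pts, radii, branch_label=phantom.kind)


def truth(phantom: Phantom) -> SimpleNamespace:
    """Closed-form ground truth for a single-branch phantom.

    Returns a namespace with ``length`` (mm), ``kappa``, ``tau`` (1/mm;
    scalars for constant-curvature kinds, callables of the curve parameter
    for ``planar_sine``), ``radius`` (mm; callable of arc length for
    ``cone_tube``), and for ``cone_tube`` also ``envelope_radius`` — the
    tangency-circle radius R(s) = r(s) sqrt(1 - slope^2).
    """
    p = phantom.params
    kind = phantom.kind
    if kind == "line":
        L = float(np.linalg.norm(np.asarray(p["end"]) - np.asarray(p["start"])))
        return SimpleNamespace(length=L, kappa=0.0, tau=0.0, radius=p["r0"])
    if kind == "circle_arc":
        return SimpleNamespace(length=p["a"] * p["span"],
                               kappa=1.0 / p["a"], tau=0.0, radius=p["r0"])
    if kind == "helix":
        a, b = p["a"], p["b"]
        denom = a * a + b * b
        return SimpleNamespace(length=p["span"] * np.sqrt(denom),
                               kappa=a / denom, tau=b / denom,
                               radius=p["r0"])
    if kind == "planar_sine":
        A, w = p["amplitude"], p["omega"]

        def kappa(t):
            t = np.asarray(t, dtype=float)
            num = np.abs(A * w * w * np.sin(w * t))
            den = (1.0 + (A * w * np.cos(w * t)) ** 2) ** 1.5
            return num / den

        from scipy.integrate import quad
        L = quad(lambda t: np.sqrt(1.0 + (A * w * np.cos(w * t)) ** 2),
                 0.0, p["span"], limit=200)[0]
        return SimpleNamespace(length=float(L), kappa=kappa, tau=0.0,
                               radius=p["r0"])
    if kind == "cone_tube":
        r0, slope, L = p["r0"], p["slope"], p["length"]

        def radius(s):
            return r0 + slope * np.asarray(s, dtype=float)

        def envelope(s):
            return radius(s) * np.sqrt(max(1.0 - slope * slope, 0.0))

        return SimpleNamespace(length=float(L), kappa=0.0, tau=0.0,
                               radius=radius, envelope_radius=envelope,
                               slope=slope)
    raise InvalidPhantomError(f"no closed-form truth for tree kind {kind!r}")


def as_graph(branches):
    """Merge per-branch point sets into one point cloud with explicit edge
    adjacency, de-duplicating shared junction coordinates exactly. Returns
    (points, edges, radii) suitable for
    ``topology.build_graph(mode='edges')``; radii is None unless every
    branch carries radii."""
    points = []
    radii = []
    index = {}
    edges = []
    with_radii = all(ps.radii is not None for ps in branches)
    for ps in branches:
        prev = None
        for j, q in enumerate(ps.points):
            key = tuple(np.round(q, 9))
            if key not in index:
                index[key] = len(points)
                points.append(q)
                if with_radii:
                    radii.append(ps.radii[j])
            cur = index[key]
            if prev is not None and prev != cur:
                edges.append((prev, cur))
            prev = cur
    return (np.asarray(points), edges,
            np.asarray(radii) if with_radii else None)


def _dense_centerline(phantom: Phantom, step: float):
    """Centerline samples at ~``step`` arc spacing with per-sample radii,
    concatenated over branches for tree kinds."""
    if phantom.kind in ("y_tree", "ring_tree"):
        chunks = []
        radii = []
        for pts in _tree_branches(phantom):
            chord = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
            n = max(int(np.ceil(chord / step)) + 1, 2)
            t = np.linspace(0.0, 1.0, n)
            s = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                 axis=1))])
            dense = np.empty((n, 3))
            for ax in range(3):
                dense[:, ax] = np.interp(t * s[-1], s, pts[:, ax])
            chunks.append(dense)
            radii.append(np.full(n, phantom.params["r0"]))
        return np.vstack(chunks), np.concatenate(radii)
    f, t0, t1, rfn = _centerline(phantom)
    coarse = f(np.linspace(t0, t1, 512))
    arc = np.linalg.norm(np.diff(coarse, axis=0), axis=1).sum()
    n = max(int(np.ceil(arc / step)) + 1, 2)
    t = np.linspace(t0, t1, n)
    return f(t), np.asarray(rfn(t), dtype=float)


def voxelize(phantom: Phantom, spacing, margin: float = 2.0):
    """Voxelize the phantom tube into a binary volume.

    A voxel is foreground iff its center lies within r(s*) of the closest
    centerline point s* (centerline sampled densely at spacing/4). Returns
    ``(volume, origin, spacing)`` with ``volume`` a boolean array indexed
    [x, y, z] and ``origin`` the physical coordinate of voxel (0,0,0).
    """
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise InvalidPhantomError("invalid phantom: spacing must be positive")
    center, radii = _dense_centerline(phantom, float(spacing.min()) / 4.0)
    if radii.min() < spacing.max():
        warnings.warn("tube under-resolved: min radius "
                      f"{radii.min():.3g} mm < voxel size "
                      f"{spacing.max():.3g} mm", stacklevel=2)
    pad = radii.max() + margin
    lo = center.min(axis=0) - pad
    hi = center.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if np.prod(shape) > MAX_VOXELS:
        raise InvalidPhantomError(
            f"phantom too large: {np.prod(shape)} voxels > {MAX_VOXELS}")
    axes = [lo[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tree = cKDTree(center)
    dist, idx = tree.query(centers, workers=-1)
    fg = dist <= radii[idx]
    # flat tube ends: drop voxels past the end planes of open centerlines
    if np.linalg.norm(center[0] - center[-1]) > 1e-9:
        for end, inward, r_end in (
                (center[0], center[1] - center[0], radii[0]),
                (center[-1], center[-2] - center[-1], radii[-1])):
            inward = inward / np.linalg.norm(inward)
            rel = centers - end
            near_end = np.linalg.norm(rel, axis=1) <= r_end * 1.5
            fg[fg & near_end & (rel @ inward < 0.0)] = False
    vol = fg.reshape(shape)
    return vol, lo, spacing


def _parallel_transport_frames(points: np.ndarray):
    """Unit tangents plus a parallel-transported normal/binormal pair along
    a polyline (no Frenet frame flips at inflections)."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n0 = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(n0, tangents[0])) > 0.9:
        n0 = np.array([0.0, 1.0, 0.0])
    n0 = n0 - np.dot(n0, tangents[0]) * tangents[0]
    n0 /= np.linalg.norm(n0)
    normals = [n0]
    for i in range(1, len(points)):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        v = np.cross(t_prev, t_cur)
        s = np.linalg.norm(v)
        c = np.dot(t_prev, t_cur)
        n = normals[-1]
        if s > 1e-12:
            v = v / s
            # Rodrigues rotation of n about v by the angle between tangents
            n = (n * c + np.cross(v, n) * s
                 + v * np.dot(v, n) * (1.0 - c))
        n = n - np.dot(n, t_cur) * t_cur
        n /= np.linalg.norm(n)
        normals.append(n)
    normals = np.asarray(normals)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def tube_mesh(phantom: Phantom, n_circ: int = 32, n_axial: int = 200,
              capped: bool = False):
    """Swept-frame triangulated tube surface of a single-branch phantom.

    Uses parallel-transport frames along the centerline. Closed sweeps
    (e.g. a full-circle centerline) are stitched watertight; open tubes are
    laterally open unless ``capped``. Returns a ``trimesh.Trimesh``.
    """
    import trimesh

    if n_circ < 3:
        raise InvalidPhantomError("invalid mesh resolution: n_circ < 3")
    if n_axial < 2:
        raise InvalidPhantomError("invalid mesh resolution: n_axial < 2")
    f, t0, t1, rfn = _centerline(phantom)
    t = np.linspace(t0, t1, n_axial)
    center = f(t)
    radii = np.asarray(rfn(t), dtype=float)
    closed = np.linalg.norm(center[0] - center[-1]) < 1e-9
    if closed:
        center = center[:-1]
        radii = radii[:-1]
        n_axial -= 1
    tangents, normals, binormals = _parallel_transport_frames(center)
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    ring = np.cos(phi)[:, None, None] * normals[None, :, :] \
        + np.sin(phi)[:, None, None] * binormals[None, :, :]
    verts = center[None, :, :] + radii[None, :, None] * ring
    verts = verts.transpose(1, 0, 2).reshape(-1, 3)  # (axial*circ, 3)

    def vid(i, j):
        return (i % n_axial) * n_circ + (j % n_circ)

    faces = []
    last = n_axial if closed else n_axial - 1
    for i in range(last):
        for j in range(n_circ):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    if capped and not closed:
        base = len(verts)
        verts = np.vstack([verts, center[[0]], center[[-1]]])
        for j in range(n_circ):
            faces.append([base, vid(0, j + 1), vid(0, j)])
            faces.append([base + 1, vid(n_axial - 1, j),
                          vid(n_axial - 1, j + 1)])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=False)
    return mesh
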