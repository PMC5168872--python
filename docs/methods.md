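# Methods

This note documents the models, numerical choices and open design
decisions behind vesselquant, and what the phantom-based validation does
and does not establish.

## Centerline fitting

**Model.** Each branch skeleton (an ordered point set q_0..q_m, physical
mm) is fitted by a clamped cubic B-spline p(u) = Σ N_{i,3}(u) p_i on
u ∈ [0,1]. Data parameters u_j are assigned by cumulative chord length
(`parameterization="chord"`, default) or centripetal (square-rooted
chords, damping overshoot at sharp turns). The knot vector is clamped with
interior knots placed by averaging windows of the data parameters, which
guarantees every knot span is supported by data and keeps the
least-squares system well conditioned. Control points minimize
Σ ‖p(u_j) − q_j‖²; the first and last control points are pinned to the
first and last data points so adjacent branches, which duplicate their
shared junction point, meet exactly.

**Control-point count.** Default `n_ctrl = min(max(4, ceil(m/3)), m)`: one
control point per ~3 skeleton points tracks branch shape while averaging
voxel-scale jitter. This is a bias–variance dial, not a constant of
nature: for noiseless dense samples more control points reduce
approximation bias (the dense-circle fits below use interpolation-level
counts), while for noisy skeletons *fewer* are needed — curvature is a
second derivative and amplifies point noise by 1/h² at knot spacing h. For
the 0.1 mm-noise experiments we use `n_ctrl=15` for 200 points (spans of
~1 mm arc), which keeps the curvature bias of a 0.8/mm helix and the
noise-induced variance both at the few-percent level.

**Refinement.** The optional refinement loop (`refine_tol`, default
0.05 mm; `refine_max_iter`, default 10) corrects each data point's
parameter to its footpoint on the current curve (damped Newton on
g(u) = (p−q)·p′) and refits. We deliberately did *not* implement
refinement as residual feedback (adding residual vectors to the data and
refitting): for an exact least-squares solver that operation is the
identity — the residual is orthogonal to the spline space, so the refit
returns the same curve; we verified this numerically (residuals unchanged
to 1e-13). Footpoint correction is the standard fitting refinement that
does reduce geometric error. It should be disabled (`refine_max_iter=0`)
for noisy data, where it chases the noise.

**Degenerate inputs.** Consecutive duplicate points are collapsed at
validation (keeping the first of each run, order otherwise preserved);
fewer than 2 distinct points is an error; all-collinear branches are valid
(zero curvature). Fewer than degree+1 points cannot be fitted (the caller
may lower the degree).

## Differential geometry

Derivatives are analytic: the r-th derivative of a degree-k spline is a
degree k−r spline whose control points come from the standard differencing
recursion; evaluation then uses de Boor's algorithm. Orders above the
degree are identically zero.

* **Arc length** and the **curvilinear integrals** ∫κ ds, ∫τ ds use fixed
  16-node Gauss–Legendre per knot span. The integrand is piecewise-smooth
  on spans, so the rule is effectively exact (machine-precision additivity
  on regular curves) and fully deterministic. No adaptivity.
* **Uniform-arc resampling** solves s(u_j) = (j−1)L/(n−1) by bracketed
  root finding (Brent, xtol 1e-13) inside the precomputed per-span
  cumulative lengths; n = 20 samples by default.
* **Curvature** requires ‖p′‖ > 1e-9; below that the parameterization is
  singular and an error is raised rather than returning noise.
* **Torsion** is undefined where V = ‖p′ × p″‖ ≤ 1e-8 (locally straight or
  osculating-plane degenerate). Such samples carry NaN, are counted per
  branch, logged, and excluded from statistics. Reporting a value there
  would only amplify floating-point noise — torsion is the most fragile
  descriptor (third derivative over V²), which is also why its variance
  dwarfs the others on real vessels.
* **Included angle** at sample B is the interior angle between B→A and
  B→C (A, C the branch endpoints): π for a straight vessel, shrinking as
  the vessel folds. The raw scalar-product form on the directed vectors
  A→B, B→C is its supplement (0 when collinear) and is available via
  `literal=True`; the interior convention is the one consistent with
  near-π angles on smooth vessels. Angles are radians; endpoints carry no
  angle, so a 20-sample profile has 18 angle values.

## Envelope radius

The vessel wall is the envelope of spheres of radius r(u) centered on
p(u). Eliminating the envelope condition gives the tangency circle:
offset |OP| = −r r′/‖p′‖ along the tangent, radius
R = √(r² − |OP|²) = r √(1 − (dr/ds)²). R is the measured vessel radius;
it equals the sphere radius exactly iff r′ = 0. When |dr/ds| ≥ 1 (radius
growing at least as fast as arc length) no real tangency circle exists;
the sample raises a degenerate-envelope error, and profile assembly
converts that to NaN with a warning and a count. Both R and the raw r(u)
column are available, since reported radii in the literature rarely state
which of the two they are.

Initial per-point radii are the distance from each skeleton point to the
segmentation boundary: an exact Euclidean distance transform with
anisotropic physical sampling for binary volumes (so 0.5×0.5×0.8 mm MRA
grids are handled correctly; accuracy is half-voxel), or exact
nearest-surface distance for triangle meshes. Points outside the lumen get
radius 0 with a warning.

## Topology

Skeleton points become graph nodes; edges come from explicit polyline
connectivity, k-nearest-neighbour linking, or a fixed connection radius
(default 1.5× the median nearest-neighbour spacing — note that this
mis-links branches meeting at angles sharper than ~97°, where cross-branch
neighbours are closer than 1.5× the along-branch spacing; explicit
connectivity is always preferable when available). Junctions are degree ≥3
nodes; branches are maximal junction/terminal-to-junction/terminal paths
with degree-2 interiors; a pure cycle becomes one closed branch split at
its lowest-id node. The junction point is duplicated into every incident
branch so pinned spline ends meet exactly. Orientation is breadth-first
search from a root terminal (default: lowest z, the basilar side in
head-first supine coordinates; overridable), with neighbour ties broken by
node id — the whole pass is deterministic and byte-stable. One independent
cycle is expected for a complete CoW and is reported, not treated as an
error. Parent/child assignment at bifurcations is purely BFS-topological;
no geometric or learned classifier is used.

## Statistics and reports

Per-branch rows hold length, mean and variance of curvature, torsion,
envelope radius and included angle over the profile samples (NaN samples
excluded; a quantity with no defined samples reports NaN), and the
fit-error triple (sum/mean/variance of distances from m=8 uniform raw
skeleton samples to the curve). Variances are population variances
(divide by the count); `ddof=1` switches to sample variance. Rounding to
two decimals happens only in the CSV writer, never internally. The
symmetric-pair comparison reverses the left profile when endpoint
quantities indicate mirrored traversal and reports per-sample |Δ| and mean
absolute differences.

## Synthetic phantoms

The generator provides every input the pipeline consumes, with closed-form
truth: lines, circular arcs, helices (κ = a/(a²+b²), τ = b/(a²+b²),
L = span·√(a²+b²)), planar sine curves, cones (envelope
R(s) = r(s)√(1−slope²)), a Y bifurcation and a 10-branch one-cycle ring.
Dimensions default to the cerebral-artery scale the pipeline targets:
branch lengths 2–25 mm, radii 1.5–3 mm, skeleton noise at or below the
half-voxel (~0.25 mm) scale of 0.5 mm MRA voxels. Noise is isotropic
Gaussian in mm, seeded and bit-reproducible; tree junctions are never
perturbed, so branches still share coordinates. The Y phantom's default
branches are gently bowed planar arcs rather than straight segments, so
curvature is nonzero and torsion (0 for planar curves) is defined at every
sample and every statistics column populates; `bow=0` recovers the exact
straight Y. Voxelization marks a voxel foreground iff its center lies
within r(s*) of the nearest densely-sampled centerline point, with voxels
beyond the end planes clipped (flat-ended tubes, matching the cylinder
volume closed form rather than a capsule). Tube meshes use
parallel-transport frames (no Frenet flips at inflections) and stitch
closed sweeps watertight.

**What the phantoms do not emulate:** imaging intensity, segmentation
error, skeletonization bias (systematic centerline drift, spurious spurs),
anatomical variation of the CoW, or non-circular lumina. Passing the
phantom suite therefore demonstrates the correctness of the geometry
pipeline given reasonable skeleton input, not robustness of upstream
segmentation/skeletonization — those stages are outside this package.

## Problem sizes and determinism

Validation uses 40–1000-point skeletons, 20-sample profiles, 20-replicate
noise Monte-Carlos, ~10⁵-voxel volumes and ~10⁴-face meshes; each check
runs in seconds on one CPU. All randomness flows through explicit seeds;
identical config and inputs give byte-identical outputs.

## Known limitations

* Torsion near straight segments is reported as undefined rather than
  estimated; branches that are straight to machine precision have no
  torsion statistics.
* The fit-error metric measures skeleton-to-curve consistency, not
  ground-truth accuracy; on noisy skeletons it is dominated by the noise,
  not by fit bias.
* Radius estimation from volumes is half-voxel limited; no sub-voxel
  boundary model is attempted.
* The radius-mode graph builder assumes roughly uniform skeleton sampling
  and branch angles wider than ~97°; supply explicit connectivity
  otherwise.
* Absolute reproduction of published per-subject CoW tables requires the
  original segmentation and skeleton stages, which are out of scope here;
  validation is property-based on phantoms instead.
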