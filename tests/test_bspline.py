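"""B-spline fitting, analytic derivative evaluation and the fit-error
metric, checked against brute-force and finite-difference oracles."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

from conftest import fd_derivative, make_random_vessel, random_rotation
from vesselquant import (
    FitConfig,
    Phantom,
    closest_point_distance,
    evaluate,
    evaluate_radius,
    fit_curve,
    fit_radius,
    fitting_error,
    generate,
    parameterize,
    validate_point_set,
)
from vesselquant.errors import (
    InsufficientPointsError,
    InvalidSampleCountError,
    ParameterRangeError,
)


class TestParameterize:
    @pytest.mark.parametrize("points,expected", [
        ([(0, 0, 0), (1, 0, 0), (2, 0, 0)], [0.0, 0.5, 1.0]),
        ([(0, 0, 0), (3, 0, 0), (4, 0, 0)], [0.0, 0.75, 1.0]),
        ([(0, 0, 0), (5, 5, 5)], [0.0, 1.0]),
    ])
    def test_chord_length_examples(self, points, expected):
        u = parameterize(validate_point_set(points), "chord")
        np.testing.assert_allclose(u, expected, atol=1e-15)

    def test_strictly_increasing_and_normalized(self, rng):
        ps = validate_point_set(np.cumsum(rng.random((40, 3)) + 0.01, axis=0))
        for method in ("chord", "centripetal"):
            u = parameterize(ps, method)
            assert u[0] == 0.0 and u[-1] == 1.0
            assert np.all(np.diff(u) > 0)


class TestFitCurve:
    def test_straight_segment_reproduced_exactly(self):
        ps = generate(Phantom("line", n_points=50))
        vessel = fit_curve(ps)
        resid = np.linalg.norm(
            evaluate(vessel, parameterize(ps)) - ps.points, axis=1)
        assert resid.max() < 1e-9

    def test_representable_cubic_reproduced_exactly(self, rng):
        # data drawn from a single cubic Bezier arc at known parameters
        bezier = make_random_vessel(rng, n_ctrl=4)
        u = np.linspace(0.0, 1.0, 8)
        ps = validate_point_set(evaluate(bezier, u))
        vessel = fit_curve(ps, FitConfig(n_ctrl=4), parameters=u)
        resid = np.linalg.norm(evaluate(vessel, u) - ps.points, axis=1)
        assert resid.max() < 1e-9

    def test_noiseless_helix_close_to_generating_curve(self):
        ph = Phantom("helix", n_points=200)
        ps = generate(ph)
        vessel = fit_curve(ps, FitConfig(n_ctrl=30))
        # residual against the generating helix by dense closest-point search
        t = np.linspace(0, 4 * np.pi, 20000)
        helix = np.stack([np.cos(t), np.sin(t), 0.5 * t], axis=1)
        fitted = evaluate(vessel, np.linspace(0, 1, 500))
        d = np.array([np.linalg.norm(helix - q, axis=1).min()
                      for q in fitted])
        assert d.max() < 1e-3

    def test_endpoint_interpolation(self, rng):
        ps = validate_point_set(np.cumsum(rng.random((30, 3)), axis=0))
        vessel = fit_curve(ps)
        assert np.linalg.norm(evaluate(vessel, 0.0) - ps.points[0]) < 1e-9
        assert np.linalg.norm(evaluate(vessel, 1.0) - ps.points[-1]) < 1e-9

    def test_too_few_points(self):
        ps = validate_point_set([(0, 0, 0), (1, 0, 0), (2, 1, 0)])
        with pytest.raises(InsufficientPointsError, match="insufficient"):
            fit_curve(ps)

    def test_rigid_motion_equivariance(self, rng):
        ps = generate(Phantom("helix", n_points=60, noise_sigma=0.05,
                              seed=11))
        R = random_rotation(rng)
        shift = rng.normal(size=3) * 5
        moved = validate_point_set(ps.points @ R.T + shift)
        v1 = fit_curve(ps)
        v2 = fit_curve(moved)
        u = np.linspace(0, 1, 100)
        r1 = np.linalg.norm(evaluate(v1, u) - ps.points[0], axis=1)
        np.testing.assert_allclose(
            evaluate(v2, u), evaluate(v1, u) @ R.T + shift, atol=1e-9)
        del r1


class TestEvaluate:
    def test_constant_curve_zero_derivative(self):
        from vesselquant.model import FittedVessel
        t = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        v = FittedVessel(degree=3, knots=t,
                         ctrl_points=np.tile([2.0, -1.0, 3.0], (4, 1)))
        for u in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(evaluate(v, u, 1), 0.0, atol=1e-14)

    def test_linear_control_polygon_derivative_parallel(self, rng):
        from vesselquant.model import FittedVessel
        t = np.array([0, 0, 0, 0, 0.4, 0.6, 1, 1, 1, 1], dtype=float)
        direction = np.array([1.0, 2.0, -1.0])
        ctrl = np.outer(np.sort(rng.random(6)), direction)
        v = FittedVessel(degree=3, knots=t, ctrl_points=ctrl)
        for u in np.linspace(0.05, 0.95, 7):
            d1 = evaluate(v, u, 1)
            cosang = d1 @ direction / (
                np.linalg.norm(d1) * np.linalg.norm(direction))
            assert abs(cosang) > 1 - 1e-12

    def test_derivatives_match_finite_differences(self, rng):
        v = make_random_vessel(rng, n_ctrl=10)
        u = 0.37
        f = lambda uu: evaluate(v, uu)  # noqa: E731
        for order in (1, 2, 3):
            analytic = evaluate(v, u, order)
            fd = fd_derivative(f, u, order, h=1e-4 if order < 3 else 1e-3)
            np.testing.assert_allclose(analytic, fd,
                                       rtol=1e-6, atol=1e-6)

    def test_derivatives_match_scipy_bspline(self, rng):
        # independent route: scipy's own derivative machinery
        v = make_random_vessel(rng, n_ctrl=12)
        spl = BSpline(v.knots, v.ctrl_points, v.degree)
        u = np.linspace(0, 1, 50)
        for order in (1, 2, 3):
            np.testing.assert_allclose(evaluate(v, u, order),
                                       spl.derivative(order)(u), atol=1e-9)

    def test_order_above_degree_is_zero(self, rng):
        v = make_random_vessel(rng)
        np.testing.assert_array_equal(evaluate(v, 0.5, 4), np.zeros(3))

    def test_out_of_range_parameter(self, rng):
        v = make_random_vessel(rng)
        with pytest.raises(ParameterRangeError):
            evaluate(v, 1.2)


class TestFitRadius:
    def test_constant_radii_reproduced(self, line_vessel):
        u = np.linspace(0, 1, 40)
        np.testing.assert_allclose(evaluate_radius(line_vessel, u), 1.5,
                                   atol=1e-9)
        np.testing.assert_allclose(evaluate_radius(line_vessel, u, 1), 0.0,
                                   atol=1e-8)

    def test_linear_radii_slope_recovered(self):
        # cone: dr/ds constant; r'(u)/||p'(u)|| must equal the slope
        ph = Phantom("cone_tube", params={"length": 20, "r0": 0.5,
                                          "slope": 0.25}, n_points=50)
        ps = generate(ph)
        vessel = fit_radius(ps, fit_curve(ps))
        u = np.linspace(0.05, 0.95, 21)
        speed = np.linalg.norm(evaluate(vessel, u, 1), axis=1)
        slope = evaluate_radius(vessel, u, 1) / speed
        np.testing.assert_allclose(slope, 0.25, atol=1e-6)

    def test_nan_radius_rejected_at_validation(self):
        from vesselquant.errors import AlignmentError
        with pytest.raises(AlignmentError):
            validate_point_set([(0, 0, 0), (1, 0, 0), (2, 0, 0),
                                (3, 0, 0), (4, 0, 0)],
                               radii=[1, 1, np.nan, 1, 1])


class TestClosestPoint:
    def test_point_on_curve(self, helix_vessel, rng):
        for u in rng.random(5):
            q = evaluate(helix_vessel, u)
            _, d = closest_point_distance(helix_vessel, q)
            assert d < 1e-8

    def test_perpendicular_foot_on_straight_segment(self):
        ps = validate_point_set(
            np.column_stack([np.linspace(0, 10, 20), np.zeros(20),
                             np.zeros(20)]))
        vessel = fit_curve(ps)
        u, d = closest_point_distance(vessel, (5.0, 2.0, 0.0))
        assert abs(d - 2.0) < 1e-8
        assert abs(u - 0.5) < 1e-6

    def test_against_brute_force_polyline(self, helix_vessel, rng):
        dense = evaluate(helix_vessel, np.linspace(0, 1, 10_000))
        for q in rng.normal(scale=2.0, size=(10, 3)):
            _, d = closest_point_distance(helix_vessel, q)
            brute = np.linalg.norm(dense - q, axis=1).min()
            assert d <= brute + 1e-12
            assert abs(d - brute) < 1e-5


class TestFittingError:
    def test_zero_for_straight_on_curve_points(self, line_vessel):
        # straight data: polyline == curve, so the error is identically zero
        pts = evaluate(line_vessel, np.linspace(0, 1, 25))
        s, m, var = fitting_error(line_vessel, validate_point_set(pts), 8)
        assert s < 1e-8 and m < 1e-9 and var < 1e-18

    def test_bounded_by_chord_sag_for_curved_points(self, rng):
        # curved data: uniform-chord samples sit on polyline chords, whose
        # deviation from the curve is at most kappa * chord^2 / 8
        v = make_random_vessel(rng, n_ctrl=8)
        n = 200
        pts = evaluate(v, np.linspace(0, 1, n))
        chord = np.linalg.norm(np.diff(pts, axis=0), axis=1).max()
        from vesselquant import curvature
        kmax = curvature(v, np.linspace(0, 1, 400)).max()
        s, m, var = fitting_error(v, validate_point_set(pts), 8)
        assert m <= kmax * chord ** 2 / 8 + 1e-12

    def test_single_offset_point_arithmetic(self):
        # straight curve; one raw sample offset by 0.4 mm, the rest on-curve.
        # Long chords keep the polyline-length inflation from the offset
        # negligible, so the m=8 uniform positions hit every second vertex.
        n = 15
        x = np.linspace(0.0, 1400.0, n)
        pts = np.column_stack([x, np.zeros(n), np.zeros(n)])
        straight = fit_curve(validate_point_set(pts), FitConfig(n_ctrl=4))
        raw = pts.copy()
        raw[4, 1] = 0.4  # vertex at 2/7 of the length = sample 2 of 8
        ps = validate_point_set(raw)
        s, m, var = fitting_error(straight, ps, 8)
        assert abs(s - 0.4) < 1e-5
        assert abs(m - 0.05) < 1e-6
        assert abs(var - (0.4 ** 2 / 8 - 0.05 ** 2)) < 1e-6

    def test_noisy_helix_error_below_noise_floor(self):
        ph = Phantom("helix", n_points=200, noise_sigma=0.1, seed=7)
        ps = generate(ph)
        vessel = fit_curve(ps, FitConfig(n_ctrl=15, refine_max_iter=0))
        _, mean, _ = fitting_error(vessel, ps, 8)
        assert mean < 0.1

    def test_invalid_sample_count(self, helix_vessel, rng):
        ps = validate_point_set(rng.random((10, 3)).cumsum(axis=0))
        with pytest.raises(InvalidSampleCountError):
            fitting_error(helix_vessel, ps, 1)


def test_refinement_reduces_geometric_residual():
    """Parameter-correction refinement moves the curve closer to the data
    (max closest-point distance decreases)."""
    ph = Phantom("planar_sine", n_points=60)
    ps = generate(ph)
    coarse = fit_curve(ps, FitConfig(n_ctrl=8, refine_max_iter=0))
    refined = fit_curve(ps, FitConfig(n_ctrl=8, refine_max_iter=10,
                                      refine_tol=1e-12))

    def max_dist(v):
        return max(closest_point_distance(v, q)[1] for q in ps.points)

    assert max_dist(refined) < max_dist(coarse)
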