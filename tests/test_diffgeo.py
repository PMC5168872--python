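"""Arc length, uniform resampling, curvature, torsion, included angles and
the curvilinear integrals, against closed forms and FD Frenet oracles."""

import numpy as np
import pytest

from conftest import fd_derivative, make_random_vessel, random_rotation
from vesselquant import (
    FitConfig,
    FittedVessel,
    Phantom,
    arc_length,
    branch_angles,
    curvature,
    curvature_integral,
    evaluate,
    fit_curve,
    generate,
    included_angle,
    resample_uniform,
    torsion,
    torsion_integral,
    validate_point_set,
)
from vesselquant.errors import (
    DegenerateAngleError,
    InvalidSampleCountError,
    SingularParameterizationError,
)


def fit_phantom(kind, n_points=400, n_ctrl=None, **params):
    ps = generate(Phantom(kind, params=params, n_points=n_points))
    return fit_curve(ps, FitConfig(n_ctrl=n_ctrl))


class TestArcLength:
    def test_straight_segment(self):
        v = fit_phantom("line", n_points=50, start=(0, 0, 0), end=(7, 0, 0))
        assert abs(arc_length(v) - 7.0) < 1e-9

    def test_full_circle(self, circle_vessel):
        assert abs(arc_length(circle_vessel) - 4 * np.pi) < 1e-4

    def test_helix_closed_form(self):
        v = fit_phantom("helix", a=3.0, b=4.0, span=2 * np.pi)
        assert abs(arc_length(v) - 10 * np.pi) < 1e-4

    def test_additivity(self, rng):
        v = make_random_vessel(rng)
        total = arc_length(v)
        for u in rng.random(5):
            assert abs(arc_length(v, 0, u) + arc_length(v, u, 1)
                       - total) < 1e-9


class TestResampleUniform:
    def test_straight_segment_unit_spacing(self, line_vessel):
        params, arc, total = resample_uniform(line_vessel, 20)
        assert abs(total - 19.0) < 1e-9
        np.testing.assert_allclose(np.diff(arc), 1.0, atol=1e-9)

    def test_circle_equal_central_angles(self, circle_vessel):
        params, _, _ = resample_uniform(circle_vessel, 20)
        pts = evaluate(circle_vessel, params)
        angles = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
        np.testing.assert_allclose(np.diff(angles), np.diff(angles)[0],
                                   rtol=1e-4)

    def test_gaps_match_dense_polyline_oracle(self, rng):
        v = make_random_vessel(rng, n_ctrl=8)
        params, arc, total = resample_uniform(v, 20)
        dense = evaluate(v, np.linspace(0, 1, 100_000))
        s = np.concatenate([[0], np.cumsum(
            np.linalg.norm(np.diff(dense, axis=0), axis=1))])
        oracle = np.interp(params, np.linspace(0, 1, 100_000), s)
        np.testing.assert_allclose(arc, oracle, atol=1e-5)

    def test_equal_gaps_property(self, helix_vessel):
        _, arc, _ = resample_uniform(helix_vessel, 20)
        gaps = np.diff(arc)
        assert np.all(np.abs(gaps - gaps[0]) <= 1e-6 * gaps[0])

    def test_too_few_samples(self, helix_vessel):
        with pytest.raises(InvalidSampleCountError):
            resample_uniform(helix_vessel, 1)


class TestCurvatureTorsion:
    def test_straight_line_zero_curvature(self, line_vessel):
        u = np.linspace(0, 1, 21)
        np.testing.assert_allclose(curvature(line_vessel, u), 0.0,
                                   atol=1e-12)

    def test_circle_curvature(self, circle_vessel):
        u = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(curvature(circle_vessel, u), 0.5,
                                   atol=1e-4)

    def test_helix_curvature_and_torsion(self):
        v = fit_phantom("helix", n_points=600, n_ctrl=200)
        u = np.linspace(0.1, 0.9, 17)
        np.testing.assert_allclose(curvature(v, u), 0.8, atol=1e-3)
        np.testing.assert_allclose(torsion(v, u), 0.4, atol=1e-3)

    def test_planar_curve_zero_torsion(self):
        v = fit_phantom("planar_sine", n_points=300)
        u = np.linspace(0.05, 0.95, 30)
        np.testing.assert_allclose(torsion(v, u), 0.0, atol=1e-6)

    def test_mirrored_helix_flips_torsion_sign(self):
        ps = generate(Phantom("helix", n_points=600))
        mirrored = validate_point_set(ps.points * [1.0, 1.0, -1.0])
        v = fit_curve(mirrored, FitConfig(n_ctrl=200))
        u = np.linspace(0.1, 0.9, 17)
        np.testing.assert_allclose(torsion(v, u), -0.4, atol=1e-3)

    def test_torsion_undefined_on_straight_curve(self, line_vessel):
        tau = torsion(line_vessel, np.linspace(0, 1, 9))
        assert np.all(np.isnan(tau))

    def test_singular_parameterization_raises(self):
        t = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        v = FittedVessel(degree=3, knots=t,
                         ctrl_points=np.tile([1.0, 2.0, 3.0], (4, 1)))
        with pytest.raises(SingularParameterizationError):
            curvature(v, 0.5)

    def test_frenet_finite_difference_oracle(self, rng):
        """Formula-based kappa/tau match a Frenet oracle built purely from
        finite differences of curve positions, on 20 random cubic curves."""
        for _ in range(20):
            v = make_random_vessel(rng, n_ctrl=10)
            # mid-span parameters keep the FD stencils inside one polynomial
            spans = np.unique(v.knots)
            u = (spans[:-1] + spans[1:]) / 2.0
            u = u[(u > 0.05) & (u < 0.95)]
            f = lambda uu: evaluate(v, uu)  # noqa: E731
            d1 = np.array([fd_derivative(f, x, 1, 1e-4) for x in u])
            d2 = np.array([fd_derivative(f, x, 2, 1e-4) for x in u])
            d3 = np.array([fd_derivative(f, x, 3, 1e-3) for x in u])
            cross = np.cross(d1, d2)
            k_fd = np.linalg.norm(cross, axis=1) / \
                np.linalg.norm(d1, axis=1) ** 3
            t_fd = np.einsum("ij,ij->i", cross, d3) / \
                np.linalg.norm(cross, axis=1) ** 2
            np.testing.assert_allclose(curvature(v, u), k_fd, atol=1e-4)
            np.testing.assert_allclose(torsion(v, u), t_fd, atol=1e-4)


class TestIncludedAngle:
    @pytest.mark.parametrize("A,B,C,expected", [
        ((0, 0, 0), (1, 0, 0), (2, 0, 0), np.pi),
        ((0, 0, 0), (1, 0, 0), (1, 1, 0), np.pi / 2),
    ])
    def test_examples(self, A, B, C, expected):
        assert abs(included_angle(A, B, C) - expected) < 1e-12

    def test_fold_back_near_zero(self):
        theta = included_angle((0, 0, 0), (1, 0, 0), (0, 0.001, 0))
        assert theta < 0.01

    def test_literal_variant_is_supplement(self):
        interior = included_angle((0, 0, 0), (1, 0, 0), (2, 1, 0))
        literal = included_angle((0, 0, 0), (1, 0, 0), (2, 1, 0),
                                 literal=True)
        assert abs(interior + literal - np.pi) < 1e-12

    def test_degenerate(self):
        with pytest.raises(DegenerateAngleError):
            included_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestBranchAngles:
    def test_straight_vessel_all_pi(self, line_vessel):
        params, _, _ = resample_uniform(line_vessel, 20)
        theta = branch_angles(line_vessel, params)
        assert np.isnan(theta[0]) and np.isnan(theta[-1])
        np.testing.assert_allclose(theta[1:-1], np.pi, atol=1e-9)

    def test_semicircle_midpoint_right_angle(self):
        v = fit_phantom("circle_arc", a=5.0, span=np.pi, n_points=400)
        params, _, _ = resample_uniform(v, 21)
        theta = branch_angles(v, params)
        assert abs(theta[10] - np.pi / 2) < 1e-3

    def test_inscribed_angle_constant_on_arc(self):
        # all interior samples see the same chord: inscribed-angle theorem
        v = fit_phantom("circle_arc", a=10.0, span=0.8, n_points=600,
                        n_ctrl=300)
        params, _, _ = resample_uniform(v, 20)
        theta = branch_angles(v, params)[1:-1]
        np.testing.assert_allclose(theta, theta[0], atol=1e-6)

    def test_too_few_samples(self, line_vessel):
        with pytest.raises(InvalidSampleCountError):
            branch_angles(line_vessel, [0.0, 1.0])


class TestIntegrals:
    def test_straight_line_zero(self, line_vessel):
        assert abs(curvature_integral(line_vessel)) < 1e-9
        assert abs(torsion_integral(line_vessel)) < 1e-9

    def test_full_circle_total_turning(self, circle_vessel):
        assert abs(curvature_integral(circle_vessel) - 2 * np.pi) < 1e-4

    def test_helix_constant_curvature_times_length(self, helix_vessel):
        L = arc_length(helix_vessel)
        assert abs(curvature_integral(helix_vessel) - 0.8 * L) < 1e-3
        assert abs(torsion_integral(helix_vessel) - 0.4 * L) < 1e-3


class TestInvariances:
    def test_rigid_motion_invariance(self, rng):
        v = make_random_vessel(rng, n_ctrl=8)
        R = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        moved = FittedVessel(degree=v.degree, knots=v.knots,
                             ctrl_points=v.ctrl_points @ R.T + shift)
        u = np.linspace(0.1, 0.9, 9)
        assert abs(arc_length(moved) - arc_length(v)) < 1e-9
        np.testing.assert_allclose(curvature(moved, u), curvature(v, u),
                                   rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(torsion(moved, u), torsion(v, u),
                                   rtol=1e-9, atol=1e-12)

    def test_reflection_negates_torsion_only(self, rng):
        v = make_random_vessel(rng, n_ctrl=8)
        mirrored = FittedVessel(degree=v.degree, knots=v.knots,
                                ctrl_points=v.ctrl_points * [1, 1, -1])
        u = np.linspace(0.1, 0.9, 9)
        assert abs(arc_length(mirrored) - arc_length(v)) < 1e-9
        np.testing.assert_allclose(curvature(mirrored, u), curvature(v, u),
                                   rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(torsion(mirrored, u), -torsion(v, u),
                                   rtol=1e-9, atol=1e-12)

    def test_uniform_scaling(self, rng):
        c = 2.5
        v = make_random_vessel(rng, n_ctrl=8)
        scaled = FittedVessel(degree=v.degree, knots=v.knots,
                              ctrl_points=v.ctrl_points * c)
        u = np.linspace(0.1, 0.9, 9)
        assert abs(arc_length(scaled) - c * arc_length(v)) < 1e-6
        np.testing.assert_allclose(curvature(scaled, u),
                                   curvature(v, u) / c, rtol=1e-6)
        np.testing.assert_allclose(torsion(scaled, u),
                                   torsion(v, u) / c, rtol=1e-6)
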