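import numpy as np
import pytest

from vesselquant import FitConfig, Phantom, fit_curve, fit_radius, generate
from vesselquant.bspline import lsq_knot_vector
from vesselquant.model import FittedVessel


def make_random_vessel(rng, n_ctrl=10, degree=3, scale=10.0,
                       with_radii=False):
    """A random smooth cubic B-spline vessel: the control polygon follows a
    slowly turning random direction, so the parameterization stays regular
    (no near-cusps where ||p'|| collapses)."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    steps = [np.zeros(3)]
    for _ in range(n_ctrl - 1):
        axis = rng.normal(size=3)
        axis -= axis @ direction * direction
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, 0.5)
        direction = np.cos(angle) * direction + np.sin(angle) * axis
        steps.append(direction * scale / n_ctrl)
    ctrl = np.cumsum(steps, axis=0)
    u = np.linspace(0.0, 1.0, n_ctrl)
    knots = lsq_knot_vector(u, n_ctrl, degree)
    radii = None
    if with_radii:
        radii = 1.5 + 0.5 * rng.random(n_ctrl)
    return FittedVessel(degree=degree, knots=knots, ctrl_points=ctrl,
                        ctrl_radii=radii)


def fd_derivative(fn, u, order, h=1e-3):
    """4th-order central finite differences of a vector function on [0,1]."""
    f = fn
    if order == 1:
        return (-f(u + 2 * h) + 8 * f(u + h)
                - 8 * f(u - h) + f(u - 2 * h)) / (12 * h)
    if order == 2:
        return (-f(u + 2 * h) + 16 * f(u + h) - 30 * f(u)
                + 16 * f(u - h) - f(u - 2 * h)) / (12 * h * h)
    if order == 3:
        return (f(u - 3 * h) - 8 * f(u - 2 * h) + 13 * f(u - h)
                - 13 * f(u + h) + 8 * f(u + 2 * h)
                - f(u + 3 * h)) / (8 * h ** 3)
    raise ValueError(order)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def helix_phantom():
    return Phantom("helix", n_points=200)  # a=1, b=0.5, span 4*pi


@pytest.fixture(scope="session")
def helix_vessel(helix_phantom):
    ps = generate(helix_phantom)
    vessel = fit_curve(ps)
    return fit_radius(ps, vessel)


@pytest.fixture(scope="session")
def circle_vessel():
    ph = Phantom("circle_arc", params={"a": 2.0, "span": 2 * np.pi},
                 n_points=1000)
    return fit_curve(generate(ph), FitConfig(n_ctrl=500))


@pytest.fixture(scope="session")
def line_vessel():
    ph = Phantom("line", params={"start": (0.0, 0.0, 0.0),
                                 "end": (19.0, 0.0, 0.0)}, n_points=50)
    ps = generate(ph)
    return fit_radius(ps, fit_curve(ps))
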