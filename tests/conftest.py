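"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

import inferode as ide


@pytest.fixture(scope="session")
def conversion_bundle_dir(tmp_path_factory):
    """Conversion-reaction fixture bundle (k1=0.06, k2=0.08, sigma=0.02)."""
    d = tmp_path_factory.mktemp("bundle")
    yaml_path = ide.write_demo_bundle(d, seed=1)
    return yaml_path


@pytest.fixture(scope="session")
def conversion_problem(conversion_bundle_dir):
    return ide.load_problem_bundle(conversion_bundle_dir)


@pytest.fixture(scope="session")
def scaled_bundle_dir(tmp_path_factory):
    """Relative-data fixture: obs_b scaled by s_b=2.5, per-observable noise
    sds estimated, all three flagged hierarchical."""
    d = tmp_path_factory.mktemp("scaled_bundle")
    return ide.write_demo_bundle(d, seed=1, scaled=True, hierarchical=True)


@pytest.fixture()
def gaussian_mean_problem():
    """Gaussian mean estimation, n=50 samples, known sigma=1; returns
    (problem, sample mean, sigma, n)."""
    rng = np.random.default_rng(7)
    n, sigma = 50, 1.0
    data = rng.normal(0.3, sigma, n)

    def nllh(x):
        return ide.gaussian_nllh(np.full(n, x[0]), data, sigma)

    obj = ide.FunctionObjective(nllh)
    prob = ide.Problem(obj, [
        ide.ParameterSpec(id="mu", lower_bound=-5.0, upper_bound=5.0,
                          nominal=0.0)
    ])
    return prob, float(data.mean()), sigma, n


@pytest.fixture()
def rosenbrock_problem():
    obj, specs = ide.get_analytic_objective("rosenbrock_2d")
    return ide.Problem(obj, specs)


class _QuadraticFun:
    """Picklable quadratic ``sum (x - c)^2`` (multiprocess engines pickle
    the problem)."""

    def __init__(self, center):
        self.center = center

    def __call__(self, x):
        return float(np.sum((x - self.center) ** 2))


class _QuadraticGrad:
    def __init__(self, center):
        self.center = center

    def __call__(self, x):
        return 2.0 * (x - self.center)


def make_quadratic_problem(center, lb=-5.0, ub=5.0):
    """Separable convex quadratic ``sum (x_i - c_i)^2`` with analytic grad."""
    center = np.asarray(center, dtype=float)
    obj = ide.FunctionObjective(_QuadraticFun(center), _QuadraticGrad(center))
    specs = [
        ide.ParameterSpec(id=f"x{i}", lower_bound=lb, upper_bound=ub,
                          nominal=0.0)
        for i in range(center.size)
    ]
    return ide.Problem(obj, specs)
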