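"""ODE backend: simulation, sensitivities, likelihood, synthetic data."""

import numpy as np
import pytest

import inferode as ide
from inferode.models import (
    CONVERSION_REACTION,
    CONVERSION_T_GRID,
    EXPONENTIAL_DECAY,
    OdeModel,
)
from inferode.objective import ORDER_GRAD, ORDER_VALUE


class TestSimulate:
    def test_conversion_symmetric_equilibrium(self):
        res = ide.simulate(CONVERSION_REACTION, [1.0, 1.0], [50.0, 100.0])
        assert np.allclose(res.states[-1], [0.5, 0.5], atol=1e-6)

    def test_conversion_mass_conservation(self):
        res = ide.simulate(
            CONVERSION_REACTION, [0.06, 0.08], np.linspace(1, 30, 20)
        )
        assert np.allclose(res.states.sum(axis=1), 1.0, atol=1e-7)

    def test_decay_closed_form(self):
        res = ide.simulate(EXPONENTIAL_DECAY, [1.0], [1.0])
        assert res.states[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-7)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            ide.simulate(EXPONENTIAL_DECAY, [1.0], [2.0, 1.0])

    def test_tolerances_consistent(self):
        """Tightening integrator tolerances changes the trajectory by less
        than the looser tolerance."""
        loose = ide.simulate(CONVERSION_REACTION, [0.06, 0.08],
                             CONVERSION_T_GRID[1:], rtol=1e-6, atol=1e-8)
        tight = ide.simulate(CONVERSION_REACTION, [0.06, 0.08],
                             CONVERSION_T_GRID[1:], rtol=1e-7, atol=1e-9)
        assert np.max(np.abs(loose.states - tight.states)) < 1e-6


class TestSensitivities:
    def test_decay_sensitivity_closed_form(self):
        """d x / d lambda = -t exp(-lambda t)."""
        res = ide.simulate_with_sensitivities(EXPONENTIAL_DECAY, [1.0], [1.0])
        assert res.sensitivities[0, 0, 0] == pytest.approx(-np.exp(-1.0),
                                                           abs=1e-6)

    def test_sensitivities_match_fd(self):
        p = np.array([0.06, 0.08])
        t = np.linspace(1.0, 30.0, 5)
        res = ide.simulate_with_sensitivities(CONVERSION_REACTION, p, t)
        h = 1e-6
        for j in range(2):
            dp = np.zeros(2)
            dp[j] = h
            hi = ide.simulate(CONVERSION_REACTION, p + dp, t).states
            lo = ide.simulate(CONVERSION_REACTION, p - dp, t).states
            fd = (hi - lo) / (2 * h)
            assert np.allclose(res.sensitivities[:, :, j], fd, rtol=1e-5,
                               atol=1e-7)

    def test_unused_parameter_has_zero_sensitivity(self):
        model = OdeModel(
            id="decay_plus_dummy",
            state_dim=1,
            parameter_ids=("lam", "unused"),
            rhs=lambda x, p, t: np.array([-p[0] * x[0]]),
            jac_state=lambda x, p, t: np.array([[-p[0]]]),
            jac_param=lambda x, p, t: np.array([[-x[0], 0.0]]),
            initial_state=lambda p: np.array([1.0]),
            observable_ids=("obs_x",),
            observation_matrix=np.eye(1),
        )
        res = ide.simulate_with_sensitivities(model, [1.0, 3.0], [0.5, 1.0])
        assert np.allclose(res.sensitivities[:, :, 1], 0.0, atol=1e-12)

    def test_registry_jacobians_match_fd(self):
        """Hand-coded rhs Jacobians agree with FD of the rhs."""
        rng = np.random.default_rng(0)
        for model in ide.MODEL_REGISTRY.values():
            for _ in range(5):
                x = rng.uniform(0.1, 1.0, model.state_dim)
                p = rng.uniform(0.05, 0.5, model.n_parameters)
                h = 1e-7
                jx = np.asarray(model.jac_state(x, p, 0.0))
                jp = np.asarray(model.jac_param(x, p, 0.0))
                for i in range(model.state_dim):
                    dx = np.zeros(model.state_dim)
                    dx[i] = h
                    fd = (np.asarray(model.rhs(x + dx, p, 0.0))
                          - np.asarray(model.rhs(x - dx, p, 0.0))) / (2 * h)
                    assert np.allclose(jx[:, i], fd, rtol=1e-6, atol=1e-8)
                for j in range(model.n_parameters):
                    dp = np.zeros(model.n_parameters)
                    dp[j] = h
                    fd = (np.asarray(model.rhs(x, p + dp, 0.0))
                          - np.asarray(model.rhs(x, p - dp, 0.0))) / (2 * h)
                    assert np.allclose(jp[:, j], fd, rtol=1e-6, atol=1e-8)


class TestGaussianNllh:
    def test_zero_residuals_log_term_only(self):
        n = 7
        v = ide.gaussian_nllh(np.ones(n), np.ones(n), 1.0)
        assert v == pytest.approx(0.5 * n * np.log(2 * np.pi))

    def test_single_point_value(self):
        v = ide.gaussian_nllh([0.0], [1.0], 1.0)
        assert v == pytest.approx(0.5 * (np.log(2 * np.pi) + 1.0),
                                  abs=1e-6)

    def test_doubling_sigma_adds_log2_per_point(self):
        n = 4
        v1 = ide.gaussian_nllh(np.zeros(n), np.zeros(n), 1.0)
        v2 = ide.gaussian_nllh(np.zeros(n), np.zeros(n), 2.0)
        assert v2 - v1 == pytest.approx(n * np.log(2.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            ide.gaussian_nllh([0.0], [0.0], 0.0)


class TestSyntheticData:
    def test_same_seed_identical(self):
        a = ide.generate_synthetic_data(
            CONVERSION_REACTION, [0.06, 0.08], CONVERSION_T_GRID, 0.02, seed=4
        )
        b = ide.generate_synthetic_data(
            CONVERSION_REACTION, [0.06, 0.08], CONVERSION_T_GRID, 0.02, seed=4
        )
        assert a.equals(b)

    def test_noise_free_matches_simulation(self):
        table = ide.generate_synthetic_data(
            CONVERSION_REACTION, [0.06, 0.08], CONVERSION_T_GRID, 0.0, seed=0
        )
        res = ide.simulate(CONVERSION_REACTION, [0.06, 0.08],
                           CONVERSION_T_GRID)
        sim = np.concatenate([res.observables[:, 0], res.observables[:, 1]])
        assert np.allclose(table["measurement"].to_numpy(), sim, atol=1e-10)

    def test_residual_sd_within_chi2_bounds(self):
        t = np.linspace(0.5, 30, 100)
        table = ide.generate_synthetic_data(
            CONVERSION_REACTION, [0.06, 0.08], t, 0.1, seed=9
        )
        res = ide.simulate(CONVERSION_REACTION, [0.06, 0.08], t)
        sim = np.concatenate([res.observables[:, 0], res.observables[:, 1]])
        sd = np.std(table["measurement"].to_numpy() - sim)
        assert 0.08 <= sd <= 0.12


class TestRegistry:
    def test_registry_contents(self):
        assert {"conversion_reaction", "exponential_decay"} <= set(
            ide.MODEL_REGISTRY
        )
        assert {"rosenbrock_2d", "gaussian_nd", "bimodal_1d"} <= set(
            ide.OBJECTIVE_REGISTRY
        )

    @pytest.mark.parametrize("name",
                             ["rosenbrock_2d", "gaussian_nd", "bimodal_1d"])
    def test_analytic_gradients_pass_check(self, name):
        obj, specs = ide.get_analytic_objective(name)
        rng = np.random.default_rng(1)
        lb = np.array([s.lower_bound for s in specs])
        ub = np.array([s.upper_bound for s in specs])
        for _ in range(10):
            x = rng.uniform(lb * 0.5, ub * 0.5)
            assert ide.check_gradient(obj, x, tol=1e-5).ok

    def test_bimodal_modes_are_minima(self):
        obj, _ = ide.get_analytic_objective("bimodal_1d")
        f_mode = obj(np.array([5.0]), (ORDER_VALUE,)).fval
        f_mid = obj(np.array([0.0]), (ORDER_VALUE,)).fval
        assert f_mode < f_mid
        assert obj(np.array([-5.0]), (ORDER_VALUE,)).fval == pytest.approx(
            f_mode
        )


class TestOdeObjectiveGradient:
    def test_sensitivity_gradient_matches_fd(self, conversion_problem):
        """Native forward-sensitivity gradients agree with central FD on
        random interior points."""
        prob = conversion_problem
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.uniform(-1.8, -0.6, prob.dim_full)  # log10 scale
            report = ide.check_gradient(prob.objective, x, tol=1e-5)
            assert report.ok

    def test_objective_counts_evaluations(self, conversion_problem):
        obj = conversion_problem.objective
        n0 = obj.n_fval
        obj(conversion_problem.nominal_est_full(), (ORDER_VALUE,))
        obj(conversion_problem.nominal_est_full(), (ORDER_VALUE, ORDER_GRAD))
        assert obj.n_fval == n0 + 2
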