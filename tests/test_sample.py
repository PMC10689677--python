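"""MCMC kernels, adaptation, tempering, diagnostics."""

import numpy as np
import pytest

import inferode as ide
from inferode.sample import DEFAULT_SAMPLE_OPTIONS, _spectral0

from conftest import make_quadratic_problem


def _gaussian_1d_problem():
    obj = ide.FunctionObjective(lambda x: 0.5 * float(x[0] ** 2),
                                lambda x: x)
    return ide.Problem(obj, [
        ide.ParameterSpec(id="x", lower_bound=-10.0, upper_bound=10.0,
                          nominal=0.0)
    ])


class TestMetropolisStep:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        target = lambda x: float(np.sum(x**2))
        for _ in range(50):
            x = rng.uniform(1.0, 2.0, 2)
            x_new, nlp, accepted, alpha = ide.metropolis_step(
                x, target(x), 0.01 * np.eye(2), 1.0, target, rng
            )
            if target(x_new) <= target(x) and not np.array_equal(x_new, x):
                assert accepted

    def test_log2_uphill_has_half_acceptance_probability(self):
        """A proposal whose nlp is log(2) higher is accepted with
        probability exactly 1/2."""
        rng = np.random.default_rng(1)
        shift = np.log(2.0)
        target = lambda x: shift if x[0] > 0.5 else 0.0
        _, _, _, alpha = ide.metropolis_step(
            np.array([0.0]), 0.0, np.eye(1) * 1e-12, 1.0,
            lambda x: shift, rng,
        )
        assert alpha == pytest.approx(0.5)

    def test_uniform_target_acceptance_equals_inbounds_fraction(self):
        """On a flat target, every in-bounds proposal is accepted, so the
        long-run acceptance rate equals the in-bounds proposal fraction
        (geometric Monte-Carlo oracle)."""
        rng = np.random.default_rng(2)
        lb, ub = np.array([0.0]), np.array([1.0])
        x = np.array([0.5])
        cov = np.eye(1)
        accepted = 0
        n = 20000
        oracle_rng = np.random.default_rng(2)
        oracle_in = 0
        for _ in range(n):
            x, _, acc, _ = ide.metropolis_step(
                x, 0.0, cov, 1.0, lambda y: 0.0, rng, lb=lb, ub=ub
            )
            accepted += acc
        # oracle: same kernel geometry via direct simulation
        y = np.array([0.5])
        for _ in range(n):
            z = oracle_rng.standard_normal(1)
            oracle_rng.uniform()
            prop = y + z
            if 0.0 <= prop[0] <= 1.0:
                oracle_in += 1
                y = prop
        assert accepted / n == pytest.approx(oracle_in / n, abs=0.02)

    def test_out_of_bounds_rejected(self):
        rng = np.random.default_rng(3)
        x = np.array([0.99])
        for _ in range(100):
            x_new, _, acc, alpha = ide.metropolis_step(
                x, 0.0, np.eye(1) * 100.0, 1.0, lambda y: 0.0, rng,
                lb=np.array([0.0]), ub=np.array([1.0]),
            )
            assert 0.0 <= x_new[0] <= 1.0


class TestAdapt:
    def test_constant_chain_fixed_point(self):
        mu = np.array([0.0])
        Sigma = np.eye(1)
        c = np.array([2.0])
        ls = 0.0
        for t in range(1, 5000):
            mu, Sigma, ls = ide.adapt(mu, Sigma, ls, c, 0.234, t)
        assert mu[0] == pytest.approx(2.0, abs=1e-3)
        assert Sigma[0, 0] < 1e-2  # decays toward the eps*I floor

    def test_on_target_acceptance_leaves_scale_unchanged(self):
        alpha_t = DEFAULT_SAMPLE_OPTIONS["alpha_target"]
        _, _, ls = ide.adapt(np.zeros(2), np.eye(2), 0.7, np.ones(2),
                             alpha_t, 10)
        assert ls == pytest.approx(0.7)

    def test_covariance_stays_symmetric_psd(self):
        rng = np.random.default_rng(4)
        mu, Sigma, ls = np.zeros(3), np.eye(3), 0.0
        for t in range(1, 500):
            x = rng.standard_normal(3)
            mu, Sigma, ls = ide.adapt(mu, Sigma, ls, x, 0.3, t)
        assert np.allclose(Sigma, Sigma.T)
        assert np.min(np.linalg.eigvalsh(Sigma)) > 0


class TestAdaptiveMetropolis:
    def test_standard_normal_moments(self):
        prob = _gaussian_1d_problem()
        tr = ide.sample_adaptive_metropolis(prob, n_iter=50000, seed=8)
        x = tr.states[10000:, 0]
        assert abs(x.mean()) < 0.05
        assert abs(x.var() - 1.0) < 0.1

    def test_terminal_acceptance_near_target(self):
        prob = _gaussian_1d_problem()
        tr = ide.sample_adaptive_metropolis(prob, n_iter=50000, seed=8)
        rate = tr.acceptance[-10000:].mean()
        assert 0.134 <= rate <= 0.334

    def test_bit_identical_given_seed(self):
        prob = _gaussian_1d_problem()
        a = ide.sample_adaptive_metropolis(prob, n_iter=2000, seed=5)
        b = ide.sample_adaptive_metropolis(prob, n_iter=2000, seed=5)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.acceptance, b.acceptance)

    def test_shift_invariance(self):
        """Adding a constant to the objective changes nothing: acceptance
        depends only on nlp differences. The target is quantized to dyadic
        values so the shifted sums are exact in floating point."""

        def base(x):
            return float(np.floor(0.5 * x[0] ** 2 * 256.0) / 256.0)

        obj1 = ide.FunctionObjective(base)
        obj2 = ide.FunctionObjective(lambda x: base(x) + 123.0)
        spec = [ide.ParameterSpec(id="x", lower_bound=-10.0, upper_bound=10.0,
                                  nominal=0.0)]
        a = ide.sample_adaptive_metropolis(ide.Problem(obj1, spec),
                                           n_iter=2000, seed=6)
        b = ide.sample_adaptive_metropolis(ide.Problem(obj2, spec),
                                           n_iter=2000, seed=6)
        assert np.array_equal(a.states, b.states)

    def test_adaptation_freeze(self):
        prob = _gaussian_1d_problem()
        tr = ide.sample_adaptive_metropolis(
            prob, n_iter=3000, seed=7, options={"adapt_until": 1000}
        )
        assert tr.n_iter == 3000  # frozen adaptation still samples

    def test_nonfinite_start_rejected(self):
        obj = ide.FunctionObjective(lambda x: float("inf"))
        prob = ide.Problem(obj, [
            ide.ParameterSpec(id="x", lower_bound=-1.0, upper_bound=1.0,
                              nominal=0.0)
        ])
        with pytest.raises(ValueError, match="non-finite"):
            ide.sample_adaptive_metropolis(prob, n_iter=10, seed=0)

    def test_frozen_kernel_detailed_balance(self):
        """With adaptation frozen, occupancy of two half-spaces of an
        asymmetric two-level target matches the analytic stationary
        frequencies within Monte-Carlo error."""
        delta = 1.0  # nlp gap between the wells

        def nlp(x):
            return 0.0 if x[0] < 0 else delta

        obj = ide.FunctionObjective(nlp)
        prob = ide.Problem(obj, [
            ide.ParameterSpec(id="x", lower_bound=-1.0, upper_bound=1.0,
                              nominal=0.0)
        ])
        tr = ide.sample_adaptive_metropolis(
            prob, x0=np.array([-0.5]), n_iter=200000, seed=3,
            options={"adapt_until": 0},
        )
        frac_high = (tr.states[20000:, 0] >= 0).mean()
        expected = np.exp(-delta) / (1 + np.exp(-delta))
        assert frac_high == pytest.approx(expected, abs=0.03)


class TestSwap:
    def test_equal_energies_always_swap(self):
        assert ide.swap_acceptance_probability(1.0, 0.5, 3.0, 3.0) == 1.0

    def test_equal_betas_always_swap(self):
        assert ide.swap_acceptance_probability(0.5, 0.5, 10.0, -4.0) == 1.0

    def test_printed_toy_values(self):
        assert ide.swap_acceptance_probability(1.0, 0.5, 10.0, 8.0) == 1.0
        assert ide.swap_acceptance_probability(1.0, 0.5, 8.0, 10.0) == (
            pytest.approx(np.exp(-1.0), abs=1e-12)
        )

    def test_swap_step_exchanges_states(self):
        rng = np.random.default_rng(0)
        states = [np.array([1.0]), np.array([2.0])]
        nlps = [5.0, 5.0]  # equal energies: certain swap
        new_states, new_nlps, acc, att = ide.swap_step(
            states, nlps, [1.0, 0.5], rng, parity=0
        )
        assert acc[0] and att[0]
        assert new_states[0][0] == 2.0 and new_states[1][0] == 1.0

    def test_alternating_parity_schedule(self):
        rng = np.random.default_rng(0)
        states = [np.array([float(i)]) for i in range(4)]
        nlps = [0.0] * 4
        _, _, _, att_even = ide.swap_step(states, nlps, [1, .5, .25, .125],
                                          rng, parity=0)
        _, _, _, att_odd = ide.swap_step(states, nlps, [1, .5, .25, .125],
                                         rng, parity=1)
        assert list(att_even) == [True, False, True]
        assert list(att_odd) == [False, True, False]


class TestLadder:
    def test_geometric_initialization(self):
        betas = ide.geometric_ladder(5, 0.25)
        assert np.allclose(betas, [1.0, 0.25, 0.0625, 0.015625, 0.00390625])

    def test_equal_acceptances_leave_ladder_unchanged(self):
        betas = ide.geometric_ladder(4, 0.5)
        out = ide.adapt_ladder(betas, [0.3, 0.3, 0.3], t=10)
        assert np.allclose(out, betas)

    def test_unequal_acceptance_widens_hot_gap(self):
        """Persistently higher acceptance of pair 0 widens gap 0 relative
        to gap 1."""
        betas = ide.geometric_ladder(4, 0.5)
        out = ide.adapt_ladder(betas, [0.8, 0.2, 0.2], t=0)
        T0, T1 = 1.0 / betas, 1.0 / out
        gaps0 = np.diff(T0)
        gaps1 = np.diff(T1)
        assert gaps1[0] / gaps0[0] > gaps1[1] / gaps0[1]

    def test_monotone_and_pinned(self):
        betas = ide.geometric_ladder(5, 0.25)
        out = ide.adapt_ladder(betas, [0.9, 0.1, 0.5, 0.4], t=3)
        assert out[0] == 1.0
        assert np.all(np.diff(out) < 0)

    def test_needs_three_chains(self):
        with pytest.raises(ValueError):
            ide.adapt_ladder([1.0, 0.5], [0.5], t=0)


class TestParallelTempering:
    def test_single_chain_reduces_to_adaptive_metropolis(self):
        prob = _gaussian_1d_problem()
        am = ide.sample_adaptive_metropolis(prob, n_iter=1500, seed=9)
        pt = ide.sample_parallel_tempering(prob, n_chains=1, n_iter=1500,
                                           seed=9)
        assert np.array_equal(am.states, pt.posterior.states)
        assert np.array_equal(am.acceptance, pt.posterior.acceptance)

    def test_deterministic_given_seed(self):
        prob = _gaussian_1d_problem()
        a = ide.sample_parallel_tempering(prob, n_chains=3, n_iter=800,
                                          seed=2)
        b = ide.sample_parallel_tempering(prob, n_chains=3, n_iter=800,
                                          seed=2)
        for ca, cb in zip(a.traces, b.traces):
            assert np.array_equal(ca.states, cb.states)

    def test_betas_sorted_and_pinned(self):
        prob = _gaussian_1d_problem()
        pt = ide.sample_parallel_tempering(prob, n_chains=4, n_iter=2000,
                                           seed=1)
        assert pt.betas[0] == 1.0
        assert np.all(np.diff(pt.betas) < 0)
        assert pt.betas[-1] > 0

    def test_swap_counters_accumulate(self):
        prob = _gaussian_1d_problem()
        pt = ide.sample_parallel_tempering(prob, n_chains=3, n_iter=1000,
                                           seed=1)
        assert pt.swap_attempt_counts.sum() == 100  # 1000/10 rounds, alt pairs
        assert np.all(pt.swap_accept_counts <= pt.swap_attempt_counts)


class TestDiagnostics:
    def test_geweke_iid_chain_no_burn_in(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((2000, 2))
            if ide.geweke_burn_in(x) == 0:
                hits += 1
        assert hits >= 8  # z < 2 with prob ~0.95 per segment pair

    def test_geweke_detects_shifted_prefix(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.standard_normal((n, 1))
        x[: int(0.3 * n)] += 10.0
        assert ide.geweke_burn_in(x) >= int(0.3 * n)

    def test_constant_chain_degenerate_flag(self):
        x = np.ones((500, 1))
        burn, diag = ide.geweke_burn_in(x, return_diagnostics=True)
        assert burn == 0
        assert diag["degenerate"]

    def test_ess_iid_near_n(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.standard_normal((n, 1))
        ess = ide.effective_sample_size(x)
        assert 0.8 * n <= ess <= 1.2 * n

    def test_ess_ar1_matches_closed_form(self):
        """AR(1) with phi=0.9: ESS ~ n (1-phi)/(1+phi) = n/19."""
        rng = np.random.default_rng(2)
        n, phi = 40000, 0.9
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + np.sqrt(1 - phi**2) * eps[t]
        ess = ide.effective_sample_size(x[:, None])
        expected = n / 19
        assert expected / 1.5 <= ess <= expected * 1.5

    def test_ess_duplicated_states_halved(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(4000)
        x = np.repeat(base, 2)[:, None]
        ess = ide.effective_sample_size(x)
        assert ess == pytest.approx(len(x) / 2, rel=0.25)

    def test_spectral_density_positive(self):
        rng = np.random.default_rng(4)
        assert _spectral0(rng.standard_normal(1000)) > 0
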