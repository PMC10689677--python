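"""Hierarchical inner solvers vs brute-force oracles and the joint fit."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import inferode as ide
from inferode.hierarchical import solve_inner_offset


class TestScaling:
    def test_exact_multiple_recovered(self):
        sim = np.array([0.5, 1.0, 2.0])
        assert ide.solve_inner_scaling(sim, 2.0 * sim) == pytest.approx(2.0)

    def test_two_point_example(self):
        assert ide.solve_inner_scaling([1.0, 1.0], [1.0, 3.0]) == pytest.approx(
            2.0
        )

    def test_matches_grid_search(self):
        rng = np.random.default_rng(3)
        sim = rng.uniform(0.1, 2.0, 12)
        data = 3.3 * sim + rng.normal(0, 0.3, 12)
        grid = np.arange(0.0, 10.0, 1e-4)
        losses = ((data[None, :] - grid[:, None] * sim[None, :]) ** 2).sum(1)
        s_grid = grid[np.argmin(losses)]
        assert ide.solve_inner_scaling(sim, data) == pytest.approx(
            s_grid, abs=1e-3
        )

    def test_zero_simulation_degenerate(self):
        with pytest.raises(ide.DegenerateGroupError):
            ide.solve_inner_scaling(np.zeros(3), np.ones(3))


class TestOffsetScaling:
    def test_exact_affine_recovered(self):
        sim = np.array([0.0, 1.0, 2.0, 5.0])
        b, s = ide.solve_inner_offset_scaling(sim, 3.0 + 2.0 * sim)
        assert (b, s) == (pytest.approx(3.0), pytest.approx(2.0))

    def test_constant_data_gives_zero_scaling(self):
        sim = np.array([0.0, 1.0, 2.0])
        b, s = ide.solve_inner_offset_scaling(sim, np.full(3, 4.2))
        assert s == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(4.2)

    def test_matches_grid_search(self):
        rng = np.random.default_rng(5)
        sim = rng.uniform(0.0, 2.0, 15)
        data = 1.5 + 0.8 * sim + rng.normal(0, 0.2, 15)
        bg = np.arange(0.5, 2.5, 5e-3)
        sg = np.arange(0.0, 2.0, 5e-3)
        B, S = np.meshgrid(bg, sg, indexing="ij")
        losses = (
            (data[None, None, :] - B[..., None] - S[..., None] * sim) ** 2
        ).sum(-1)
        i, j = np.unravel_index(np.argmin(losses), losses.shape)
        b, s = ide.solve_inner_offset_scaling(sim, data)
        assert b == pytest.approx(bg[i], abs=5e-3)
        assert s == pytest.approx(sg[j], abs=5e-3)

    def test_constant_simulation_degenerate(self):
        with pytest.raises(ide.DegenerateGroupError):
            ide.solve_inner_offset_scaling(np.ones(4), np.arange(4.0))


class TestSigma:
    def test_equal_residuals(self):
        sim = np.zeros(5)
        assert ide.solve_inner_sigma(sim, np.full(5, -1.3)) == pytest.approx(
            1.3
        )

    def test_two_residual_example(self):
        assert ide.solve_inner_sigma(np.zeros(2), np.array([3.0, 4.0])
                                     ) == pytest.approx(np.sqrt(12.5))

    def test_matches_numeric_minimization(self):
        rng = np.random.default_rng(11)
        sim = rng.uniform(0, 1, 20)
        data = sim + rng.normal(0, 0.4, 20)

        def nllh_of_sigma(log_sigma):
            return ide.gaussian_nllh(sim, data, np.exp(log_sigma))

        res = minimize_scalar(nllh_of_sigma, bounds=(-8, 2),
                              method="bounded",
                              options={"xatol": 1e-10})
        assert ide.solve_inner_sigma(sim, data) == pytest.approx(
            np.exp(res.x), abs=1e-6
        )

    def test_zero_residuals_give_zero(self):
        sim = np.arange(4.0)
        assert ide.solve_inner_sigma(sim, sim) == 0.0


class TestRandomInstancesAgainstBruteForce:
    def test_inner_solutions_match_numeric_optimum(self):
        """Core correctness surface: analytic (b*, s*, sigma*) equal
        numeric inner optimization on 100 random instances."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(4, 20)
            sim = rng.uniform(-1, 2, n)
            if np.ptp(sim) < 1e-3:
                sim[0] += 1.0
            data = (rng.uniform(-2, 2) + rng.uniform(0.1, 3) * sim
                    + rng.normal(0, 0.3, n))
            b, s = ide.solve_inner_offset_scaling(sim, data)
            sigma = ide.solve_inner_sigma(sim, data, b=b, s=s)

            # numeric oracle: Nelder-Mead over (b, s), closed form checked
            # against direct 1-D minimization for sigma
            from scipy.optimize import minimize as num_min
            res = num_min(
                lambda v: np.sum((data - v[0] - v[1] * sim) ** 2),
                x0=np.array([0.0, 1.0]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14,
                         "maxiter": 10000},
            )
            assert b == pytest.approx(res.x[0], abs=1e-6)
            assert s == pytest.approx(res.x[1], abs=1e-6)

            res_sig = minimize_scalar(
                lambda ls: ide.gaussian_nllh(b + s * sim, data, np.exp(ls)),
                bounds=(-10, 3), method="bounded",
                options={"xatol": 1e-12},
            )
            assert sigma == pytest.approx(np.exp(res_sig.x), abs=1e-6)


class TestHierarchicalObjective:
    def test_inner_optimum_dominates_fixed_inner_values(self, tmp_path):
        yml = ide.write_demo_bundle(tmp_path, seed=1, scaled=True,
                                    hierarchical=True)
        hier = ide.load_problem_bundle(yml)
        joint = ide.load_problem_bundle(yml, hierarchical=False)
        outer = hier.nominal_est_full()
        f_hier = hier.objective(outer).fval
        rng = np.random.default_rng(0)
        for _ in range(5):
            inner = rng.uniform(
                [np.log10(0.5), np.log10(0.005), np.log10(0.005)],
                [np.log10(5.0), np.log10(0.1), np.log10(0.1)],
            )
            full = np.concatenate([outer, inner])
            assert f_hier <= joint.objective(full).fval + 1e-10

    def test_noise_free_scaling_recovered_exactly(self, tmp_path):
        yml = ide.write_demo_bundle(tmp_path, sigma=0.0, seed=1, scaled=True,
                                    hierarchical=True)
        prob = ide.load_problem_bundle(yml)
        val = prob.objective(prob.nominal_est_full())
        assert val.inner_parameters["s_b"] == pytest.approx(2.5, abs=1e-8)

    def test_outer_dimension_reduced(self, scaled_bundle_dir):
        hier = ide.load_problem_bundle(scaled_bundle_dir)
        joint = ide.load_problem_bundle(scaled_bundle_dir,
                                        hierarchical=False)
        assert hier.dim_full == 2
        assert joint.dim_full == 5

    def test_hierarchical_and_joint_share_optimum(self, scaled_bundle_dir):
        """Same optimal fval; hierarchical outer argmin matches the outer
        coordinates of the joint argmin."""
        hier = ide.load_problem_bundle(scaled_bundle_dir)
        joint = ide.load_problem_bundle(scaled_bundle_dir,
                                        hierarchical=False)
        r_hier = ide.minimize_multistart(hier, n_starts=5, seed=2)
        r_joint = ide.minimize_multistart(joint, n_starts=8, seed=2)
        assert r_hier.best.fval == pytest.approx(r_joint.best.fval, abs=1e-6)
        assert np.allclose(r_hier.best.x, r_joint.best.x[:2], atol=1e-3)

    def test_offset_only_group(self):
        """Offset-only inner role: b* is the mean residual."""
        sim = np.array([0.1, 0.4, 0.9])
        data = sim + 0.7
        assert solve_inner_offset(sim, data) == pytest.approx(0.7)
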