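import numpy as np
import pytest
from scipy import optimize

from mtglasso.solver import (
    SolverConfig,
    gcd_fit,
    group_soft_threshold,
    kkt_residual,
    lambda_max,
    objective,
    solve_path,
)
from mtglasso.stacking import MultiResponseData, orthonormalize, stack

from _oracles import fista_group_lasso, random_instance


class TestGroupSoftThreshold:
    @pytest.mark.parametrize(
        "z, t, expected",
        [
            ([3.0, 4.0], 5.0, [0.0, 0.0]),  # ||z|| = threshold boundary
            ([3.0, 4.0], 0.0, [3.0, 4.0]),  # no penalty
            ([0.0, 0.0], 1.0, [0.0, 0.0]),  # zero input
            ([-6.0, 8.0], 5.0, [-3.0, 4.0]),  # half shrinkage
        ],
    )
    def test_closed_form_cases(self, z, t, expected):
        np.testing.assert_allclose(group_soft_threshold(z, t), expected)

    def test_matches_numeric_minimizer(self):
        """S(z, t) solves min_b 0.5||z-b||^2 + t*||b||, checked against a
        direct 2-D numerical minimisation."""
        z = np.array([3.0, 4.0])
        t = 2.5

        def crit(b):
            return 0.5 * np.sum((z - b) ** 2) + t * np.linalg.norm(b)

        res = optimize.minimize(crit, [1.0, 1.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(group_soft_threshold(z, t), res.x, atol=1e-6)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            group_soft_threshold([1.0, 2.0], -0.1)


class TestLambdaMax:
    def test_zero_response(self, random_data):
        data = MultiResponseData(
            random_data.genotypes, np.zeros_like(random_data.phenotypes) + [[1.0, 2.0]]
        )
        stacked = stack(data, standardize_traits=False)
        basis = orthonormalize(stacked)
        assert lambda_max(stacked, basis) == 0.0

    def test_q1_closed_form(self, rng):
        G = rng.integers(0, 3, size=(30, 4))
        G[:2] = [[0, 1, 2, 1], [2, 0, 1, 0]]
        y = rng.normal(size=(30, 1))
        stacked = stack(MultiResponseData(G, y))
        basis = orthonormalize(stacked)
        expected = np.abs(stacked.Xs.T @ stacked.Yw[:, 0]).max() / stacked.c
        np.testing.assert_allclose(lambda_max(stacked, basis), expected, rtol=1e-12)

    def test_brackets_the_zero_solution(self, stacked_basis):
        stacked, basis = stacked_basis
        lmax = lambda_max(stacked, basis)
        b_at = gcd_fit(stacked, basis, lmax).values
        b_below = gcd_fit(stacked, basis, 0.9 * lmax).values
        assert np.all(b_at == 0)
        assert np.any(b_below != 0)


class TestGcdFit:
    def test_matches_convex_oracle(self, rng):
        """Final objective within 1e-6 relative of an independent
        proximal-gradient optimum on random small instances."""
        for _ in range(8):
            data = random_instance(rng)
            stacked = stack(data)
            basis = orthonormalize(stacked)
            w = np.full(stacked.p, np.sqrt(stacked.q))
            lam = float(rng.uniform(0.05, 0.8)) * lambda_max(stacked, basis, w)
            coef, info = gcd_fit(
                stacked, basis, lam, config=SolverConfig(tol=1e-7), return_info=True
            )
            _, obj_oracle = fista_group_lasso(stacked, basis, lam, w, n_iter=5000)
            assert abs(info["objective"] - obj_oracle) <= 1e-6 * abs(obj_oracle)

    def test_objective_non_increasing_per_sweep(self, rng):
        for _ in range(4):
            data = random_instance(rng)
            stacked = stack(data)
            basis = orthonormalize(stacked)
            lam = 0.2 * lambda_max(stacked, basis)
            _, info = gcd_fit(
                stacked,
                basis,
                lam,
                config=SolverConfig(strategy="cyclic", track_objective=True),
                return_info=True,
            )
            objs = np.array(info["objective_per_sweep"])
            assert np.all(np.diff(objs) <= 1e-12)

    def test_kkt_conditions_hold(self, stacked_basis):
        stacked, basis = stacked_basis
        tol = 1e-6
        lam = 0.3 * lambda_max(stacked, basis)
        coef = gcd_fit(stacked, basis, lam, config=SolverConfig(tol=tol))
        assert kkt_residual(stacked, basis, coef, lam) <= 10 * tol

    def test_all_in_all_out_selection(self, small_signal_dataset):
        """A group is either entirely zero or entirely nonzero."""
        stacked = stack(small_signal_dataset.data)
        basis = orthonormalize(stacked)
        coef = gcd_fit(stacked, basis, 0.3 * lambda_max(stacked, basis)).values
        for row in coef:
            assert np.all(row == 0) or np.all(row != 0)

    def test_group_order_permutation_invariance(self, rng):
        """Cycling groups in a different order changes the converged solution
        by at most 10*tol in every coefficient."""
        data = random_instance(rng)
        stacked = stack(data)
        basis = orthonormalize(stacked)
        lam = 0.15 * lambda_max(stacked, basis)
        tol = 1e-7
        b1 = gcd_fit(stacked, basis, lam, config=SolverConfig(tol=tol)).values
        # permute the SNP order, fit, un-permute
        perm = rng.permutation(data.p)
        data_p = MultiResponseData(data.genotypes[:, perm], data.phenotypes)
        stacked_p = stack(data_p)
        basis_p = orthonormalize(stacked_p)
        b2p = gcd_fit(stacked_p, basis_p, lam, config=SolverConfig(tol=tol)).values
        b2 = np.empty_like(b2p)
        b2[perm] = b2p
        np.testing.assert_allclose(b1, b2, atol=10 * tol)

    def test_active_set_matches_plain_cyclic(self, rng):
        data = random_instance(rng)
        stacked = stack(data)
        basis = orthonormalize(stacked)
        lam = 0.1 * lambda_max(stacked, basis)
        tol = 1e-8
        b_a = gcd_fit(stacked, basis, lam,
                      config=SolverConfig(tol=tol, strategy="active_set")).values
        b_c = gcd_fit(stacked, basis, lam,
                      config=SolverConfig(tol=tol, strategy="cyclic")).values
        np.testing.assert_allclose(b_a, b_c, atol=10 * tol)

    def test_q1_matches_sklearn_lasso(self, rng):
        """With q=1 the group Lasso is the Lasso: coefficients must match a
        reference Lasso on the same standardized data."""
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        G = rng.integers(0, 3, size=(60, 8))
        G[:2] = [[0, 1, 2, 0, 1, 2, 0, 1], [2, 0, 1, 2, 0, 1, 2, 0]]
        beta = np.zeros(8)
        beta[[1, 4]] = [0.7, -0.5]
        y = (G - G.mean(0)) @ beta + rng.normal(size=60)
        data = MultiResponseData(G, y[:, None])
        stacked = stack(data, standardize_traits=False)
        basis = orthonormalize(stacked)
        lmax = lambda_max(stacked, basis)
        for lam in np.geomspace(lmax * 0.9, lmax * 0.01, 8):
            b = gcd_fit(stacked, basis, lam, config=SolverConfig(tol=1e-9)).values
            ref = sklearn_linear.Lasso(alpha=lam, fit_intercept=False,
                                       tol=1e-12, max_iter=100000)
            ref.fit(stacked.Xs, stacked.Yw[:, 0])
            np.testing.assert_allclose(b[:, 0], ref.coef_, atol=1e-5)


class TestSolvePath:
    def test_single_lambda_max_grid(self, stacked_basis):
        stacked, basis = stacked_basis
        lmax = lambda_max(stacked, basis)
        path = solve_path(
            stacked, basis, SolverConfig(lambda_grid=np.array([lmax]))
        )
        assert path.n_active[0] == 0

    def test_warm_equals_cold(self, rng):
        """Warm-started path solutions agree with cold starts in objective."""
        data = random_instance(rng)
        stacked = stack(data)
        basis = orthonormalize(stacked)
        config = SolverConfig(tol=1e-8, n_lambdas=12)
        path = solve_path(stacked, basis, config)
        for i, lam in enumerate(path.lambdas):
            cold, info = gcd_fit(stacked, basis, lam,
                                 config=SolverConfig(tol=1e-8), return_info=True)
            assert abs(path.objectives[i] - info["objective"]) <= 1e-6 * max(
                abs(info["objective"]), 1e-12
            )

    def test_activity_grows_along_path(self, small_signal_dataset):
        stacked = stack(small_signal_dataset.data)
        basis = orthonormalize(stacked)
        path = solve_path(stacked, basis, SolverConfig(n_lambdas=30))
        assert path.n_active[0] == 0
        assert path.n_active[-1] >= path.n_active[0]
        assert path.n_active[-1] > 0

    def test_grid_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            SolverConfig(lambda_grid=np.array([0.1, 0.2]))


class TestObjective:
    def test_null_coefficients(self, stacked_basis):
        stacked, basis = stacked_basis
        b = np.zeros((stacked.p, stacked.q))
        expected = 0.5 * float(stacked.y @ stacked.y) / stacked.c
        np.testing.assert_allclose(objective(stacked, basis, b, 0.5), expected)

    def test_dimension_mismatch(self, stacked_basis):
        stacked, basis = stacked_basis
        with pytest.raises(ValueError, match="shape"):
            objective(stacked, basis, np.zeros((2, 2)), 0.1)
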