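import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quantherit.pairs import build_op_pairs
from quantherit.quantreg import (
    DegenerateDesignError,
    QuantileGrid,
    bootstrap_process,
    check_loss,
    fit_quantile_process,
    fit_weighted_ols,
    fit_weighted_quantile,
)

from conftest import lp_quantile_oracle, weighted_check_objective


class TestCheckLoss:
    @pytest.mark.parametrize(
        "u,tau,expected",
        [(1.0, 0.9, 0.9), (-1.0, 0.9, 0.1), (-2.0, 0.5, 1.0), (0.0, 0.3, 0.0),
         (3.0, 0.25, 0.75)],
    )
    def test_closed_form(self, u, tau, expected):
        assert check_loss(u, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_tau_domain(self, tau):
        with pytest.raises(ValueError):
            check_loss(1.0, tau)

    @given(st.floats(-1e6, 1e6), st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_nonnegative_and_zero_iff_zero(self, u, tau):
        v = check_loss(u, tau)
        assert v >= 0.0
        assert (v == 0.0) == (u == 0.0)


class TestSingleQuantileFit:
    def test_perfect_fit_any_tau(self, rng):
        x = rng.normal(size=50)
        for tau in (0.1, 0.5, 0.9):
            a, b = fit_weighted_quantile((x, x, None), tau)
            assert a == pytest.approx(0.0, abs=1e-9)
            assert b == pytest.approx(1.0, abs=1e-9)

    def test_three_point_median_example(self):
        """(0,0),(1,1),(2,4) at tau=0.5: the best line is y=2x (loss 1),
        verified by enumerating every two-point line."""
        x, y = np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 4.0])
        a, b = fit_weighted_quantile((x, y, None), 0.5)
        best = min(
            weighted_check_objective(x, y, None, 0.5,
                                     y[i] - (y[j] - y[i]) / (x[j] - x[i]) * x[i],
                                     (y[j] - y[i]) / (x[j] - x[i]))
            for i in range(3) for j in range(3) if i != j
        )
        got = weighted_check_objective(x, y, None, 0.5, a, b)
        assert got == pytest.approx(best, abs=1e-12)
        assert (a, b) == (pytest.approx(0.0, abs=1e-9), pytest.approx(2.0, abs=1e-9))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("tau", [0.05, 0.25, 0.5, 0.75, 0.95])
    def test_matches_lp_oracle_weighted(self, seed, tau):
        rng = np.random.default_rng(seed)
        n = 200
        x = rng.normal(size=n)
        y = 1 + 2 * x + rng.standard_t(3, size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        a, b = fit_weighted_quantile((x, y, w), tau)
        *_, f_lp = lp_quantile_oracle(x, y, w, tau)
        f = weighted_check_objective(x, y, w, tau, a, b)
        assert f <= f_lp + 1e-6 * (1 + abs(f_lp))

    def test_matches_statsmodels_unweighted(self, rng):
        import statsmodels.api as sm

        n = 300
        x = rng.normal(size=n)
        y = 0.5 + 1.5 * x + rng.normal(size=n)
        X = sm.add_constant(x)
        for tau in (0.25, 0.75):
            ref = sm.QuantReg(y, X).fit(q=tau, p_tol=1e-10)
            a, b = fit_weighted_quantile((x, y, None), tau)
            f_ours = weighted_check_objective(x, y, None, tau, a, b)
            f_ref = weighted_check_objective(x, y, None, tau, *ref.params)
            assert f_ours <= f_ref + 1e-6

    def test_degenerate_x_raises(self):
        with pytest.raises(DegenerateDesignError):
            fit_weighted_quantile(([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], None), 0.5)

    def test_objective_beats_ols_line(self, rng):
        x = rng.normal(size=100)
        y = 2 * x + rng.gamma(2.0, 1.0, size=100)
        ols = fit_weighted_ols((x, y, None))
        for tau in (0.2, 0.5, 0.8):
            a, b = fit_weighted_quantile((x, y, None), tau)
            assert weighted_check_objective(x, y, None, tau, a, b) <= (
                weighted_check_objective(x, y, None, tau, ols.intercept, ols.slope)
            )


class TestEquivariance:
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
        tau=st.sampled_from([0.2, 0.5, 0.8]),
    )
    @settings(deadline=None, max_examples=15)
    def test_affine_equivariance(self, scale, shift, tau):
        rng = np.random.default_rng(99)
        x = rng.normal(size=80)
        y = 1 + x + rng.normal(size=80) * (1 + 0.3 * np.abs(x))
        w = rng.uniform(0.5, 1.5, size=80)
        a0, b0 = fit_weighted_quantile((x, y, w), tau)
        # scale y
        a1, b1 = fit_weighted_quantile((x, scale * y, w), tau)
        assert b1 == pytest.approx(scale * b0, rel=1e-6, abs=1e-8)
        # scale x
        a2, b2 = fit_weighted_quantile((scale * x, y, w), tau)
        assert b2 == pytest.approx(b0 / scale, rel=1e-6, abs=1e-8)
        # shift x: slope unchanged, intercept absorbs
        a3, b3 = fit_weighted_quantile((x + shift, y, w), tau)
        assert b3 == pytest.approx(b0, rel=1e-6, abs=1e-8)
        assert a3 == pytest.approx(a0 - b0 * shift, rel=1e-6, abs=1e-6)


class TestProcess:
    def test_grid_of_length_one_matches_single_fit(self, rng):
        x = rng.normal(size=120)
        y = x + rng.normal(size=120)
        fit = fit_quantile_process((x, y, None), QuantileGrid(np.array([0.3])))
        a, b = fit_weighted_quantile((x, y, None), 0.3)
        assert fit.intercepts[0] == pytest.approx(a, abs=1e-10)
        assert fit.slopes[0] == pytest.approx(b, abs=1e-10)

    def test_constant_slope_under_bivariate_normal(self, rng):
        rho = 0.4
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=4000)
        grid = QuantileGrid(np.array([0.1, 0.5, 0.9]))
        fit = bootstrap_process((z[:, 1], z[:, 0], None), grid, n_boot=200, seed=5)
        spread = fit.slopes.max() - fit.slopes.min()
        assert spread < 4 * fit.slope_se.max()

    def test_lognormal_slopes_rise_with_tau(self, rng):
        rho = 0.4
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=6000)
        y, x = np.exp(0.6 * z[:, 0]), np.exp(0.6 * z[:, 1])
        fit = fit_quantile_process((x, y, None), QuantileGrid(np.array([0.1, 0.9])))
        assert fit.slopes[1] > fit.slopes[0]


class TestBootstrap:
    def _pairs(self, rng, n=400):
        rho = 0.4
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        return z[:, 1], z[:, 0], None

    def test_seed_determinism(self, rng):
        x, y, w = self._pairs(rng)
        grid = QuantileGrid(np.array([0.25, 0.5, 0.75]))
        f1 = bootstrap_process((x, y, w), grid, n_boot=50, seed=11)
        f2 = bootstrap_process((x, y, w), grid, n_boot=50, seed=11)
        np.testing.assert_array_equal(f1.slope_cov, f2.slope_cov)
        f3 = bootstrap_process((x, y, w), grid, n_boot=50, seed=12)
        assert not np.array_equal(f1.slope_cov, f3.slope_cov)

    def test_two_replicates_give_rank_one_covariance(self, rng):
        x, y, w = self._pairs(rng, n=100)
        grid = QuantileGrid(np.array([0.3, 0.5, 0.7]))
        fit = bootstrap_process((x, y, w), grid, n_boot=2, seed=1)
        assert np.linalg.matrix_rank(fit.slope_cov, tol=1e-10) <= 1

    def test_covariance_psd_and_se_consistent(self, rng):
        x, y, w = self._pairs(rng)
        grid = QuantileGrid(np.array([0.2, 0.5, 0.8]))
        fit = bootstrap_process((x, y, w), grid, n_boot=100, seed=3)
        eig = np.linalg.eigvalsh(fit.slope_cov)
        assert eig.min() >= -1e-12
        np.testing.assert_allclose(
            fit.slope_se, np.sqrt(np.diag(fit.slope_cov)), atol=1e-12
        )

    def test_median_se_matches_analytic_sandwich(self, rng):
        """iid-normal errors: bootstrap SE of the median slope within 25% of
        sqrt(tau(1-tau)/f(0)^2 * [(X'X)^-1]_bb)."""
        n = 2000
        x = rng.normal(size=n)
        sigma = 0.8
        y = 1.0 + 0.5 * x + rng.normal(0, sigma, size=n)
        grid = QuantileGrid(np.array([0.5]))
        fit = bootstrap_process((x, y, None), grid, n_boot=300, seed=21)
        X = np.column_stack([np.ones(n), x])
        f0 = 1.0 / (sigma * np.sqrt(2 * np.pi))
        analytic = np.sqrt(0.25 / f0**2 * np.linalg.inv(X.T @ X)[1, 1])
        assert fit.slope_se[0] == pytest.approx(analytic, rel=0.25)

    def test_family_resampling(self, family_values):
        adjusted, ped = family_values
        ps = build_op_pairs(adjusted, ped)
        grid = QuantileGrid(np.array([0.5]))
        f1 = bootstrap_process(ps, grid, n_boot=20, seed=2, resample_unit="family")
        f2 = bootstrap_process(ps, grid, n_boot=20, seed=2, resample_unit="family")
        np.testing.assert_array_equal(f1.slope_cov, f2.slope_cov)
        assert f1.resample_unit == "family"


class TestWeightedOls:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_weighted_ols((x, 2 * x + 1, None))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.correlation == pytest.approx(1.0)

    def test_matches_normal_equations_on_weighted_fixture(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        w = np.array([1.0, 2.0, 1.0, 0.5])
        fit = fit_weighted_ols((x, y, w))
        W = np.diag(w)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_weight_doubling_leaves_slope_and_correlation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        w = rng.uniform(0.5, 2, size=40)
        f1 = fit_weighted_ols((x, y, w))
        f2 = fit_weighted_ols((x, y, 2 * w))
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)
        assert f2.correlation == pytest.approx(f1.correlation, abs=1e-12)
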