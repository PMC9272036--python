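"""Estimator: first stage, design, selection, LRT, curves, IV filter."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from polymr import (
    CollinearityError,
    DegenerateInputError,
    InsufficientSampleError,
    PolyMR,
    build_design,
    filter_ivs_reverse,
    fit_first_stage,
    fit_polymr,
    standardize,
)
from polymr.model import reverse_filter_indices, standardized_marginal_betas


class TestStandardize:
    def test_three_point_case(self):
        z, mean, sd = standardize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (mean, sd) == (2.0, 1.0)

    def test_idempotent(self, rng):
        v = rng.standard_normal(100)
        z1 = standardize(v)[0]
        z2 = standardize(z1)[0]
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize(np.full(10, 3.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.integers(3, 50),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        ).filter(lambda v: v.std() > 1e-9)
    )
    def test_round_trip_restores_scale(self, v):
        z, mean, sd = standardize(v)
        np.testing.assert_allclose(z * sd + mean, v, rtol=1e-9, atol=1e-9)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestFirstStage:
    def test_perfect_single_instrument(self, rng):
        x = rng.standard_normal(50)
        fs = fit_first_stage(x[:, None], x)
        assert fs.beta_hat[0] == pytest.approx(1.0)
        np.testing.assert_allclose(fs.residual_exposure, 0.0, atol=1e-12)

    def test_orthogonal_exposure_gives_zero_beta(self):
        G = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        x = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to both columns
        fs = fit_first_stage(G, x)
        np.testing.assert_allclose(fs.beta_hat, 0.0, atol=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        G = rng.standard_normal((6, 2))
        x = rng.standard_normal(6)
        fs = fit_first_stage(G, x)
        oracle = np.linalg.inv(G.T @ G) @ G.T @ x
        np.testing.assert_allclose(fs.beta_hat, oracle, atol=1e-10)
        np.testing.assert_allclose(
            fs.fitted_exposure + fs.residual_exposure, x, atol=1e-12
        )
        # OLS normal equations: residual orthogonal to every instrument
        np.testing.assert_allclose(G.T @ fs.residual_exposure, 0.0, atol=1e-10)

    def test_rank_deficiency_reported(self, rng):
        g = rng.standard_normal(20)
        with pytest.raises(CollinearityError, match="rank deficient"):
            fit_first_stage(np.column_stack([g, g]), rng.standard_normal(20))

    def test_empty_and_undersized_rejected(self, rng):
        with pytest.raises(ValueError, match="empty instrument"):
            fit_first_stage(np.empty((10, 0)), rng.standard_normal(10))
        with pytest.raises(InsufficientSampleError):
            fit_first_stage(rng.standard_normal((3, 5)), rng.standard_normal(3))


class TestDesign:
    def test_control_function_design(self, rng):
        x = rng.standard_normal(10)
        fitted = rng.standard_normal(10)
        M = build_design(x, fitted, k=1, l=1)
        np.testing.assert_allclose(M[:, 0], 1.0)
        np.testing.assert_allclose(M[:, 1], x)
        np.testing.assert_allclose(M[:, 2], x - fitted)

    @pytest.mark.parametrize("k,l,ncols", [(2, 0, 3), (10, 10, 21), (3, 1, 5)])
    def test_column_counts(self, rng, k, l, ncols):
        M = build_design(rng.standard_normal(30), rng.standard_normal(30), k, l)
        assert M.shape == (30, ncols)

    def test_linear_floor_enforced(self, rng):
        with pytest.raises(ValueError, match="floor"):
            build_design(rng.standard_normal(5), rng.standard_normal(5), k=0, l=1)


class TestOlsEquivalence:
    """Dual route: the projected-QR fitter against statsmodels OLS."""

    @pytest.fixture()
    def routes(self, small_dataset):
        d = small_dataset
        res = fit_polymr(
            d.genotypes, d.exposure, d.outcome_raw, k=3, l=3, select=False,
            genotypes_standardized=True,
        )
        x_std = standardize(d.exposure)[0]
        y_std = standardize(d.outcome_raw)[0]
        fs = fit_first_stage(d.genotypes, x_std)
        M = build_design(x_std, fs.fitted_exposure, 3, 3)
        return res, sm.OLS(y_std, M).fit()

    def test_coefficients_match(self, routes):
        res, ols = routes
        np.testing.assert_allclose(res.params, ols.params, rtol=1e-8, atol=1e-12)

    def test_inference_matches(self, routes):
        res, ols = routes
        np.testing.assert_allclose(res.bse, ols.bse, rtol=1e-8)
        np.testing.assert_allclose(res.pvalues, ols.pvalues, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(
            res.coef_cov, np.asarray(ols.cov_params()), rtol=1e-8, atol=1e-15
        )

    def test_likelihood_matches(self, routes):
        res, ols = routes
        assert res.loglik_full == pytest.approx(ols.llf, rel=1e-10)

    def test_small_fixture_pvalue_formula(self, rng):
        # brute-force p values from (M'M)^-1 sigma^2 on a tiny fixture
        G = rng.standard_normal((40, 2))
        x = G @ np.array([0.5, 0.2]) + rng.standard_normal(40)
        y = 0.3 * x + rng.standard_normal(40)
        res = fit_polymr(G, x, y, k=2, l=1, select=False)
        x_std, y_std = standardize(x)[0], standardize(y)[0]
        Gs = (G - G.mean(0)) / G.std(0)
        fs = fit_first_stage(Gs, x_std)
        M = build_design(x_std, fs.fitted_exposure, 2, 1)
        beta = np.linalg.solve(M.T @ M, M.T @ y_std)
        resid = y_std - M @ beta
        sigma2 = resid @ resid / (40 - M.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(M.T @ M)))
        from scipy import stats as sps

        p = 2 * sps.t.sf(np.abs(beta / se), df=40 - M.shape[1])
        np.testing.assert_allclose(res.params, beta, rtol=1e-8)
        np.testing.assert_allclose(res.pvalues, p, rtol=1e-6, atol=1e-12)


class TestControlFunctionEquivalence:
    def test_k1_l1_equals_2sls(self, small_dataset):
        d = small_dataset
        res = fit_polymr(
            d.genotypes, d.exposure, d.outcome_raw, k=1, l=1, select=False,
            genotypes_standardized=True,
        )
        x_std = standardize(d.exposure)[0]
        y_std = standardize(d.outcome_raw)[0]
        xhat = fit_first_stage(d.genotypes, x_std).fitted_exposure
        X = np.column_stack([np.ones_like(xhat), xhat])
        slope_2sls = np.linalg.solve(X.T @ X, X.T @ y_std)[1]
        assert res.alpha[1] == pytest.approx(slope_2sls, abs=1e-8)


class TestSelectionAndInference:
    def test_quadratic_recovered_under_base_settings(self, small_fit):
        _, res = small_fit
        assert res.exposure_orders == [1, 2]
        assert res.alpha[1] == pytest.approx(0.1, abs=0.03)
        assert res.alpha[2] == pytest.approx(0.05, abs=0.03)
        assert res.nonlinearity_p < 1e-4

    def test_residual_orders_never_exceed_exposure_orders(self, small_fit):
        _, res = small_fit
        assert max(res.r) <= max(res.alpha)

    def test_null_linear_confounding_keeps_linear_only(self):
        from polymr import get_scenario, simulate_dataset

        d = simulate_dataset(
            get_scenario("linear", n_samples=8_000, n_causal_snps=20, seed=9)
        )
        res = fit_polymr(
            d.genotypes, d.exposure, d.outcome_raw, genotypes_standardized=True
        )
        assert res.exposure_orders == [1]
        assert res.nonlinearity_p == 1.0  # zero-df LRT convention
        assert res.causal_r2 == pytest.approx(0.01, abs=0.01)

    def test_lrt_statistic_matches_gaussian_rss_oracle(self, small_dataset, small_fit):
        d = small_dataset
        _, res = small_fit
        x_std = standardize(d.exposure)[0]
        y_std = standardize(d.outcome_raw)[0]
        G_sel = d.genotypes[:, res.model.instrument_indices]
        fs = fit_first_stage(G_sel, x_std)
        n = d.n_samples

        def rss(exp_orders, res_orders):
            cols = [np.ones(n)]
            cols += [x_std**j for j in exp_orders]
            cols += [fs.residual_exposure**j for j in res_orders]
            M = np.column_stack(cols)
            r = y_std - M @ np.linalg.lstsq(M, y_std, rcond=None)[0]
            return r @ r

        res_orders = sorted(res.r)
        lr_oracle = n * np.log(rss([1], res_orders) / rss(res.exposure_orders, res_orders))
        lr = 2.0 * (res.loglik_full - res.loglik_linear)
        assert lr == pytest.approx(lr_oracle, abs=1e-8)

    def test_causal_r2_is_r2_difference(self, small_dataset, small_fit):
        d = small_dataset
        _, res = small_fit
        x_std = standardize(d.exposure)[0]
        y_std = standardize(d.outcome_raw)[0]
        G_sel = d.genotypes[:, res.model.instrument_indices]
        e = fit_first_stage(G_sel, x_std).residual_exposure
        res_orders = sorted(res.r)

        def r2(exp_orders):
            cols = [np.ones(d.n_samples)]
            cols += [x_std**j for j in exp_orders]
            cols += [e**j for j in res_orders]
            return sm.OLS(y_std, np.column_stack(cols)).fit().rsquared

        oracle = r2(res.exposure_orders) - r2([])
        assert res.causal_r2 == pytest.approx(oracle, abs=1e-10)

    def test_residual_noise_orthogonal_to_design(self, small_dataset, small_fit):
        d = small_dataset
        _, res = small_fit
        x_std = standardize(d.exposure)[0]
        e = res.first_stage.residual_exposure
        tau = res.residual_noise
        for j in res.exposure_orders:
            col = x_std**j
            assert abs(col @ tau) / (np.linalg.norm(col) * np.linalg.norm(tau)) < 1e-8
        for j in sorted(res.r):
            col = e**j
            assert abs(col @ tau) / (np.linalg.norm(col) * np.linalg.norm(tau)) < 1e-8

    def test_covariance_symmetric_psd(self, small_fit):
        _, res = small_fit
        C = res.coef_cov
        assert C.shape[0] == len(res.coef_names)
        np.testing.assert_allclose(C, C.T, atol=1e-15)
        assert np.linalg.eigvalsh(C).min() > -1e-15

    def test_insufficient_sample_and_degenerate_errors(self, rng):
        G = rng.standard_normal((15, 2))
        x = G @ np.array([0.5, 0.5]) + rng.standard_normal(15)
        with pytest.raises(InsufficientSampleError):
            fit_polymr(G, x, rng.standard_normal(15), k=10, l=10, select=False)
        with pytest.raises(DegenerateInputError):
            PolyMR(rng.standard_normal(20), np.ones(20), rng.standard_normal((20, 2)))

    def test_missing_rows_dropped(self, rng):
        G = rng.standard_normal((200, 3))
        x = G @ np.array([0.4, 0.3, 0.2]) + rng.standard_normal(200)
        y = 0.2 * x + rng.standard_normal(200)
        x[5] = np.nan
        y[10] = np.nan
        model = PolyMR(y, x, G, k_max=2, l_max=2, reverse_filter=False)
        assert model.exposure_orig.shape[0] == 198
        with pytest.raises(ValueError, match="missing"):
            PolyMR(y, x, G, missing="raise")

    def test_from_dataframe_roundtrip(self, rng):
        import pandas as pd

        G = rng.standard_normal((300, 2))
        x = G @ np.array([0.6, 0.4]) + rng.standard_normal(300)
        y = 0.3 * x + rng.standard_normal(300)
        df = pd.DataFrame({"bmi": x, "ldl": y, "rs1": G[:, 0], "rs2": G[:, 1]})
        m1 = PolyMR.from_dataframe(df, exposure="bmi", outcome="ldl", k_max=2, l_max=2)
        m2 = PolyMR(y, x, G, k_max=2, l_max=2)
        r1, r2 = m1.fit(), m2.fit()
        assert r1.exposure_orders == r2.exposure_orders
        for j in r1.alpha:
            assert r1.alpha[j] == pytest.approx(r2.alpha[j], rel=1e-12)
        with pytest.raises(KeyError, match="available"):
            PolyMR.from_dataframe(df, exposure="bmi", outcome="hdl")


class TestCausalCurve:
    def test_anchored_at_mean_and_ordered(self, small_fit):
        _, res = small_fit
        mean_x = res.model.x_mean
        curve = res.causal_curve(grid=np.array([mean_x]), n_draws=1_000, seed=0)
        assert curve.estimate[0] == pytest.approx(0.0, abs=1e-12)
        full = res.causal_curve(n_draws=1_000, seed=0)
        assert full.grid.size == 99
        assert np.all(full.lower95 <= full.estimate + 1e-12)
        assert np.all(full.estimate <= full.upper95 + 1e-12)

    def test_deterministic_given_seed(self, small_fit):
        _, res = small_fit
        c1 = res.causal_curve(n_draws=500, seed=3)
        c2 = res.causal_curve(n_draws=500, seed=3)
        np.testing.assert_array_equal(c1.lower95, c2.lower95)

    def test_zero_covariance_gives_zero_width(self, small_fit):
        import copy

        _, res = small_fit
        res0 = copy.copy(res)
        res0.coef_cov = np.zeros_like(res.coef_cov)
        curve = res0.causal_curve(n_draws=500, seed=0)
        np.testing.assert_allclose(curve.upper95 - curve.lower95, 0.0, atol=1e-12)
        np.testing.assert_allclose(curve.estimate, curve.upper95, atol=1e-12)

    def test_linear_fit_gives_straight_line(self, rng):
        G = rng.standard_normal((4_000, 5))
        x = G @ (np.ones(5) * 0.3) + rng.standard_normal(4_000)
        y = 0.25 * x + rng.standard_normal(4_000)
        res = fit_polymr(G, x, y, k=2, l=2)
        assert res.exposure_orders == [1]
        curve = res.causal_curve(n_draws=500, seed=1)
        slopes = np.diff(curve.estimate) / np.diff(curve.grid)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)

    def test_min_draws_enforced(self, small_fit):
        _, res = small_fit
        with pytest.raises(ValueError, match="n_draws"):
            res.causal_curve(n_draws=50)


class TestReverseCausationFilter:
    @pytest.mark.parametrize(
        "b_exp,b_out,kept",
        [
            ([0.05], [0.08], []),               # outcome effect larger: removed
            ([0.05], [-0.05], [0]),             # boundary: retained
            ([0.1, 0.2, 0.05], [0.05, 0.3, 0.01], [0, 2]),
        ],
    )
    def test_rule(self, b_exp, b_out, kept):
        assert filter_ivs_reverse(np.array(b_exp), np.array(b_out)).tolist() == kept

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            filter_ivs_reverse(np.zeros(2), np.zeros(3))

    def test_marginal_betas_are_correlations(self, rng):
        G = rng.standard_normal((500, 4))
        t = rng.standard_normal(500)
        b = standardized_marginal_betas(G, t)
        oracle = [np.corrcoef(G[:, j], t)[0, 1] for j in range(4)]
        np.testing.assert_allclose(b, oracle, atol=1e-12)

    def test_reverse_instrument_removed_from_data(self, rng):
        n = 5_000
        g_fwd = rng.standard_normal(n)
        g_rev = rng.standard_normal(n)
        y0 = 0.5 * g_rev + rng.standard_normal(n)  # SNP acts on outcome
        x = 0.3 * g_fwd + 0.1 * y0 + rng.standard_normal(n)
        kept = reverse_filter_indices(np.column_stack([g_fwd, g_rev]), x, y0)
        assert kept.tolist() == [0]
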