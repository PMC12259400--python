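"""Estimator identities, oracle equivalences and diagnostic calibration."""

import dataclasses

import numpy as np
import pytest

import taxiv
from taxiv.exceptions import EstimationError
from taxiv.iv_estimators import _mle_nll_grad, probit_newton
from conftest import make_dataset


def _self_instrumented(ds):
    """Dataset whose only instrument is the exposure itself (X-hat = X)."""
    return dataclasses.replace(ds, Z=ds.x[:, None], z_names=["self"])


class TestFirstStage:
    def test_partial_f_equals_squared_t_single_instrument(self, calib_data):
        ds = dataclasses.replace(calib_data, Z=calib_data.Z[:, [0]],
                                 z_names=["beer_tax"])
        fs = taxiv.fit_first_stage(ds)
        t = fs.pi["beer_tax"] / fs.pi_se["beer_tax"]
        assert fs.partial_f == pytest.approx(t**2, rel=1e-9)

    def test_matches_statsmodels_ols(self, calib_data):
        import statsmodels.api as sm
        fs = taxiv.fit_first_stage(calib_data)
        W = np.column_stack([calib_data.Z, calib_data.C])
        ref = sm.OLS(calib_data.x, W).fit()
        np.testing.assert_allclose(fs.coef, ref.params, rtol=1e-9)
        np.testing.assert_allclose(fs.se, ref.bse, rtol=1e-7)

    def test_noise_instruments_give_null_f(self):
        # irrelevant instruments: partial F is F(3, n-p) with mean ~ 1
        rng = np.random.default_rng(12)
        n = 400
        fs_vals = []
        for _ in range(300):
            C = np.column_stack([np.ones(n), rng.normal(size=n)])
            ds = taxiv.AnalysisDataset(
                y=rng.integers(0, 2, n).astype(float),
                x=C @ [2.0, 0.3] + rng.normal(size=n),
                Z=rng.normal(size=(n, 3)), C=C,
                z_names=["z1", "z2", "z3"], c_names=["const", "c1"],
                state=np.zeros(n, dtype=int),
                meta={"n": n, "x_mean": 2.0, "x_sd": 1.0})
            fs_vals.append(taxiv.fit_first_stage(ds).partial_f)
        assert abs(np.mean(fs_vals) - 1.0) < 0.17

    def test_residuals_orthogonal_to_regressors(self, calib_data):
        fs = taxiv.fit_first_stage(calib_data)
        W = np.column_stack([calib_data.Z, calib_data.C])
        assert np.max(np.abs(W.T @ fs.residuals)) / calib_data.n < 1e-8

    def test_rank_deficiency_names_column(self, calib_data):
        ds = dataclasses.replace(
            calib_data, Z=np.column_stack([calib_data.Z, calib_data.Z[:, 0]]),
            z_names=calib_data.z_names + ["beer_tax_copy"])
        with pytest.raises(EstimationError, match="collinear"):
            taxiv.fit_first_stage(ds)


class TestProbit:
    def test_matches_statsmodels(self, calib_data):
        import statsmodels.api as sm
        fit = taxiv.fit_probit(calib_data)
        X = np.column_stack([calib_data.x, calib_data.C])
        ref = sm.Probit(calib_data.y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-7)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)), ref.bse, rtol=1e-4)

    def test_intercept_only_balanced_data_gives_zero(self):
        y = np.repeat([0.0, 1.0], 100)
        coef, _, _, _ = probit_newton(y, np.ones((200, 1)))
        assert coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_separation_raises(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        X = np.column_stack([x, np.ones(300)])
        y = (x > 0).astype(float)
        with pytest.raises(EstimationError, match="separation"):
            probit_newton(y, X)

    def test_null_calibration_of_naive_probit(self):
        # beta=0, rho=0: the exposure z-statistic should be null-distributed
        zs = []
        for s in range(40):
            _, _, _, ds = make_dataset(n=4000, seed=500 + s, beta=0.0, rho=0.0,
                                       negative_fraction=0.0)
            fit = taxiv.fit_probit(ds)
            zs.append(fit.beta / fit.beta_se)
        rej = np.mean(np.abs(zs) > 1.96)
        assert rej <= 0.20  # nominal 5%; generous band for 40 replicates
        assert abs(np.mean(zs)) < 3.5 / np.sqrt(40)


class TestIVProbit2SPS:
    def test_exposure_as_own_instrument_equals_plain_probit(self, calib_data):
        plain = taxiv.fit_probit(calib_data)
        sub = taxiv.fit_iv_probit_2sps(_self_instrumented(calib_data))
        np.testing.assert_allclose(sub.coef, plain.coef, atol=1e-10)

    def test_agrees_with_probit_when_exogenous(self):
        _, _, _, ds = make_dataset(n=20000, seed=21, rho=0.0,
                                   negative_fraction=0.0)
        plain = taxiv.fit_probit(ds)
        sub = taxiv.fit_iv_probit_2sps(ds)
        # both consistent under rho=0; IV is noisier, compare at 3.5 IV SEs
        assert abs(sub.beta - plain.beta) < 3.5 * sub.beta_se

    def test_covariance_flagged_naive(self, calib_data):
        assert taxiv.fit_iv_probit_2sps(calib_data).cov_is_naive


class TestIVProbitMLE:
    def test_gradient_matches_numeric(self, calib_data):
        ds = calib_data
        V = np.column_stack([ds.x, ds.C])
        W = np.column_stack([ds.Z, ds.C])
        q = 2 * ds.y - 1
        rng = np.random.default_rng(3)
        fit = taxiv.fit_probit(ds)
        fs = taxiv.fit_first_stage(ds)
        theta = np.concatenate([fit.coef * 0.9, fs.coef * 0.95, [0.15, 0.03]])
        _, g = _mle_nll_grad(theta, ds.y, q, V, W, None)
        num = np.zeros_like(theta)
        for j in range(theta.size):
            h = 1e-6 * (1 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            num[j] = (_mle_nll_grad(tp, ds.y, q, V, W, None)[0]
                      - _mle_nll_grad(tm, ds.y, q, V, W, None)[0]) / (2 * h)
        np.testing.assert_allclose(g, num, rtol=2e-4, atol=1e-8)

    def test_rho_fixed_at_zero_factorises(self, calib_data):
        plain = taxiv.fit_probit(calib_data)
        fs = taxiv.fit_first_stage(calib_data)
        m0 = taxiv.fit_iv_probit_mle(calib_data, fix_rho=0.0, gtol=1e-10,
                                     compute_cov=False)
        np.testing.assert_allclose(m0.coef, plain.coef, atol=1e-6)
        p_v = len(m0.coef)
        np.testing.assert_allclose(m0.theta[p_v:p_v + len(fs.coef)], fs.coef,
                                   atol=1e-6)
        assert m0.sigma == pytest.approx(
            float(np.sqrt(fs.residuals @ fs.residuals / calib_data.n)), abs=1e-8)

    def test_loglik_at_optimum_beats_factorised_solution(self, calib_data):
        full = taxiv.fit_iv_probit_mle(calib_data, compute_cov=False)
        m0 = taxiv.fit_iv_probit_mle(calib_data, fix_rho=0.0, compute_cov=False)
        assert full.loglik >= m0.loglik - 1e-8

    def test_recovers_rho(self):
        _, _, _, ds = make_dataset(n=30000, seed=23, rho=0.3,
                                   negative_fraction=0.0)
        fit = taxiv.fit_iv_probit_mle(ds)
        se_rho = fit.se_atanh_rho  # atanh is ~identity near 0.3
        assert abs(fit.rho - 0.3) < 3 * se_rho + 0.02

    def test_wald_power_under_strong_endogeneity(self):
        # rho=0.3 at n=50k: the exogeneity test must reject at p < 0.001
        pvals = []
        for s in range(5):
            _, _, _, ds = make_dataset(n=50000, seed=600 + s, rho=0.3,
                                       beta=0.0, negative_fraction=0.0)
            fit = taxiv.fit_iv_probit_mle(ds)
            pvals.append(taxiv.wald_exogeneity(fit).pvalue)
        assert all(p < 1e-3 for p in pvals)

    def test_wald_zero_rho_is_zero_statistic(self, calib_data):
        fit = taxiv.fit_iv_probit_mle(calib_data)
        fit2 = dataclasses.replace(fit, atanh_rho=0.0)
        res = taxiv.wald_exogeneity(fit2)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_wald_requires_mle_fit(self, calib_data):
        with pytest.raises(EstimationError):
            taxiv.wald_exogeneity(taxiv.fit_probit(calib_data))


class TestEquivariance:
    def test_tax_rescaling_leaves_estimates_invariant(self, calib_data):
        scaled = dataclasses.replace(calib_data, Z=calib_data.Z.copy())
        scaled.Z[:, 0] *= 10.0
        fa, fb = taxiv.fit_first_stage(calib_data), taxiv.fit_first_stage(scaled)
        assert fb.pi["beer_tax"] == pytest.approx(fa.pi["beer_tax"] / 10, rel=1e-9)
        assert fb.partial_f == pytest.approx(fa.partial_f, rel=1e-9)
        la, lb = taxiv.fit_2sls_lpm(calib_data), taxiv.fit_2sls_lpm(scaled)
        assert lb.coef == pytest.approx(la.coef, rel=1e-9)
        ma = taxiv.fit_iv_probit_mle(calib_data, compute_cov=False)
        mb = taxiv.fit_iv_probit_mle(scaled, compute_cov=False)
        assert mb.beta == pytest.approx(ma.beta, abs=5e-5)
        ra = taxiv.standardised_ratio(ma, calib_data)
        rb = taxiv.standardised_ratio(mb, scaled)
        assert rb == pytest.approx(ra, abs=1e-4)


class Test2SLS:
    def test_exposure_as_own_instrument_equals_ols(self, calib_data):
        ds = _self_instrumented(calib_data)
        lin = taxiv.fit_2sls_lpm(ds, instrument_set=["self"])
        Xf = np.column_stack([calib_data.x, calib_data.C])
        ols = np.linalg.lstsq(Xf, calib_data.y, rcond=None)[0]
        assert lin.coef == pytest.approx(ols[0], abs=1e-10)

    def test_just_identified_equals_covariance_ratio(self, calib_data):
        ds = dataclasses.replace(calib_data, Z=calib_data.Z[:, [0]],
                                 z_names=["beer_tax"])
        lin = taxiv.fit_2sls_lpm(ds)

        def resid(v):
            coef, *_ = np.linalg.lstsq(calib_data.C, v, rcond=None)
            return v - calib_data.C @ coef

        z, x, y = resid(ds.Z[:, 0]), resid(ds.x), resid(ds.y)
        assert lin.coef == pytest.approx(float(z @ y) / float(z @ x), rel=1e-10)

    def test_matches_bruteforce_matrix_algebra_small_n(self):
        rng = np.random.default_rng(7)
        n = 40
        Z = rng.normal(size=(n, 2))
        C = np.column_stack([np.ones(n), rng.normal(size=n)])
        x = Z @ [0.5, -0.3] + C @ [0.2, 0.4] + rng.normal(size=n)
        y = 0.7 * x + C @ [0.1, -0.2] + rng.normal(size=n)
        ds = taxiv.AnalysisDataset(
            y=y, x=x, Z=Z, C=C, z_names=["z1", "z2"], c_names=["const", "c1"],
            state=np.zeros(n, dtype=int),
            meta={"n": n, "x_mean": x.mean(), "x_sd": x.std(ddof=1)})
        lin = taxiv.fit_2sls_lpm(ds)
        W = np.column_stack([Z, C])
        Xf = np.column_stack([x, C])
        P = W @ np.linalg.inv(W.T @ W) @ W.T
        brute = np.linalg.inv(Xf.T @ P @ Xf) @ Xf.T @ P @ y
        assert lin.coef == pytest.approx(brute[0], abs=1e-10)

    def test_matches_statsmodels_sandbox(self, calib_data):
        from statsmodels.sandbox.regression.gmm import IV2SLS
        lin = taxiv.fit_2sls_lpm(calib_data)
        W = np.column_stack([calib_data.Z, calib_data.C])
        Xf = np.column_stack([calib_data.x, calib_data.C])
        ref = IV2SLS(calib_data.y, Xf, W).fit()
        assert lin.coef == pytest.approx(ref.params[0], abs=1e-10)

    def test_empty_instrument_set_rejected(self, calib_data):
        with pytest.raises(EstimationError):
            taxiv.fit_2sls_lpm(calib_data, instrument_set=[])
        with pytest.raises(EstimationError, match="unknown"):
            taxiv.fit_2sls_lpm(calib_data, instrument_set=["soda_tax"])

    def test_ci_contains_point(self, calib_data):
        lin = taxiv.fit_2sls_lpm(calib_data)
        lo, hi = lin.conf_int()
        assert lo <= lin.coef <= hi
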