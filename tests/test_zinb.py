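import dataclasses

import numpy as np
import pandas as pd
import pytest

import airpanel as ap
from airpanel.zinb import _AGHEngine

from conftest import make_toy_design, small_study_config

# log pmf of NB(y=3 | mu=2, theta=1.5), evaluated symbolically to 30 digits
NB_LOGPMF_3_2_15 = -2.16703481513744103734


class TestPMFs:
    def test_nb_closed_forms(self):
        assert ap.nb_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)
        assert ap.nb_log_pmf(3, 2.0, 1.5) == pytest.approx(NB_LOGPMF_3_2_15, abs=1e-12)

    def test_nb_poisson_limit(self):
        pois = 2 * np.log(1.0) - 1.0 - np.log(2.0)  # Poisson(1) at y=2
        assert ap.nb_log_pmf(2, 1.0, 1e8) == pytest.approx(pois, abs=1e-4)

    def test_nb_large_count_no_overflow(self):
        val = ap.nb_log_pmf(10**6, 1e6, 2.0)
        assert np.isfinite(val)

    def test_nb_domain_errors(self):
        with pytest.raises(ap.FitError):
            ap.nb_log_pmf(1, -1.0, 1.0)
        with pytest.raises(ap.FitError):
            ap.nb_log_pmf(1, 1.0, 0.0)

    def test_zinb_reduces_to_nb_at_pi_zero(self):
        y = np.arange(6)
        assert np.allclose(
            ap.zinb_log_pmf(y, 1.7, 2.2, 0.0), ap.nb_log_pmf(y, 1.7, 2.2), atol=1e-12
        )

    def test_zinb_closed_forms(self):
        assert ap.zinb_log_pmf(0, 1.0, 1.0, 0.3) == pytest.approx(np.log(0.65), abs=1e-12)
        assert ap.zinb_log_pmf(2, 1.0, 1.0, 0.3) == pytest.approx(
            np.log(0.7) + ap.nb_log_pmf(2, 1.0, 1.0), abs=1e-12
        )

    def test_zinb_pi_domain(self):
        with pytest.raises(ap.FitError):
            ap.zinb_log_pmf(0, 1.0, 1.0, 1.0)

    def test_zinb_sums_to_one(self):
        ks = np.arange(0, 500)
        total = np.exp(ap.zinb_log_pmf(ks, 3.0, 0.8, 0.25)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)


class TestMarginalLoglik:
    def test_sigma_zero_reduction_is_exact(self, toy_design):
        beta = np.array([0.3, 0.2])
        spec = ap.ZINBMixedSpec(design=toy_design)
        ll = ap.marginal_loglik(beta, -1.2, np.log(1.3), np.log(1e-7), spec)
        mu = np.exp(toy_design.X.to_numpy() @ beta)
        direct = ap.zinb_log_pmf(
            toy_design.y, mu, 1.3, 1 / (1 + np.exp(1.2))
        ).sum()
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_agrees_with_dense_bruteforce_integration(self, toy_design):
        beta, g0, theta, sig = np.array([0.3, 0.2]), -1.2, 1.3, 0.4
        spec = ap.ZINBMixedSpec(design=toy_design)
        ll = ap.marginal_loglik(beta, g0, np.log(theta), np.log(sig), spec)
        mu = np.exp(toy_design.X.to_numpy() @ beta)
        pi = 1 / (1 + np.exp(-g0))
        grid = np.linspace(-10 * sig, 10 * sig, 100_001)
        phi = np.exp(-0.5 * (grid / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        total = 0.0
        for i in range(toy_design.n_units):
            idx = toy_design.groups == i
            cond = np.array(
                [
                    ap.zinb_log_pmf(toy_design.y[idx], mu[idx] * np.exp(b), theta, pi).sum()
                    for b in grid
                ]
            )
            total += np.log(np.trapezoid(np.exp(cond) * phi, grid))
        assert abs(ll - total) < 1e-6

    def test_quadrature_self_convergence(self, toy_design):
        beta = np.array([0.3, 0.2])
        lls = {
            k: ap.marginal_loglik(
                beta, -1.2, np.log(1.3), np.log(0.4),
                ap.ZINBMixedSpec(design=toy_design, n_nodes=k),
            )
            for k in (7, 15, 31)
        }
        assert abs(lls[15] - lls[7]) < 1e-6
        assert abs(lls[31] - lls[15]) < 1e-8

    def test_analytic_gradient_matches_numeric(self):
        dm = make_toy_design(n_units=4, n_days=8, seed=3)
        eng = _AGHEngine(dm, 15)
        x0 = np.array([0.2, -0.3, -1.0, np.log(1.4), np.log(0.3)])
        _, g = eng.loglik_grad(x0[:2], x0[2], x0[3], x0[4])
        analytic = np.concatenate([g[0], [g[1], g[2], g[3]]])
        numeric = np.zeros_like(analytic)
        for j in range(len(x0)):
            h = 1e-6 * max(1, abs(x0[j]))
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            lp, _ = eng.loglik_grad(xp[:2], xp[2], xp[3], xp[4], want_grad=False)
            lm, _ = eng.loglik_grad(xm[:2], xm[2], xm[3], xm[4], want_grad=False)
            numeric[j] = (lp - lm) / (2 * h)
        assert np.abs(analytic - numeric).max() < 1e-6

    def test_invalid_spec_rejected(self, toy_design):
        with pytest.raises(ap.FitError):
            ap.ZINBMixedSpec(design=toy_design, n_nodes=4)
        with pytest.raises(ap.FitError):
            ap.ZINBMixedSpec(design=toy_design, n_nodes=10)
        with pytest.raises(ap.FitError):
            ap.ZINBMixedSpec(design=toy_design, fixed={"beta": 1.0})

    def test_beta_label_alignment(self, toy_design):
        spec = ap.ZINBMixedSpec(design=toy_design)
        as_series = pd.Series({"x1": 0.2, "const": 0.3})  # order scrambled
        a = ap.marginal_loglik(as_series, -1.0, 0.0, np.log(0.3), spec)
        b = ap.marginal_loglik(np.array([0.3, 0.2]), -1.0, 0.0, np.log(0.3), spec)
        assert a == pytest.approx(b, abs=1e-12)
        with pytest.raises(ap.FitError):
            ap.marginal_loglik(pd.Series({"x1": 0.2}), -1.0, 0.0, 0.0, spec)


class TestFit:
    def test_structural_errors(self, toy_design):
        one_unit = dataclasses.replace(
            toy_design,
            groups=np.zeros(toy_design.n_obs, dtype=int),
            unit_ids=np.array(["u0"]),
        )
        with pytest.raises(ap.FitError, match="2 units"):
            ap.fit_zinb_mixed(ap.ZINBMixedSpec(design=one_unit))
        all_zero = dataclasses.replace(toy_design, y=np.zeros(toy_design.n_obs, dtype=int))
        with pytest.raises(ap.FitError, match="zero"):
            ap.fit_zinb_mixed(ap.ZINBMixedSpec(design=all_zero))

    def test_covariate_rescaling_invariance(self, desk_small_panel):
        """Multiplying a covariate by c divides its coefficient by c and
        leaves the maximized log-likelihood unchanged."""
        panel = desk_small_panel
        dm = ap.build_design(panel, ap.decompose(panel, "pm10"), ap.LagSpec("lag0"),
                             "asthma_copd_urti", "all_ages")
        fit1 = ap.fit_zinb_mixed(ap.ZINBMixedSpec(design=dm))
        c = 10.0
        X2 = dm.X.copy()
        X2["pm10_short"] = X2["pm10_short"] * c
        dm2 = dataclasses.replace(dm, X=X2)
        fit2 = ap.fit_zinb_mixed(ap.ZINBMixedSpec(design=dm2))
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-4)
        assert fit2.beta["pm10_short"] == pytest.approx(
            fit1.beta["pm10_short"] / c, rel=1e-3
        )

    def test_fit_quality_on_small_panel(self, desk_small_panel, desk_small_design,
                                        desk_small_fit):
        """Single-fit sanity: converged, truth within a few Wald SEs, and
        the MLE dominates the generating parameters."""
        from airpanel.design import trend_df_for
        from airpanel.simulate import _params_to_beta

        fit = desk_small_fit
        assert fit.converged
        true = desk_small_panel.true_params[("asthma_copd_urti", "all_ages")]
        b, se = fit.beta["pm10_short"], fit.se("pm10_short")
        assert abs(b - true.beta_short) < 4 * se
        beta_t = _params_to_beta(
            true, desk_small_design.X.columns,
            trend_df_for(desk_small_panel.study_start, desk_small_panel.study_end),
        )
        spec = ap.ZINBMixedSpec(design=desk_small_design)
        ll_true = ap.marginal_loglik(
            beta_t, true.gamma0, np.log(true.theta), np.log(true.sigma_b), spec
        )
        assert fit.loglik >= ll_true

    def test_vcov_is_symmetric_psd(self, desk_small_fit):
        V = desk_small_fit.vcov.to_numpy()
        assert np.allclose(V, V.T, atol=1e-10)
        assert np.linalg.eigvalsh(V).min() > -1e-8
        # every coefficient addressable by design label
        for label in desk_small_fit.beta.index:
            assert np.isfinite(desk_small_fit.se(label))

    def test_sigma_zero_data_hits_boundary_and_matches_flat_oracle(self):
        """Data generated without a random intercept: sigma_b estimates at
        its floor and fixed effects match the independent no-random-effect
        ZINB fit (statsmodels) to 1e-3."""
        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        cfg = small_study_config(n_units=20, months=6, seed=13, sigma_b=0.0,
                                 gamma0=-1.8)
        panel = ap.generate_study(cfg)
        dm = ap.build_design(panel, ap.decompose(panel, "pm10"), ap.LagSpec("lag0"),
                             "asthma_copd_urti", "all_ages")
        keep = ["const", "pm10_short", "pm10_long", "dow_Tue", "dow_Wed",
                "dow_Thu", "dow_Fri", "pct_elderly", "deprivation"]
        dm = dataclasses.replace(dm, X=dm.X[keep])
        fit = ap.fit_zinb_mixed(ap.ZINBMixedSpec(design=dm))
        assert fit.sigma_b < 1e-3  # flat region: indistinguishable from zero
        assert "log_sigma_b" in fit.boundary
        sm_fit = ZeroInflatedNegativeBinomialP(
            dm.y, dm.X.to_numpy(), exog_infl=np.ones((dm.n_obs, 1)), p=2
        ).fit(method="bfgs", maxiter=500, disp=0)
        sm_beta = sm_fit.params[1:-1]
        assert np.abs(fit.beta.to_numpy() - sm_beta).max() < 1e-3

    def test_predict_mean(self, desk_small_fit, desk_small_design):
        fit, dm = desk_small_fit, desk_small_design
        pred = ap.predict_mean(fit, dm.X, kind="population")
        assert pred.shape == (dm.n_obs,)
        # well-specified fit: mean prediction tracks mean observed count
        assert np.mean(pred) == pytest.approx(np.mean(dm.y), rel=0.05)
        # conditional mean differs by exactly the lognormal factor
        cond = ap.predict_mean(fit, dm.X, kind="conditional")
        assert np.allclose(pred, cond * np.exp(0.5 * fit.sigma_b**2))
        # label mismatch is an error
        with pytest.raises(ap.FitError):
            ap.predict_mean(fit, dm.X.rename(columns={"const": "intercept"}))

    def test_predict_mean_ignores_zero_coefficient_covariates(self, desk_small_fit,
                                                              desk_small_design):
        fit = dataclasses.replace(desk_small_fit)
        fit.beta = desk_small_fit.beta.copy()
        fit.beta["pm10_long"] = 0.0
        X2 = desk_small_design.X.copy()
        X2["pm10_long"] = X2["pm10_long"] * 2.0
        a = ap.predict_mean(fit, desk_small_design.X)
        b = ap.predict_mean(fit, X2)
        assert np.allclose(a, b)
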