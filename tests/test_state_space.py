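import numpy as np
import pandas as pd
import pytest
from scipy import special

import statsmodels.api as sm

from fluctsel.barcode import CalibrationMap
from fluctsel.environment import TreatmentSpec
from fluctsel.state_space import (
    DEFAULT_VIF,
    FitResult,
    LineObs,
    ModelSpec,
    SELECTED_MODEL,
    bootstrap_latent_sd,
    default_start,
    fit,
    laplace_marginal_loglik_single,
    lines_from_frames,
    lr_test,
    marginal_loglik,
    mean_selection_ci,
    quadrature_marginal_loglik,
    wald_test,
)
from fluctsel.synthetic import ExperimentConfig, generate_experiment

#: prior spread of a single latent after one average transfer of process
#: noise at the constant-treatment selection variance
ONE_TRANSFER_PRIOR_VAR = DEFAULT_VIF * 0.0196 * 3.5


class TestLaplaceAccuracy:
    @pytest.mark.parametrize("depth", [5, 50, 500])
    @pytest.mark.parametrize("p", [0.05, 0.5, 0.95])
    def test_laplace_close_to_quadrature(self, depth, p):
        """Laplace within 1e-2 of 41-node adaptive Gauss-Hermite on scalar latents."""
        mu = special.logit(p)
        n = round(depth * p)
        m = round(depth * (0.19 + 0.79 * p))
        lap = laplace_marginal_loglik_single(n, depth, m, depth, mu, ONE_TRANSFER_PRIOR_VAR)
        quad = quadrature_marginal_loglik(n, depth, m, depth, mu, ONE_TRANSFER_PRIOR_VAR)
        assert abs(lap - quad) < 1e-2

    def test_gaussian_limit_is_exact(self):
        """With no observations the marginal likelihood integrates to one."""
        line = LineObs("empty", [21.0], [0], [0], [0], [0], 0.0, 1.0, 0.0)
        assert line.n_obs == 0


class TestMarginalLoglik:
    def _two_lines(self):
        days = np.array([21.0, 49.0, 129.0])
        l1 = LineObs("a", days, [50, 80, 120], [200, 200, 200], [90, 110, 140], [300, 300, 300], 0.0, 1.0, 0.0)
        l2 = LineObs("b", days, [20, 30, 45], [150, 150, 150], [60, 70, 90], [250, 250, 250], 0.0, 1.0, 0.9)
        return [l1, l2]

    def _params(self):
        return {
            "theta_intercept": 0.01,
            "theta_mu": 0.0,
            "theta_mu2": 0.0,
            "theta_sigma2": -0.02,
            "theta_rho2": 0.03,
            "psi0_mean": -1.0,
            "v_psi0": 0.05,
            "sigma0_sq": 0.02,
            "sigma1_sq": 0.1,
        }

    def test_zero_depth_line_contributes_nothing(self):
        lines = self._two_lines()
        ll_base = marginal_loglik(self._params(), lines)
        empty = LineObs("c", [21.0, 49.0], [0, 0], [0, 0], [0, 0], [0, 0], 0.0, 1.0, 0.0)
        assert empty.n_obs == 0
        ll_with = marginal_loglik(self._params(), lines + [empty] if empty.n_obs else lines)
        assert ll_with == pytest.approx(ll_base)

    def test_single_timepoint_matches_quadrature(self):
        p = self._params()
        line = LineObs("a", [21.0], [6], [10], [7], [10], 0.0, 1.0, 0.0)
        ll = marginal_loglik(p, [line])
        s_bar = p["theta_intercept"] + p["theta_sigma2"]
        prior_mean = p["psi0_mean"] + s_bar * 21.0
        prior_var = p["v_psi0"] + DEFAULT_VIF * p["sigma1_sq"] * 21.0
        quad = quadrature_marginal_loglik(6, 10, 7, 10, prior_mean, prior_var)
        assert ll == pytest.approx(quad, abs=5e-2)

    def test_invalid_calibration_rejected(self):
        params = dict(self._params())
        params["alpha"], params["beta"] = 0.7, 0.6  # exceeds 1 at p = 1
        with pytest.raises(ValueError):
            marginal_loglik(params, self._two_lines(), model=ModelSpec(estimate_calibration=True))


class TestDegenerateNoiseLimit:
    def test_matches_logistic_regression(self):
        """Zero process noise + huge depth: theta equals GLM logistic slopes.

        With all variance components at (effectively) zero the latent is
        deterministic and the model is an ordinary binomial logistic
        regression of allele counts on time x environment covariates.
        """
        rng = np.random.default_rng(8)
        days = np.array([21.0, 49.0, 73.0, 129.0])
        truth = {"psi0": -1.0, "a": 0.05, "b": -0.03, "c": -0.01}
        rows_counts, rows_treat = [], []
        for i, mu in enumerate((-1.6, 0.0, 0.8)):
            for rep in range(3):
                lid = f"L{i}{rep}"
                s = truth["a"] + truth["b"] * mu + truth["c"] * mu * mu
                psi = truth["psi0"] + s * days
                n = rng.binomial(100_000, special.expit(psi))
                for d, nn in zip(days, n):
                    rows_counts.append((lid, 0, d, "chloroplast", nn, 100_000))
                    rows_counts.append((lid, 0, d, "its2", 0, 0))
                rows_treat.append((lid, 2.4 + mu, 0.0, 0.0))
        counts = pd.DataFrame(rows_counts, columns=["line_id", "transfer", "day", "locus", "n_C", "N_total"])
        treat = pd.DataFrame(rows_treat, columns=["line_id", "mean", "variance", "autocorrelation"])
        lines = lines_from_frames(counts, treat)
        model = ModelSpec(mean_terms=("intercept", "mu", "mu2"), variance_structure="pooled")
        res = fit(lines, model=model, compute_cov=False)

        # GLM oracle on the same counts
        X, y = [], []
        for ln in lines:
            for d, n_, N_ in zip(ln.days, ln.n, ln.N):
                X.append([1.0, d, d * ln.mu, d * ln.mu**2])
                y.append([n_, N_ - n_])
        glm = sm.GLM(np.array(y), np.array(X), family=sm.families.Binomial()).fit()
        psi0_g, a_g, b_g, c_g = glm.params
        assert res.params["psi0_mean"] == pytest.approx(psi0_g, abs=1e-3)
        assert res.params["theta_intercept"] == pytest.approx(a_g, abs=1e-3)
        assert res.params["theta_mu"] == pytest.approx(b_g, abs=1e-3)
        assert res.params["theta_mu2"] == pytest.approx(c_g, abs=1e-3)
        # and the variance component collapses to its floor
        assert res.params["sigma_sq"] < 1e-4


class TestLatentShrinkage:
    def _fit_latent(self, depth):
        params = {
            "theta_intercept": 0.0,
            "psi0_mean": -2.0,
            "v_psi0": 0.5,
            "sigma0_sq": 0.01,
            "sigma1_sq": 0.01,
        }
        model = ModelSpec(mean_terms=("intercept",))
        n = round(depth * 0.8)
        line = LineObs("a", [21.0], [n], [depth], [0], [0], 0.0, 1.0, 0.0)
        _, latents = marginal_loglik(params, [line], model=model, return_latents=True)
        return latents[0][2][0]

    def test_no_data_returns_prior_mean(self):
        assert self._fit_latent(1) != self._fit_latent(100000)
        psi_small = self._fit_latent(1)
        # depth 1: mode pulled near the process mean -2.0
        assert abs(psi_small - (-2.0)) < 1.5

    def test_infinite_depth_returns_empirical_logit(self):
        psi_big = self._fit_latent(1_000_000)
        assert psi_big == pytest.approx(special.logit(0.8), abs=1e-3)


@pytest.fixture(scope="module")
def small_fit():
    cfg = ExperimentConfig(
        treatments=[
            (TreatmentSpec(2.4, 0.0, 0.0, constant=True), 4),
            (TreatmentSpec(2.4, 1.0, 0.0), 8),
            (TreatmentSpec(2.4, 1.0, 0.9), 8),
        ],
        attrition_fluct=0.0,
        attrition_const=0.0,
    )
    exp = generate_experiment(cfg, seed=42)
    lines = lines_from_frames(exp.counts, exp.treatments)
    model = ModelSpec(mean_terms=("intercept", "sigma2", "rho2"))
    return lines, model, fit(lines, model=model)


class TestFitMachineryOnSmallExperiment:
    def test_converged_with_finite_se(self, small_fit):
        _, _, res = small_fit
        assert res.converged
        for key in ("theta_intercept", "theta_sigma2", "theta_rho2", "sigma1_sq"):
            assert np.isfinite(res.se[key]) and res.se[key] > 0

    def test_refit_from_truth_start_reaches_same_optimum(self, small_fit, published_truth):
        lines, model, res = small_fit
        start = {
            "theta_intercept": published_truth["theta_intercept"],
            "theta_sigma2": published_truth["theta_sigma2"],
            "theta_rho2": published_truth["theta_rho2"],
            "psi0_mean": published_truth["psi0_mean"],
            "v_psi0": published_truth["v_psi0"],
            "sigma0_sq": published_truth["sigma0_sq"],
            "sigma1_sq": published_truth["sigma1_sq"],
        }
        res2 = fit(lines, model=model, start=start, compute_cov=False)
        assert res2.loglik == pytest.approx(res.loglik, abs=0.05)
        assert res2.params["theta_rho2"] == pytest.approx(res.params["theta_rho2"], abs=5e-3)

    def test_likelihood_monotone_in_model_size(self, small_fit):
        """Adding a free parameter never decreases the maximized log-likelihood."""
        lines, model, res = small_fit
        reduced = ModelSpec(mean_terms=("intercept", "sigma2"))
        res_red = fit(lines, model=reduced, compute_cov=False)
        assert res.loglik >= res_red.loglik - 1e-3
        t = lr_test(res, res_red)
        assert t.statistic >= 0.0
        assert t.df == 1

    def test_latents_cover_observed_timepoints(self, small_fit):
        lines, _, res = small_fit
        n_obs = sum(ln.n_obs for ln in lines)
        assert len(res.latents) == n_obs
        assert np.all(np.isfinite(res.latents["psi_mode"]))

    def test_summary_table_shape(self, small_fit):
        _, model, res = small_fit
        tab = res.summary()
        assert list(tab.columns) == ["term", "estimate", "se", "p_value"]
        assert len(tab) == model.n_free()


class TestWaldTest:
    def _dummy_fit(self):
        names = ["theta_intercept", "theta_sigma2", "theta_rho2"]
        cov = pd.DataFrame(np.diag([0.01**2, 0.02**2, 0.03**2]), index=names, columns=names)
        return FitResult(
            model=ModelSpec(mean_terms=("intercept", "sigma2", "rho2")),
            params={"theta_intercept": 0.0, "theta_sigma2": 0.0392, "theta_rho2": 0.05},
            se={n: np.sqrt(cov.loc[n, n]) for n in names},
            cov=cov,
            loglik=0.0,
            converged=True,
            message="",
            n_lines=1,
            n_obs=1,
            latents=pd.DataFrame(columns=["line_id", "day", "psi_mode"]),
            calibration=CalibrationMap(0.19, 0.79),
        )

    def test_zero_estimate_p_one(self):
        t = wald_test(self._dummy_fit(), "theta_intercept")
        assert t.p_value == pytest.approx(1.0)

    def test_1p96_se_p_05(self):
        t = wald_test(self._dummy_fit(), "theta_sigma2")  # 0.0392 = 1.96 * 0.02
        assert t.p_value == pytest.approx(0.05, abs=1e-3)

    def test_contrast_consistent_with_scalar(self):
        f = self._dummy_fit()
        assert wald_test(f, {"theta_rho2": 1.0}).p_value == pytest.approx(
            wald_test(f, "theta_rho2").p_value
        )


class TestMeanSelectionCI:
    def _fit_with_cov(self, published_truth):
        names = ["theta_intercept", "theta_sigma2", "theta_rho2"]
        A = np.array([[1.0, 0.3, 0.1], [0.3, 1.5, -0.2], [0.1, -0.2, 2.0]]) * 1e-4
        cov = pd.DataFrame(A, index=names, columns=names)
        params = {
            "theta_intercept": published_truth["theta_intercept"],
            "theta_sigma2": published_truth["theta_sigma2"],
            "theta_rho2": published_truth["theta_rho2"],
        }
        return FitResult(
            model=ModelSpec(mean_terms=("intercept", "sigma2", "rho2")),
            params=params,
            se={},
            cov=cov,
            loglik=0.0,
            converged=True,
            message="",
            n_lines=1,
            n_obs=1,
            latents=pd.DataFrame(columns=["line_id", "day", "psi_mode"]),
            calibration=CalibrationMap(0.19, 0.79),
        )

    def test_point_estimate_at_zero_autocorrelation(self, published_truth):
        est, lo, hi = mean_selection_ci(self._fit_with_cov(published_truth), 0.0)
        assert est == pytest.approx(0.0927 - 0.0765, abs=1e-6)
        assert lo < est < hi

    def test_symmetric_in_rho_sign(self, published_truth):
        f = self._fit_with_cov(published_truth)
        assert mean_selection_ci(f, 0.5) == mean_selection_ci(f, -0.5)

    def test_delta_se_matches_parametric_bootstrap(self, published_truth, rng):
        """Delta-method SE within 10% of a draw-from-covariance bootstrap SE."""
        f = self._fit_with_cov(published_truth)
        est, lo, hi = mean_selection_ci(f, 0.9)
        delta_se = (hi - est) / 1.959963984540054
        names = list(f.cov.index)
        draws = rng.multivariate_normal(
            [f.params[n] for n in names], f.cov.to_numpy(), size=1000
        )
        w = np.array([1.0, 1.0, 0.81])
        boot_se = (draws @ w).std(ddof=1)
        assert delta_se == pytest.approx(boot_se, rel=0.10)


class TestBootstrapLatentSd:
    def test_identical_lines_zero_sd(self):
        rows = [(f"L{i}", d, -1.5) for i in range(6) for d in (21.0, 49.0)]
        lat = pd.DataFrame(rows, columns=["line_id", "day", "psi_mode"])
        out = bootstrap_latent_sd(lat, B=200, seed=0)
        assert np.allclose(out["psi_sd"], 0.0)

    def test_gaussian_latents_match_analytic_sd(self, rng):
        true_sd = 1.7
        rows = [
            (f"L{i}", d, rng.normal(0, true_sd))
            for i in range(200)
            for d in (21.0, 49.0, 129.0)
        ]
        lat = pd.DataFrame(rows, columns=["line_id", "day", "psi_mode"])
        out = bootstrap_latent_sd(lat, B=2000, seed=1)
        assert np.allclose(out["psi_sd"], true_sd, rtol=0.10)

    def test_subtract_mean_removes_between_group_spread(self, rng):
        rows = []
        for g, center in (("hi", 5.0), ("lo", -5.0)):
            for i in range(40):
                rows.append((f"{g}{i}", 21.0, center + rng.normal(0, 0.5)))
        lat = pd.DataFrame(rows, columns=["line_id", "day", "psi_mode"])
        labels = {lid: lid[:2] for lid in lat["line_id"]}
        raw = bootstrap_latent_sd(lat, B=300, seed=2)
        centered = bootstrap_latent_sd(lat, B=300, seed=2, subtract_mean=True, group_labels=labels)
        assert raw["psi_sd"][0] > 3.0
        assert centered["psi_sd"][0] == pytest.approx(0.5, abs=0.15)

    def test_minimum_replicates_enforced(self):
        lat = pd.DataFrame([("a", 1.0, 0.0)], columns=["line_id", "day", "psi_mode"])
        with pytest.raises(ValueError):
            bootstrap_latent_sd(lat, B=10)
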