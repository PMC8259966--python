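import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fluctsel.environment import TreatmentSpec, simulate_ar1
from fluctsel.reaction_norms import (
    ReactionNormBi,
    ReactionNormUni,
    ToleranceCurvePair,
    bivariate_mean_selection,
    bivariate_selection_at,
    bivariate_var_selection,
    bivariate_var_selection_exact,
    mean_selection_gaussian,
    optimum_and_max,
    predict_trajectory,
    selection_at,
    selection_distribution,
    selection_from_tolerance,
    var_selection_gaussian,
    variance_inflation_factor,
)

coef = st.floats(-0.5, 0.5, allow_nan=False)


class TestSelectionAt:
    def test_published_norm_values(self, fitted_norm):
        assert selection_at(fitted_norm, 0.0) == pytest.approx(0.0927)
        # advantage nearly vanishes towards 3.2 M (deviation 0.8)
        assert selection_at(fitted_norm, 0.8) == pytest.approx(-0.0094, abs=5e-4)

    def test_linear_norm_constant_in_E(self):
        rn = ReactionNormUni(0.3, 0.0, 0.0)
        assert np.all(selection_at(rn, np.linspace(-2, 2, 9)) == 0.3)


class TestOptimum:
    def test_published_norm_optimum(self, fitted_norm):
        opt, smax = optimum_and_max(fitted_norm)
        assert opt == pytest.approx(1.0, abs=0.05)
        assert smax == pytest.approx(0.16, abs=0.005)

    def test_symmetric_norm_peaks_at_reference(self):
        opt, smax = optimum_and_max(ReactionNormUni(0.2, 0.0, -1.0))
        assert opt == pytest.approx(2.4)
        assert smax == pytest.approx(0.2)

    def test_hand_worked(self):
        opt, smax = optimum_and_max(ReactionNormUni(1.0, 2.0, -1.0))
        assert opt == pytest.approx(2.4 + 1.0)
        assert smax == pytest.approx(2.0)

    def test_convex_norm_rejected(self):
        with pytest.raises(ValueError):
            optimum_and_max(ReactionNormUni(0.0, 1.0, 0.5))


class TestGaussianMoments:
    def test_mean_closed_form(self, fitted_norm):
        assert mean_selection_gaussian(fitted_norm, 0.0, 1.0) == pytest.approx(
            0.0927 - 0.0353
        )
        assert mean_selection_gaussian(fitted_norm, 0.3, 0.0) == pytest.approx(
            selection_at(fitted_norm, 0.3)
        )

    def test_var_published_value(self, fitted_norm):
        assert var_selection_gaussian(fitted_norm, 0.0, 1.0) == pytest.approx(0.012, abs=5e-4)

    def test_linear_norm_variance(self):
        rn = ReactionNormUni(0.1, -0.2, 0.0)
        assert var_selection_gaussian(rn, 0.7, 1.0) == pytest.approx(0.04)
        # linear norm: mean independent of sigma2
        assert mean_selection_gaussian(rn, 0.7, 3.0) == mean_selection_gaussian(rn, 0.7, 0.0)

    @pytest.mark.parametrize("mu,sigma2", [(0.0, 1.0), (0.5, 0.49), (-1.0, 2.0)])
    def test_moments_match_monte_carlo(self, fitted_norm, mu, sigma2, rng):
        """Closed forms agree with 1e6-draw Monte Carlo within 3 MC SEs."""
        n = 1_000_000
        E = mu + np.sqrt(sigma2) * rng.standard_normal(n)
        s = selection_at(fitted_norm, E)
        se_mean = s.std() / np.sqrt(n)
        assert mean_selection_gaussian(fitted_norm, mu, sigma2) == pytest.approx(
            s.mean(), abs=3 * se_mean
        )
        se_var = s.var() * np.sqrt(2.0 / n) * 2
        assert var_selection_gaussian(fitted_norm, mu, sigma2) == pytest.approx(
            s.var(), abs=3 * se_var
        )

    @given(a=coef, b=coef, c=coef, mu=st.floats(-1, 1), sigma2=st.floats(0.01, 2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_jensen_direction(self, a, b, c, mu, sigma2):
        """Concave norms lose mean selection under environmental variance; convex gain."""
        rn = ReactionNormUni(a, b, c)
        diff = mean_selection_gaussian(rn, mu, sigma2) - selection_at(rn, mu)
        assert diff == pytest.approx(c * sigma2, abs=1e-12)


class TestSelectionDistribution:
    def test_moments_match_closed_forms(self, fitted_norm):
        d = selection_distribution(fitted_norm, 0.0, 1.0)
        assert d.kind == "displaced-noncentral-chi-square"
        assert d.mean == pytest.approx(0.0574, abs=1e-6)
        assert d.variance == pytest.approx(0.012373, abs=1e-5)

    def test_sampler_matches_cdf(self, fitted_norm):
        """KS distance between 1e5 draws and the closed-form CDF below alpha=0.01 cutoff."""
        d = selection_distribution(fitted_norm, 0.0, 1.0)
        x = d.rvs(100_000, seed=5)
        res = stats.kstest(x, d.cdf)
        assert res.pvalue > 0.01

    def test_linear_norm_is_gaussian(self):
        d = selection_distribution(ReactionNormUni(0.05, -0.1, 0.0), 0.0, 1.0)
        assert d.kind == "normal"
        x = d.rvs(200_000, seed=2)
        assert abs(stats.skew(x)) < 0.02

    def test_sampled_moments(self, fitted_norm):
        d = selection_distribution(fitted_norm, 0.3, 0.8)
        n = 1_000_000
        x = d.rvs(n, seed=9)
        assert x.mean() == pytest.approx(d.mean, abs=4 * x.std() / np.sqrt(n))
        assert x.var() == pytest.approx(d.variance, abs=4 * x.var() * np.sqrt(2 / n) * 2)

    def test_degenerate_environment_rejected(self, fitted_norm):
        with pytest.raises(ValueError):
            selection_distribution(fitted_norm, 0.0, 0.0)


class TestBivariateNorm:
    def test_reduction_to_univariate(self):
        rnb = ReactionNormBi(0.1, -0.2, 0.05)
        rn = rnb.as_univariate()
        for e_prev in (-1.0, 0.0, 2.0):
            assert bivariate_selection_at(rnb, e_prev, 0.7) == pytest.approx(
                selection_at(rn, 0.7)
            )

    def test_hand_worked_values(self):
        assert bivariate_selection_at(ReactionNormBi(0, 0, 0, 1, 0, 0), 0.5, 9.9) == 0.5
        assert bivariate_selection_at(ReactionNormBi(1, 1, 1, 1, 1, 1), 1.0, 2.0) == 11.0

    def test_mean_affine_in_rho(self):
        """Mean selection responds linearly to autocorrelation, slope f*sigma2."""
        rnb = ReactionNormBi(0.1, -0.1, -0.05, 0.02, -0.01, 0.07)
        rhos = np.linspace(-0.9, 0.9, 13)
        means = np.array([bivariate_mean_selection(rnb, 0.3, 1.5, r) for r in rhos])
        second_diff = np.diff(means, 2)
        assert np.allclose(second_diff, 0.0, atol=1e-12)
        slope = (means[-1] - means[0]) / (rhos[-1] - rhos[0])
        assert slope == pytest.approx(rnb.f * 1.5)

    def test_no_interaction_no_rho_effect(self):
        rnb = ReactionNormBi(0.1, -0.1, -0.05, 0.02, -0.01, 0.0)
        assert bivariate_mean_selection(rnb, 0, 1, 0.9) == bivariate_mean_selection(
            rnb, 0, 1, -0.9
        )

    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.7])
    def test_mean_matches_monte_carlo(self, rho, rng):
        rnb = ReactionNormBi(0.05, -0.08, -0.03, 0.04, 0.01, 0.06)
        mu, sigma2, n = 0.2, 1.0, 1_000_000
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        e_prev = mu + z1
        e_cur = mu + rho * z1 + np.sqrt(1 - rho**2) * z2
        s = bivariate_selection_at(rnb, e_prev, e_cur)
        assert bivariate_mean_selection(rnb, mu, sigma2, rho) == pytest.approx(
            s.mean(), abs=3 * s.std() / np.sqrt(n)
        )

    def test_variance_exact_vs_monte_carlo(self):
        rnb = ReactionNormBi(0.05, -0.08, -0.03, 0.04, 0.01, 0.06)
        for rho in (-0.5, 0.0, 0.9):
            mc = bivariate_var_selection(rnb, 0.1, 1.0, rho, n_draws=1_000_000, seed=3)
            exact = bivariate_var_selection_exact(rnb, 0.1, 1.0, rho)
            assert mc == pytest.approx(exact, rel=0.01)

    def test_variance_reductions(self):
        # no past terms at mu=0: equals the univariate variance
        rnb = ReactionNormBi(0.1, -0.2, 0.05)
        assert bivariate_var_selection_exact(rnb, 0.0, 1.3, 0.4) == pytest.approx(
            var_selection_gaussian(ReactionNormUni(0.1, -0.2, 0.05), 0.0, 1.3)
        )
        # independent linear terms
        rnb = ReactionNormBi(0.0, 0.3, 0.0, -0.2, 0.0, 0.0)
        assert bivariate_var_selection_exact(rnb, 0.0, 2.0, 0.0) == pytest.approx(
            (0.3**2 + 0.2**2) * 2.0
        )
        # perfectly correlated environments collapse the linear terms
        assert bivariate_var_selection_exact(rnb, 0.0, 2.0, 1.0) == pytest.approx(
            (0.3 - 0.2) ** 2 * 2.0
        )


class TestVarianceInflation:
    def test_weekly_cycle(self):
        assert variance_inflation_factor([3, 4]) == pytest.approx(25 / 7)

    def test_degenerate_cycles(self):
        assert variance_inflation_factor([1]) == 1.0
        assert variance_inflation_factor([7]) == 7.0

    def test_rotation_invariance(self):
        assert variance_inflation_factor([3, 4]) == variance_inflation_factor([4, 3])

    @given(st.lists(st.floats(0.5, 10), min_size=1, max_size=6), st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scaling(self, durations, k):
        """Rescaling all durations by k rescales the factor by k."""
        assert variance_inflation_factor(np.array(durations) * k) == pytest.approx(
            k * variance_inflation_factor(durations), rel=1e-9
        )

    def test_brute_force_block_variance(self, rng):
        """Independent MC derivation: block-constant vs daily-iid selection variance.

        Selection is redrawn once per transfer and held constant for its
        3 or 4 days; the variance of the weekly cumulative logit change,
        relative to daily redraws, is the inflation factor.
        """
        n = 100_000
        sigma = 0.3
        s_blocks = sigma * rng.standard_normal((n, 2))
        block = s_blocks[:, 0] * 3 + s_blocks[:, 1] * 4
        daily = (sigma * rng.standard_normal((n, 7))).sum(axis=1)
        ratio = block.var() / daily.var()
        se = ratio * np.sqrt(2.0 / n) * 2
        assert ratio == pytest.approx(25 / 7, abs=4 * se)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            variance_inflation_factor([])


class TestToleranceCurves:
    def test_identical_strains_zero_selection(self):
        f = lambda x: 0.5 - 0.1 * (x - 2.0) ** 2
        rn = selection_from_tolerance(ToleranceCurvePair(f, f))
        assert rn.a == pytest.approx(0.0, abs=1e-12)
        assert rn.b == pytest.approx(0.0, abs=1e-12)
        assert rn.c == pytest.approx(0.0, abs=1e-12)

    def test_equal_breadth_gives_flat_norm(self):
        """Same width and optimum, different heights: constant selection."""
        gC = lambda x: 0.7 * np.exp(-((x - 2.4) ** 2) / 8)
        gA = lambda x: 0.5 * np.exp(-((x - 2.4) ** 2) / 8)
        rn = selection_from_tolerance(ToleranceCurvePair(gC, gA))
        # heights differ multiplicatively so selection is not exactly flat,
        # but a common-breadth *quadratic* pair is:
        gC2 = lambda x: 0.7 - 0.1 * (x - 2.4) ** 2
        gA2 = lambda x: 0.5 - 0.1 * (x - 2.4) ** 2
        rn2 = selection_from_tolerance(ToleranceCurvePair(gC2, gA2))
        assert rn2.a == pytest.approx(0.2, abs=1e-10)
        assert rn2.b == pytest.approx(0.0, abs=1e-10)
        assert rn2.c == pytest.approx(0.0, abs=1e-10)

    def test_curvature_difference_recovered(self):
        gC = lambda x: 0.6 - 0.15 * (x - 2.4) ** 2
        gA = lambda x: 0.6 - 0.10 * (x - 2.4) ** 2
        rn = selection_from_tolerance(ToleranceCurvePair(gC, gA))
        assert rn.c == pytest.approx(-0.05, abs=1e-10)

    def test_underdetermined_grid(self):
        f = lambda x: x
        with pytest.raises(ValueError):
            selection_from_tolerance(ToleranceCurvePair(f, f), E_grid=np.array([0.0, 1.0]))

    def test_breadth_definition(self, fitted_norm):
        assert fitted_norm.breadth == pytest.approx(1 / np.sqrt(0.0353))


class TestPredictTrajectory:
    def test_constant_environment_linear(self, fitted_norm):
        spec = TreatmentSpec(2.4, 0.0, 0.0, n_transfers=37, constant=True)
        series = simulate_ar1(spec, seed=0)
        traj = predict_trajectory(fitted_norm, series, psi0=-3.8)
        assert traj[-1] == pytest.approx(-3.8 + 0.0927 * 129)

    def test_zero_selection_flat(self):
        spec = TreatmentSpec(2.4, 1.0, 0.5, n_transfers=10)
        series = simulate_ar1(spec, seed=4)
        traj = predict_trajectory(ReactionNormUni(0, 0, 0), series, psi0=1.5)
        assert np.all(traj == 1.5)

    def test_bivariate_reduces_to_univariate(self):
        spec = TreatmentSpec(2.4, 1.0, 0.0, n_transfers=8)
        series = simulate_ar1(spec, seed=4)
        uni = ReactionNormUni(0.1, -0.05, 0.02)
        bi = ReactionNormBi(0.1, -0.05, 0.02)
        assert np.allclose(
            predict_trajectory(uni, series, 0.0), predict_trajectory(bi, series, 0.0)
        )
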