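import numpy as np
import pytest

from _oracles import conjugate_single_subtrial, grid_posterior_two_subtrials, pinv_ols
from basketbhm import (
    BasketTrialData,
    BhmSpec,
    EffectEstimate,
    FitError,
    McmcConfig,
    PosteriorDraws,
    ScenarioConfig,
    center_covariates,
    decide_rejection,
    estimate_overall_effect,
    fit_bhm,
    generate_scenario,
    summarize_posterior,
)
from basketbhm.bhm_core import build_design


def _draws_from_theta(theta_draws: np.ndarray, K: int | None = None) -> PosteriorDraws:
    """Wrap raw theta draws (n, K) in a PosteriorDraws for summary tests."""
    theta_draws = np.atleast_2d(theta_draws.T).T
    n, K = theta_draws.shape
    coef = np.zeros((n, K, 2))
    coef[:, :, 1] = theta_draws
    return PosteriorDraws(
        coef=coef, coef_names=("alpha", "theta"),
        mu_theta=theta_draws.mean(axis=1),
        sigma_theta=np.ones(n), sigma_y2=np.ones(n),
        spec=BhmSpec(), mcmc=McmcConfig(n_iter=n + 1, burn_in=0),
    )


@pytest.fixture(scope="module")
def two_subtrial_fixture():
    """8-patient, 2-subtrial dataset with hand-written outcomes."""
    return BasketTrialData(
        subtrial=[1, 1, 1, 1, 2, 2, 2, 2],
        treatment=[0, 0, 1, 1, 0, 0, 1, 1],
        outcome=[0.3, -0.6, 2.1, 2.8, 0.9, 0.1, 3.5, 2.4],
        covariates=np.empty((8, 0)),
    )


class TestSamplerOracles:
    def test_gibbs_matches_dense_grid_with_degenerate_scales(self, two_subtrial_fixture):
        """Exact-posterior check: with point-mass priors on both variance
        scales the model is small enough for 3-D quadrature."""
        sigma_theta, sigma_y2 = 0.8, 1.5
        spec = BhmSpec(
            data_model="UNADJUSTED",
            fixed_sigma_theta=sigma_theta,
            fixed_sigma_y2=sigma_y2,
        )
        draws = fit_bhm(
            two_subtrial_fixture, spec, McmcConfig(n_iter=110_000, burn_in=10_000, seed=7)
        )
        ref = grid_posterior_two_subtrials(
            two_subtrial_fixture.outcome,
            two_subtrial_fixture.treatment,
            two_subtrial_fixture.subtrial,
            sigma_theta,
            sigma_y2,
        )
        for k, (ref_mean, ref_sd) in enumerate(ref):
            mean = draws.theta[:, k].mean()
            sd = draws.theta[:, k].std(ddof=1)
            assert abs(mean - ref_mean) <= 0.02 * max(abs(ref_mean), ref_sd)
            assert abs(sd - ref_sd) <= 0.02 * ref_sd

    def test_single_subtrial_flat_hierarchy_matches_conjugate_reference(self):
        """With a near-flat half-t scale and K=1 the model collapses to a
        normal linear model whose posterior is computable by quadrature
        over the outcome variance."""
        y = np.array([0.2, -0.9, 0.5, 2.4, 3.1, 1.8])
        t = np.array([0, 0, 0, 1, 1, 1])
        data = BasketTrialData(
            subtrial=np.ones(6, dtype=int), treatment=t, outcome=y,
            covariates=np.empty((6, 0)),
        )
        spec = BhmSpec(data_model="UNADJUSTED", sigma_ht=1e6)
        draws = fit_bhm(data, spec, McmcConfig(n_iter=220_000, burn_in=20_000, seed=3))
        ref_mean, ref_sd = conjugate_single_subtrial(y, t)
        assert abs(draws.theta[:, 0].mean() - ref_mean) < 0.01 + 0.01 * abs(ref_mean)
        assert abs(draws.theta[:, 0].std(ddof=1) - ref_sd) < 0.01 + 0.01 * ref_sd

    def test_all_zero_outcomes_give_null_posterior(self, two_subtrial_fixture):
        data = BasketTrialData(
            subtrial=two_subtrial_fixture.subtrial,
            treatment=two_subtrial_fixture.treatment,
            outcome=np.zeros(8),
            covariates=np.empty((8, 0)),
        )
        draws = fit_bhm(data, BhmSpec(), McmcConfig(seed=1))
        for k in range(2):
            mean = draws.theta[:, k].mean()
            sd = draws.theta[:, k].std(ddof=1)
            assert abs(mean) < 3 * sd


class TestChainMechanics:
    def test_reproducible_with_same_seed(self, two_subtrial_fixture):
        a = fit_bhm(two_subtrial_fixture, BhmSpec(), McmcConfig(n_iter=3000, burn_in=500, seed=9))
        b = fit_bhm(two_subtrial_fixture, BhmSpec(), McmcConfig(n_iter=3000, burn_in=500, seed=9))
        assert np.array_equal(a.coef, b.coef)
        c = fit_bhm(two_subtrial_fixture, BhmSpec(), McmcConfig(n_iter=3000, burn_in=500, seed=10))
        assert not np.array_equal(a.coef, c.coef)

    def test_retained_draw_count_and_positive_scales(self, two_subtrial_fixture):
        mcmc = McmcConfig(n_iter=4000, burn_in=1000, seed=2, thin=3)
        draws = fit_bhm(two_subtrial_fixture, BhmSpec(), mcmc)
        assert draws.n_draws == mcmc.n_retained == 1000
        assert (draws.sigma_theta > 0).all()
        assert (draws.sigma_y2 > 0).all()

    def test_uncentered_covariates_refused(self):
        data = generate_scenario(
            ScenarioConfig("S2", 56, seed=1, standardize_covariates=False)
        )
        with pytest.raises(FitError, match="center"):
            fit_bhm(data, BhmSpec(data_model="ANCOVA1"), McmcConfig(n_iter=200, burn_in=50))
        fit_bhm(
            data, BhmSpec(data_model="ANCOVA1"),
            McmcConfig(n_iter=200, burn_in=50), allow_uncentered=True,
        )

    def test_collinear_design_names_subtrial(self):
        data = BasketTrialData(
            subtrial=[1] * 6 + [2] * 6,
            treatment=[0, 0, 0, 1, 1, 1] * 2,
            outcome=np.arange(12.0),
            covariates=np.r_[np.zeros(6), np.random.default_rng(0).standard_normal(6)][:, None],
        )
        with pytest.raises(FitError, match="subtrial 1"):
            fit_bhm(
                data, BhmSpec(data_model="ANCOVA2"),
                McmcConfig(n_iter=200, burn_in=50), allow_uncentered=True,
            )


class TestSummaries:
    def test_three_draw_symmetric_interval(self):
        draws = _draws_from_theta(np.array([[-1.0], [0.0], [1.0]]))
        with pytest.warns(UserWarning):
            est = summarize_posterior(draws, level=2 / 3)
        np.testing.assert_allclose([est.lower[0], est.upper[0]], [-1, 1])

    def test_large_normal_sample_halfwidth(self):
        z = np.random.default_rng(0).standard_normal(10**6)[:, None]
        with np.errstate(all="ignore"):
            est = summarize_posterior(_draws_from_theta(z))
        halfwidth = (est.upper[0] - est.lower[0]) / 2
        assert abs(halfwidth - 1.959964) < 0.01

    def test_constant_draws_degenerate(self):
        draws = _draws_from_theta(np.full((1500, 1), 3.25))
        est = summarize_posterior(draws)
        assert est.se[0] == 0
        np.testing.assert_allclose([est.lower[0], est.estimate[0], est.upper[0]], 3.25)

    def test_empty_draws_error(self):
        draws = _draws_from_theta(np.empty((0, 1)))
        with pytest.raises(ValueError):
            summarize_posterior(draws)

    def test_normal_interval_variant(self, two_subtrial_fixture):
        spec = BhmSpec(interval_method="normal")
        draws = fit_bhm(two_subtrial_fixture, spec, McmcConfig(seed=4))
        est = summarize_posterior(draws)
        np.testing.assert_allclose(
            est.upper - est.estimate, 1.959964 * est.se, rtol=1e-5
        )

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.2, 0.9, True), (-0.1, 0.5, False), (0.0, 0.8, False)],
    )
    def test_rejection_rule(self, lo, hi, expected):
        est = EffectEstimate(
            method="toy", estimate=[(lo + hi) / 2], se=[1.0], lower=[lo], upper=[hi]
        )
        assert decide_rejection(est)[0] == expected


class TestSerialization:
    def test_draws_to_frame(self, two_subtrial_fixture):
        draws = fit_bhm(
            two_subtrial_fixture, BhmSpec(), McmcConfig(n_iter=1500, burn_in=500, seed=0)
        )
        frame = draws.to_frame()
        assert len(frame) == draws.n_draws
        assert {"mu_theta", "sigma_theta", "sigma_y2", "theta_1", "theta_2"} <= set(frame.columns)
        np.testing.assert_array_equal(frame["theta_1"], draws.theta[:, 0])

    def test_yaml_config_loaders(self, tmp_path):
        from basketbhm.bhm_core import bhm_spec_from_yaml, mcmc_config_from_yaml

        sy = tmp_path / "spec.yml"
        sy.write_text("data_model: ANCOVA2\nsigma_ht: 100\ndf: 5\n")
        spec = bhm_spec_from_yaml(sy)
        assert spec.data_model == "ANCOVA2" and spec.sigma_ht == 100
        my = tmp_path / "mcmc.yml"
        my.write_text("n_iter: 5000\nburn_in: 1000\nseed: 3\n")
        mcmc = mcmc_config_from_yaml(my)
        assert mcmc.n_retained == 4000 and mcmc.seed == 3


class TestHierarchyBehaviour:
    def test_prior_only_chain_recovers_population_mean_prior(self, two_subtrial_fixture):
        draws = fit_bhm(
            two_subtrial_fixture, BhmSpec(), McmcConfig(n_iter=42_000, burn_in=2_000, seed=5),
            prior_only=True,
        )
        overall = estimate_overall_effect(draws)
        # prior is N(0, 100); the chain is autocorrelated, so wide tolerances
        assert abs(overall.mean) < 2.0
        assert 8.0 < overall.sd < 12.0

    def test_duplicating_subtrials_sharpens_population_mean(self):
        base = generate_scenario(ScenarioConfig("S2", 112, seed=8))
        doubled = BasketTrialData(
            subtrial=np.r_[base.subtrial, base.subtrial + base.K],
            treatment=np.r_[base.treatment, base.treatment],
            outcome=np.r_[base.outcome, base.outcome],
            covariates=np.r_[base.covariates, base.covariates],
        )
        sd_single = estimate_overall_effect(
            fit_bhm(base, BhmSpec(), McmcConfig(seed=6))
        ).sd
        sd_double = estimate_overall_effect(
            fit_bhm(doubled, BhmSpec(), McmcConfig(seed=6))
        ).sd
        assert sd_double < sd_single

    def test_shrinkage_toward_population_mean(self):
        """Posterior means of theta_k lie between the stratified OLS
        estimate and the population-mean posterior (hierarchical-normal
        contraction), up to Monte Carlo error."""
        for seed in range(4):
            data = generate_scenario(ScenarioConfig("S2", 112, seed=seed))
            draws = fit_bhm(data, BhmSpec(), McmcConfig(seed=100 + seed))
            mu_hat = draws.mu_theta.mean()
            X, _ = build_design(data, "UNADJUSTED")
            for k in range(1, data.K + 1):
                m = data.mask(k)
                ols = pinv_ols(X[m], data.outcome[m])[1]
                post = draws.theta[:, k - 1].mean()
                # batch-means MCSE of the posterior mean
                batches = draws.theta[:, k - 1].reshape(40, -1).mean(axis=1)
                mcse = batches.std(ddof=1) / np.sqrt(40)
                lo, hi = min(ols, mu_hat), max(ols, mu_hat)
                assert lo - 3 * mcse <= post <= hi + 3 * mcse

    def test_weaker_half_t_borrows_less(self):
        """HT(100,5) shrinks the extreme subtrials toward the population
        mean no more than HT(2,5) does."""
        data = generate_scenario(
            ScenarioConfig("S2", 560, theta_true=(0.0, 0.0, 4.0, 4.0), seed=12)
        )
        X, _ = build_design(data, "UNADJUSTED")
        ols = np.array(
            [pinv_ols(X[data.mask(k)], data.outcome[data.mask(k)])[1] for k in (1, 4)]
        )
        gaps = {}
        for s_ht in (2.0, 100.0):
            draws = fit_bhm(data, BhmSpec(sigma_ht=s_ht), McmcConfig(seed=13))
            post = draws.theta[:, [0, 3]].mean(axis=0)
            gaps[s_ht] = np.abs(post - ols)
        assert (gaps[100.0] <= gaps[2.0] + 0.02).all()

    def test_overall_effect_recovery_homogeneous(self):
        data = center_covariates(generate_scenario(ScenarioConfig("HOMOG", 560, seed=21)))
        draws = fit_bhm(data, BhmSpec(data_model="ANCOVA1"), McmcConfig(seed=22))
        overall = estimate_overall_effect(draws)
        assert abs(overall.mean - 1.0) < 3 * overall.sd


class TestLogisticVariant:
    def test_separation_sets_nonconvergence_flag(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        y = (x > 0).astype(float)  # outcome perfectly separated on covariate
        data = BasketTrialData(
            subtrial=np.r_[np.ones(40, int), np.full(40, 2)],
            treatment=np.r_[np.repeat([0, 1], 20), np.repeat([0, 1], 20)],
            outcome=np.r_[y, (rng.random(40) < 0.5).astype(float)],
            covariates=np.r_[x, rng.standard_normal(40)][:, None],
        )
        data = center_covariates(data)
        spec = BhmSpec(data_model="ANCOVA1", outcome_model="logistic")
        draws = fit_bhm(data, spec, McmcConfig(n_iter=12_000, burn_in=2_000, seed=1))
        assert not draws.converged

    def test_wellposed_logistic_recovers_effect_sign(self):
        rng = np.random.default_rng(3)
        n = 400
        sub = np.r_[np.ones(n, int), np.full(n, 2)]
        t = np.r_[np.repeat([0, 1], n // 2), np.repeat([0, 1], n // 2)]
        x = rng.standard_normal(2 * n)
        lp = -0.5 + 1.5 * t + 0.8 * x
        y = (rng.random(2 * n) < 1 / (1 + np.exp(-lp))).astype(float)
        data = center_covariates(
            BasketTrialData(subtrial=sub, treatment=t, outcome=y, covariates=x[:, None])
        )
        spec = BhmSpec(data_model="ANCOVA1", outcome_model="logistic")
        draws = fit_bhm(data, spec, McmcConfig(n_iter=12_000, burn_in=2_000, seed=2))
        assert draws.converged
        est = summarize_posterior(draws)
        assert (est.estimate > 0.5).all() and (est.estimate < 3.0).all()
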