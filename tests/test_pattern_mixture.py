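import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mnar_elicit import (
    ArmSummary,
    McmcConfig,
    NormalSpec,
    PatternMixtureModel,
    SensitivityPrior,
    TrialGenConfig,
    bayesian_fit,
    generate_trial,
    linear_pool,
    mar_fit,
    moment_estimate,
    moment_estimate_pooled,
    prob_exceeds,
    sample_pool,
    summarise_arm,
    tipping_point_scan,
)

DELTA_E = NormalSpec(-0.01, 0.04)
DELTA_O = NormalSpec(-0.05, 0.10)


def degenerate_pool(mean_O=-0.05, mean_E=-0.01, sd=1e-6, rho=0.0):
    return linear_pool(
        [SensitivityPrior("point", mean_O, sd, mean_E, sd, rho)], label="degenerate"
    )


class TestSummariseArm:
    def test_arithmetic(self):
        df = pd.DataFrame(
            {
                "arm": ["OPEN"] * 3 + ["EEVAR"] * 2,
                "qol": [0.5, 0.9, None, 0.7, 0.8],
                "missing": [False, False, True, False, False],
            }
        )
        s = summarise_arm(df, "OPEN")
        assert s.mu == pytest.approx(0.7)
        assert s.pi == pytest.approx(1 / 3)
        assert s.se_mu == pytest.approx(np.std([0.5, 0.9], ddof=1) / np.sqrt(2))

    def test_absent_arm_errors(self):
        df = pd.DataFrame({"arm": ["OPEN"] * 2, "qol": [0.5, 0.6], "missing": [False, False]})
        with pytest.raises(ValueError, match="not present"):
            summarise_arm(df, "EEVAR")

    def test_all_missing_arm_errors(self):
        df = pd.DataFrame(
            {
                "arm": ["OPEN", "OPEN", "EEVAR"],
                "qol": [0.5, 0.6, None],
                "missing": [False, False, True],
            }
        )
        with pytest.raises(ValueError, match="observed outcomes"):
            summarise_arm(df, "EEVAR")

    def test_recovers_generating_mean(self):
        cfg = TrialGenConfig(n_per_arm=5000, seed=31)
        data, truth = generate_trial(cfg)
        s = summarise_arm(data, "EEVAR")
        # observed mean estimates E[Y | observed] = true mean - pi*delta/(1-pi)... no:
        # mean = (1-pi)*E[Y|obs] + pi*E[Y|miss]  =>  E[Y|obs] = mean - pi*delta
        expected_obs_mean = cfg.true_mean_E - truth.pi_E_true * truth.delta_E_true
        assert s.mu == pytest.approx(expected_obs_mean, abs=3 * s.se_mu)


class TestArmSummaryInvariants:
    def test_pi_bounds(self):
        with pytest.raises(ValueError, match="pi"):
            ArmSummary(mu=0.7, se_mu=0.02, pi=1.2)

    def test_counts_must_match_pi(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ArmSummary(mu=0.7, se_mu=0.02, pi=0.5, n_obs=80, n_miss=20)

    def test_consistent_counts_accepted(self):
        s = ArmSummary(mu=0.7, se_mu=0.02, pi=0.2, n_obs=80, n_miss=20)
        assert s.pi == 0.2


class TestMomentEstimator:
    def test_worked_example_exact(self, worked_example_arms):
        evar, open_ = worked_example_arms
        m = moment_estimate(evar, open_, DELTA_E, DELTA_O)
        assert m.delta_hat == pytest.approx(0.0802, abs=1e-12)
        assert m.variance == pytest.approx(0.00192784, abs=1e-12)
        assert round(m.delta_hat, 2) == 0.08
        assert round(m.variance, 3) == 0.002
        assert round(m.se, 3) == 0.044
        assert round(m.ci_low, 2) == -0.01
        assert round(m.ci_high, 2) == 0.17

    def test_observed_only(self, worked_example_arms):
        evar, open_ = worked_example_arms
        zero = NormalSpec(0.0, 0.0)
        m = moment_estimate(evar, open_, zero, zero)
        assert round(m.delta_hat, 2) == 0.07
        assert round(m.ci_low, 2) == 0.00
        assert round(m.ci_high, 2) == 0.14

    def test_symmetry_gives_exact_zero(self):
        s = ArmSummary(mu=0.7, se_mu=0.02, pi=0.2)
        m = moment_estimate(s, s, DELTA_E, DELTA_E)
        assert m.delta_hat == 0.0

    def test_pooled_single_component_reduces_to_plain(self, worked_example_arms):
        evar, open_ = worked_example_arms
        pool = linear_pool(
            [SensitivityPrior("e", DELTA_O.mean, DELTA_O.sd, DELTA_E.mean, DELTA_E.sd, 0.0)]
        )
        a = moment_estimate_pooled(evar, open_, pool)
        b = moment_estimate(evar, open_, DELTA_E, DELTA_O)
        assert a.delta_hat == pytest.approx(b.delta_hat, abs=1e-14)
        assert a.variance == pytest.approx(b.variance, abs=1e-14)

    def test_positive_correlation_shrinks_variance(self, worked_example_arms):
        evar, open_ = worked_example_arms

        def pool_with(rho):
            return linear_pool(
                [SensitivityPrior("e", DELTA_O.mean, DELTA_O.sd, DELTA_E.mean, DELTA_E.sd, rho)]
            )

        v0 = moment_estimate_pooled(evar, open_, pool_with(0.0)).variance
        v9 = moment_estimate_pooled(evar, open_, pool_with(0.9)).variance
        assert v9 < v0

    def test_pooled_matches_monte_carlo_plugin(self, worked_example_arms, panel_pool):
        evar, open_ = worked_example_arms
        m = moment_estimate_pooled(evar, open_, panel_pool)
        n = 200_000
        d = sample_pool(panel_pool, n, seed=77)
        vals = (evar.mu + evar.pi * d[:, 1]) - (open_.mu + open_.pi * d[:, 0])
        se_mean = vals.std(ddof=1) / np.sqrt(n)
        assert m.delta_hat == pytest.approx(vals.mean(), abs=3 * se_mean)
        mc_var = vals.var(ddof=1) + evar.se_mu**2 + open_.se_mu**2
        c = vals - vals.mean()
        se_var = np.sqrt((np.mean(c**4) - vals.var(ddof=1) ** 2) / n)
        assert m.variance == pytest.approx(mc_var, abs=3 * se_var)


class TestTippingPointScan:
    def test_worked_example_cells(self, worked_example_arms):
        evar, open_ = worked_example_arms
        scan = tipping_point_scan(evar, open_, grid_O=[-0.05, 0.0], grid_E=[-0.01, 0.0])
        t = scan.table.set_index(["delta_O", "delta_E"])
        assert round(t.loc[(-0.05, -0.01), "estimate"], 2) == 0.08
        assert round(t.loc[(0.0, 0.0), "estimate"], 2) == 0.07

    def test_monotone_in_offsets(self, worked_example_arms):
        evar, open_ = worked_example_arms
        grid = np.linspace(-0.2, 0.2, 9)
        scan = tipping_point_scan(evar, open_, grid_O=grid, grid_E=grid)
        t = scan.table
        for _, grp in t.groupby("delta_O"):
            assert grp.sort_values("delta_E")["estimate"].is_monotonic_increasing
        for _, grp in t.groupby("delta_E"):
            assert grp.sort_values("delta_O")["estimate"].is_monotonic_decreasing

    def test_flags_mark_ci_zero_crossing(self, worked_example_arms):
        evar, open_ = worked_example_arms
        grid_o = np.linspace(-0.3, 0.3, 13)
        scan = tipping_point_scan(evar, open_, grid_O=grid_o, grid_E=[0.0])
        flips = scan.tipping_cells()
        assert len(flips) >= 1  # significance must flip somewhere on this grid


class TestBayesianFit:
    def test_degenerate_prior_matches_closed_form(self, worked_example_arms):
        # with point-mass offsets and a summary-level likelihood the posterior
        # of Delta is normal with the moment estimator's mean and SD
        evar, open_ = worked_example_arms
        cfg = McmcConfig(seed=101, chains=4, warmup=0, draws=4000)
        res = bayesian_fit((open_, evar), degenerate_pool(), cfg)
        d = res.delta_draws
        n = d.size
        exact_mean = 0.0802
        exact_sd = math.sqrt(0.02**2 + 0.03**2)
        assert d.mean() == pytest.approx(exact_mean, abs=3 * exact_sd / np.sqrt(n))
        assert d.std(ddof=1) == pytest.approx(exact_sd, rel=3 / np.sqrt(2 * n) + 0.01)

    def test_posterior_of_offsets_equals_prior(self, small_trial, panel_pool):
        # delta never enters the likelihood: its posterior IS the pooled prior
        from scipy.stats import ks_2samp

        data, _ = small_trial
        cfg = McmcConfig(seed=11, chains=2, warmup=200, draws=2000)
        res = bayesian_fit(data, panel_pool, cfg)
        fresh = sample_pool(panel_pool, res.delta_draws.size, seed=987)
        for i, name in enumerate(["delta_O", "delta_E"]):
            stat = ks_2samp(res.draws[name].reshape(-1), fresh[:, i]).statistic
            assert stat < 0.05

    def test_mar_fit_equals_zero_point_mass_pool(self, small_trial):
        data, _ = small_trial
        cfg = McmcConfig(seed=21, chains=2, warmup=200, draws=1500)
        a = mar_fit(data, cfg)
        b = bayesian_fit(data, degenerate_pool(mean_O=0.0, mean_E=0.0, sd=1e-12), cfg)
        tol = 3 * a.delta_draws.std() / np.sqrt(a.delta_draws.size)
        assert a.posterior_mean == pytest.approx(b.posterior_mean, abs=2 * tol)
        assert a.delta_draws.std() == pytest.approx(b.delta_draws.std(), rel=0.05)

    def test_mar_on_worked_example_summaries(self, worked_example_arms):
        evar, open_ = worked_example_arms
        cfg = McmcConfig(seed=31, chains=2, warmup=0, draws=4000)
        res = mar_fit((open_, evar), cfg)
        mc_se = res.delta_draws.std() / np.sqrt(res.delta_draws.size)
        assert res.posterior_mean == pytest.approx(0.07, abs=3 * mc_se)

    def test_mcar_trial_mar_matches_complete_case(self):
        cfg_gen = TrialGenConfig(
            n_per_arm=400, miss_slope_O=0.0, miss_slope_E=0.0,
            miss_intercept_O=-1.2, miss_intercept_E=-1.2, seed=17,
        )
        data, truth = generate_trial(cfg_gen)
        assert truth.delta_O_true == pytest.approx(0.0, abs=1e-12)
        cfg = McmcConfig(seed=41, chains=2, warmup=200, draws=1500)
        a = mar_fit(data, cfg)
        b = mar_fit(data, cfg, complete_case=True)
        assert a.posterior_mean == pytest.approx(b.posterior_mean, abs=1e-9)

    def test_conjugacy_data_level(self, small_trial):
        # all-normal, plug-in pi, no covariates: the Bayesian posterior of
        # Delta matches the moment estimator built from the same prior
        data, _ = small_trial
        prior = linear_pool([SensitivityPrior("e", -0.05, 0.08, -0.01, 0.06, 0.0)])
        model = PatternMixtureModel.from_dataframe(data, prior=prior)
        res = model.fit(McmcConfig(seed=51, chains=2, warmup=300, draws=3000))
        mom = model.fit_moment()
        n = res.delta_draws.size
        mc_se = res.delta_draws.std() / np.sqrt(n)
        assert res.posterior_mean == pytest.approx(mom.delta_hat, abs=4 * mc_se)
        assert res.delta_draws.std(ddof=1) == pytest.approx(mom.se, rel=0.05)

    def test_mnar_interval_wider_than_mar(self, small_trial, panel_pool):
        data, _ = small_trial
        cfg = McmcConfig(seed=61, chains=2, warmup=200, draws=1500)
        mnar = bayesian_fit(data, panel_pool, cfg)
        mar = mar_fit(data, cfg)
        assert (mnar.ci_high - mnar.ci_low) >= (mar.ci_high - mar.ci_low)

    def test_seed_determinism(self, small_trial, panel_pool):
        data, _ = small_trial
        cfg = McmcConfig(seed=71, chains=2, warmup=100, draws=500)
        r1 = bayesian_fit(data, panel_pool, cfg)
        r2 = bayesian_fit(data, panel_pool, cfg)
        assert np.array_equal(r1.draws["delta"], r2.draws["delta"])

    def test_covariate_adjustment_recovers_effect(self):
        cfg_gen = TrialGenConfig(n_per_arm=400, covariate_effect=0.1, seed=19)
        data, truth = generate_trial(cfg_gen)
        model = PatternMixtureModel.from_dataframe(data, covariates=("x",))
        res = model.fit(McmcConfig(seed=81, chains=2, warmup=300, draws=1500))
        beta = res.draws["beta_x"].reshape(-1)
        lo, hi = np.percentile(beta, [2.5, 97.5])
        assert lo < 0.1 < hi

    def test_beta_binomial_pi_adds_uncertainty(self, small_trial, panel_pool):
        data, _ = small_trial
        plug = bayesian_fit(data, panel_pool, McmcConfig(seed=91, chains=2, warmup=100, draws=1500))
        bb = bayesian_fit(
            data, panel_pool,
            McmcConfig(seed=91, chains=2, warmup=100, draws=1500, pi_mode="beta_binomial"),
        )
        assert bb.delta_draws.std() >= 0.95 * plug.delta_draws.std()

    def test_summary_table_lists_monitored_parameters(self, small_trial, panel_pool):
        data, _ = small_trial
        res = bayesian_fit(data, panel_pool, McmcConfig(seed=3, chains=2, warmup=100, draws=1000))
        tab = res.summary()
        for name in ("delta", "mu_O", "mu_E", "delta_O", "delta_E", "sigma_O"):
            assert name in tab.index
            assert np.isfinite(tab.loc[name, "rhat"])


class TestProbExceeds:
    def test_constant_draws(self, small_trial):
        data, _ = small_trial
        res = mar_fit(data, McmcConfig(seed=1, chains=2, warmup=100, draws=1000))
        res.draws["delta"] = np.full_like(res.draws["delta"], 0.05)
        assert prob_exceeds(res, 0.03) == 1.0
        assert prob_exceeds(res, -1e9) == 1.0

    def test_normal_draws_match_closed_form(self, small_trial):
        data, _ = small_trial
        res = mar_fit(data, McmcConfig(seed=5, chains=2, warmup=50, draws=1000))
        rng = np.random.default_rng(4)
        res.draws["delta"] = rng.normal(0.08, 0.044, size=(2, 100_000))
        p = prob_exceeds(res, 0.03)
        exact = norm.sf((0.03 - 0.08) / 0.044)
        assert p == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / 200_000))

    def test_too_few_draws_warns(self, small_trial):
        data, _ = small_trial
        res = mar_fit(data, McmcConfig(seed=2, chains=2, warmup=50, draws=100))
        with pytest.warns(UserWarning, match="noisy"):
            res.prob_exceeds()


class TestConfigValidation:
    def test_requires_two_chains(self):
        with pytest.raises(ValueError, match="chains"):
            McmcConfig(seed=1, chains=1)

    def test_unknown_pi_mode(self):
        with pytest.raises(ValueError, match="pi_mode"):
            McmcConfig(seed=1, pi_mode="magic")
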