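"""Gibbs sampler and likelihood for the AR(1) longitudinal model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import xlogy

from dmdlv import (
    CohortPanel,
    McmcConfig,
    ModelParams,
    PriorSpec,
    SimulationConfig,
    covariate_effects,
    fit_model,
    log_likelihood,
    peak_strain_params,
    simulate_cohort,
    trajectory_differences,
)
from conftest import PEAK_ALPHA


def mvn_log_likelihood(panel, params):
    """Independent oracle: joint multivariate-normal density per subject with
    the covariance built from the AR(1) recursion, plus Bernoulli mass."""
    total = 0.0
    for _, sub in panel.subset(group="dmd").groupby("subject_id"):
        sub = sub.sort_values("visit")
        L = len(sub)
        mu = params.mu(sub["visit"], sub["loa"], sub["ace"],
                       sub["age_baseline"])
        var = np.zeros(L)
        var[0] = params.sigma_y**2
        for t in range(1, L):
            var[t] = params.beta**2 * var[t - 1] + params.sigma_y**2
        cov = np.zeros((L, L))
        for s in range(L):
            for t in range(s, L):
                cov[s, t] = cov[t, s] = params.beta ** (t - s) * var[s]
        total += sps.multivariate_normal.logpdf(
            sub["value"].to_numpy(), mean=mu, cov=cov)
        for col, eta in (("loa", params.eta_loa), ("ace", params.eta_ace)):
            x = sub[col].to_numpy(dtype=float)
            total += float(xlogy(x, eta).sum() + xlogy(1 - x, 1 - eta).sum())
    return float(total)


class TestLogLikelihood:
    def test_noise_free_single_subject_hits_gaussian_maximum(self):
        sigma = 1.3
        params = ModelParams(alpha=PEAK_ALPHA, sigma_y=sigma,
                             eta_loa=0.5, eta_ace=0.5)
        rec = pd.DataFrame({
            "subject_id": "s0", "group": "dmd", "visit": range(6),
            "age_baseline": 0.0, "loa": 0.0, "ace": 0.0,
            "response_name": "peak_strain_pct", "value": PEAK_ALPHA,
        })
        ll = log_likelihood(CohortPanel(rec), params)
        gaussian_max = 6 * sps.norm.logpdf(0.0, scale=sigma)
        bern = 12 * np.log(0.5)      # 6 visits x 2 indicators at eta = 0.5
        assert ll == pytest.approx(gaussian_max + bern, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_sequential_equals_joint_mvn_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        params = ModelParams(
            alpha=rng.normal(-17, 2, size=rng.integers(2, 6)),
            beta=rng.uniform(-0.8, 0.8), gamma_loa=rng.normal(0, 1),
            gamma_ace=rng.normal(0, 1), delta=rng.normal(0, 0.3),
            sigma_y=rng.uniform(0.5, 3.0),
            eta_loa=rng.uniform(0.1, 0.9), eta_ace=rng.uniform(0.1, 0.9))
        cfg = SimulationConfig(params=params,
                               n_subjects=int(rng.integers(2, 5)),
                               n_visits=params.n_visits, loa_mode="iid",
                               seed=seed)
        panel = simulate_cohort(cfg)
        assert log_likelihood(panel, params) == pytest.approx(
            mvn_log_likelihood(panel, params), abs=1e-8)

    def test_inflating_sigma_lowers_noise_free_likelihood(self, small_panel):
        params = peak_strain_params(beta=0.4, sigma_y=2.0)
        assert log_likelihood(small_panel, params) > log_likelihood(
            small_panel, params.replace(sigma_y=4.0))

    def test_gap_in_visit_sequence_rejected(self, small_panel):
        df = small_panel.records.copy()
        df = df[~((df.subject_id == "dmd000") & (df.visit == 1))]
        with pytest.raises(ValueError, match="gaps|lacks rows"):
            log_likelihood(CohortPanel(df), peak_strain_params())


class TestMcmcConfig:
    @pytest.mark.parametrize("kw", [
        dict(n_iterations=100, n_burnin=100),
        dict(n_chains=1),
        dict(thin=0),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            McmcConfig(**kw)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(normal_sd=0.0)


@pytest.fixture(scope="module")
def conjugate_fit():
    """beta = 0, sigma known, covariate effects pinned at zero: the visit
    intercepts then have an exact Gaussian conjugate posterior."""
    params = ModelParams(alpha=PEAK_ALPHA[:3], beta=0.0, sigma_y=1.5)
    cfg = SimulationConfig(params=params, n_subjects=40, n_visits=3,
                           loa_mode="iid", seed=77)
    panel = simulate_cohort(cfg)
    fit = fit_model(
        panel, "peak_strain_pct",
        mcmc=McmcConfig(n_chains=2, n_iterations=5500, n_burnin=500, seed=8),
        fixed={"beta": 0.0, "sigma_y": 1.5, "gamma_loa": 0.0,
               "gamma_ace": 0.0, "delta": 0.0})
    return panel, fit


class TestConjugateClosedForm:
    def test_alpha_draws_match_closed_form(self, conjugate_fit):
        panel, fit = conjugate_fit
        df = panel.subset(group="dmd")
        sigma2, tau2 = 1.5**2, 100.0**2
        for t in range(3):
            y = df.loc[df.visit == t, "value"].to_numpy()
            prec = y.size / sigma2 + 1.0 / tau2
            mean, sd = (y.sum() / sigma2) / prec, np.sqrt(1.0 / prec)
            draws = fit.pooled(f"alpha_{t}")
            assert draws.size == 10_000
            ks = sps.kstest(draws, sps.norm(mean, sd).cdf)
            assert ks.statistic < 0.05
            assert fit[f"alpha_{t}"].mean == pytest.approx(mean, abs=4 * sd / 100)

    def test_vague_prior_posterior_mean_is_visitwise_average(self, conjugate_fit):
        panel, fit = conjugate_fit
        y0 = panel.subset(group="dmd").query("visit == 0")["value"]
        assert fit["alpha_0"].mean == pytest.approx(y0.mean(), abs=0.1)


@pytest.fixture(scope="module")
def standard_fit():
    cfg = SimulationConfig(params=peak_strain_params(), n_subjects=150,
                           n_visits=6, loa_mode="iid", seed=31)
    panel = simulate_cohort(cfg)
    fit = fit_model(panel, "peak_strain_pct",
                    mcmc=McmcConfig(n_chains=2, n_iterations=2000,
                                    n_burnin=500, seed=32))
    return panel, fit


class TestFitModel:
    def test_summaries_respect_ci_and_significance_rule(self, standard_fit):
        _, fit = standard_fit
        for s in fit.summaries:
            assert s.ci_low < s.ci_high
            assert s.significant == (not s.ci_low <= 0.0 <= s.ci_high)

    def test_intercepts_recovered_within_posterior_uncertainty(self, standard_fit):
        _, fit = standard_fit
        for t, truth in enumerate(PEAK_ALPHA):
            s = fit[f"alpha_{t}"]
            half = (s.ci_high - s.ci_low) / 2
            assert abs(s.mean - truth) < 2 * half

    def test_posterior_invariant_to_record_order(self, standard_fit):
        panel, fit = standard_fit
        shuffled = CohortPanel(
            panel.records.sample(frac=1.0, random_state=99).reset_index(drop=True))
        refit = fit_model(shuffled, "peak_strain_pct",
                          mcmc=McmcConfig(n_chains=2, n_iterations=2000,
                                          n_burnin=500, seed=32))
        for s, r in zip(fit.summaries, refit.summaries):
            assert s.name == r.name
            assert s.mean == r.mean
            assert (s.ci_low, s.ci_high) == (r.ci_low, r.ci_high)

    def test_reporting_horizon_limits_intercepts_not_draws(self):
        alpha9 = np.linspace(-17.9, -13.0, 9)
        params = ModelParams(alpha=alpha9, beta=0.3, sigma_y=1.5)
        cfg = SimulationConfig(params=params, n_subjects=60, n_visits=9,
                               loa_mode="iid", seed=55)
        fit = fit_model(simulate_cohort(cfg), "peak_strain_pct",
                        mcmc=McmcConfig(n_chains=2, n_iterations=800,
                                        n_burnin=300, seed=56))
        reported = {s.name for s in fit.summaries if s.name.startswith("alpha")}
        assert reported == {f"alpha_{t}" for t in range(6)}
        assert "alpha_8" in fit.draws          # fitted, just not reported

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            fit_model(CohortPanel(), "peak_strain_pct")

    def test_single_visit_subjects_insufficient(self):
        rec = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(5)], "group": "dmd",
            "visit": 0, "age_baseline": 10.0, "loa": 0.0, "ace": 0.0,
            "response_name": "peak_strain_pct", "value": -17.0,
        })
        with pytest.raises(ValueError, match=">= 2"):
            fit_model(CohortPanel(rec), "peak_strain_pct")

    def test_collinear_indicator_widens_marginals_not_their_sum(self):
        # every subject ambulatory-lost at every visit: alpha_t and gamma_loa
        # are only identified through the vague prior; their sum stays tight
        params = peak_strain_params().replace(eta_loa=1.0, gamma_loa=1.0)
        cfg = SimulationConfig(params=params, n_subjects=60, n_visits=4,
                               loa_mode="iid", seed=61)
        fit = fit_model(simulate_cohort(cfg), "peak_strain_pct",
                        mcmc=McmcConfig(n_chains=2, n_iterations=1500,
                                        n_burnin=500, seed=62))
        marginal_sd = fit.pooled("gamma_loa").std()
        sum_sd = (fit.pooled("alpha_0") + fit.pooled("gamma_loa")).std()
        assert marginal_sd > 10 * sum_sd
        assert sum_sd < 1.0


class TestTrajectoryDifferences:
    def test_drawwise_difference_equals_difference_of_means(self, standard_fit):
        _, fit = standard_fit
        diffs = trajectory_differences(fit)
        for s in diffs:
            t = int(s.name.split("-")[0].split("_")[1])
            assert s.mean == pytest.approx(
                fit[f"alpha_{t}"].mean - fit["alpha_0"].mean, abs=1e-12)

    def test_constant_trajectory_not_significant(self, standard_fit):
        _, fit = standard_fit
        frozen = dict(fit.draws)
        frozen["alpha_1"] = frozen["alpha_0"]
        fit2 = type(fit)(summaries=fit.summaries, draws=frozen,
                         alpha_names=fit.alpha_names, converged=True,
                         rhat=fit.rhat, max_visit_report=5)
        s = trajectory_differences(fit2, max_t=1)[0]
        assert s.mean == 0.0
        assert not s.significant

    def test_visit_beyond_fit_rejected(self, standard_fit):
        _, fit = standard_fit
        with pytest.raises(ValueError):
            trajectory_differences(fit, max_t=9)


class TestCovariateEffects:
    def test_indicator_recoding_flips_effect_sign(self):
        params = peak_strain_params(gamma_loa=1.5)
        cfg = SimulationConfig(params=params, n_subjects=120, n_visits=4,
                               loa_mode="iid", seed=71)
        panel = simulate_cohort(cfg)
        mc = McmcConfig(n_chains=2, n_iterations=1500, n_burnin=500, seed=72)
        g = fit_model(panel, "peak_strain_pct", mcmc=mc)["gamma_loa"]
        flipped = panel.records.copy()
        flipped["loa"] = 1.0 - flipped["loa"]
        g_flip = fit_model(CohortPanel(flipped), "peak_strain_pct",
                           mcmc=mc)["gamma_loa"]
        assert g.mean == pytest.approx(1.5, abs=0.5)
        assert g_flip.mean == pytest.approx(-g.mean, abs=0.3)

    def test_effects_are_the_fitted_rows(self, standard_fit):
        _, fit = standard_fit
        names = [s.name for s in covariate_effects(fit)]
        assert names == ["gamma_loa", "gamma_ace", "delta"]


class TestMissingData:
    def test_fit_handles_dropout_and_missing_covariates(self):
        cfg = SimulationConfig(params=peak_strain_params(), n_subjects=150,
                               n_visits=6, loa_mode="iid", dropout_prob=0.15,
                               seed=81)
        panel = simulate_cohort(cfg)
        df = panel.records.copy()
        df.loc[(df.subject_id == "dmd000") & (df.visit == 2), "value"] = np.nan
        df.loc[(df.subject_id == "dmd001") & (df.visit == 1), "loa"] = np.nan
        fit = fit_model(CohortPanel(df), "peak_strain_pct",
                        mcmc=McmcConfig(n_chains=2, n_iterations=2000,
                                        n_burnin=500, seed=82))
        assert fit.converged
        for t, truth in enumerate(PEAK_ALPHA):
            s = fit[f"alpha_{t}"]
            half = (s.ci_high - s.ci_low) / 2
            assert abs(s.mean - truth) < 3 * half
        s = fit["beta"]
        assert s.ci_low - 0.2 < 0.3 < s.ci_high + 0.2
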