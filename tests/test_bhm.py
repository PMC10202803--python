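"""Hierarchical-model engine: closed forms, limits, method agreement."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, norm

from baskettrial import (
    BHMConfig,
    CohortData,
    CohortSpec,
    fit_bhm,
    independent_posterior_prob,
    posterior_exceedance,
    posterior_prob_exceeds,
)


def single_cohort_oracle(x, n, q, tau, mu_mean=0.0, mu_sd=2.0):
    """1-D quadrature of the single-cohort logit-normal model at fixed tau.

    Marginally theta ~ Normal(mu_mean, tau^2 + mu_sd^2); posterior exceedance
    computed on a dense wide grid, independent of the package's grid code.
    """
    sd = np.hypot(tau, mu_sd)
    th = np.linspace(mu_mean - 12 * sd, mu_mean + 12 * sd, 400001)
    post = norm.pdf(th, mu_mean, sd) * binom.pmf(x, n, expit(th + logit(q)))
    post /= post.sum()
    return float(post[th > 0].sum())


def _specs(qs):
    return [
        CohortSpec(cohort_id=f"C{i}", historical_rate=q) for i, q in enumerate(qs)
    ]


class TestIndependentPosterior:
    def test_uniform_prior_no_data(self):
        assert independent_posterior_prob(0, 0, 0.10) == pytest.approx(0.90, abs=1e-12)

    def test_all_responders_closed_form(self):
        # I_q(11, 1) = q^11, so P = 1 - 0.1^11 exactly
        assert independent_posterior_prob(10, 10, 0.10) == pytest.approx(
            1.0 - 0.1**11, abs=1e-13
        )

    def test_deep_tail(self):
        assert independent_posterior_prob(0, 1000, 0.10) < 1e-12

    @pytest.mark.parametrize("x,n,q", [(-1, 5, 0.1), (6, 5, 0.1), (1, 5, 0.0), (1, 5, 1.0)])
    def test_parameter_errors(self, x, n, q):
        with pytest.raises(ValueError):
            independent_posterior_prob(x, n, q)


class TestQuadrature:
    def test_exchangeability_symmetry(self):
        specs = _specs([0.10, 0.10])
        data = [CohortData("C0", 12, 5), CohortData("C1", 12, 5)]
        probs = posterior_exceedance(data, specs, BHMConfig(grid_resolution=101, theta_bins=260))
        assert probs[0] == pytest.approx(probs[1], abs=1e-12)

    def test_independence_limit_matches_single_cohort_oracle(self):
        # fixed huge tau: borrowing vanishes, each cohort reduces to the
        # 1-D logit-normal model
        tau = 8.0
        cfg = BHMConfig(
            tau_prior_family="fixed",
            tau_prior_scale=tau,
            grid_resolution=101,
            theta_span=30.0,
            theta_bins=600,
        )
        specs = _specs([0.10, 0.15, 0.25])
        data = [CohortData("C0", 12, 5), CohortData("C1", 12, 2), CohortData("C2", 12, 7)]
        probs = posterior_exceedance(data, specs, cfg)
        for j, d in enumerate(data):
            oracle = single_cohort_oracle(
                d.x_responders, d.n_evaluable, specs[j].historical_rate, tau
            )
            assert probs[j] == pytest.approx(oracle, abs=0.01)

    def test_pooling_limit_common_posterior(self):
        # tau prior concentrated at 0 with equal nulls: all cohorts share one
        # posterior response rate
        cfg = BHMConfig(
            tau_prior_family="half_normal",
            tau_prior_scale=0.01,
            grid_resolution=101,
            theta_bins=520,
        )
        specs = _specs([0.10, 0.10, 0.10])
        data = [CohortData("C0", 12, 9), CohortData("C1", 12, 1), CohortData("C2", 12, 5)]
        summary = fit_bhm(data, specs, cfg)
        means = [summary[f"C{i}"].post_mean_p for i in range(3)]
        assert max(means) - min(means) < 0.01

    def test_shrinkage_rescues_empty_cohort(self):
        # a 0/12 cohort borrows strength from an all-responder neighbour
        specs = _specs([0.10, 0.10])
        data = [CohortData("C0", 12, 12), CohortData("C1", 12, 0)]
        probs = posterior_exceedance(data, specs, BHMConfig(grid_resolution=101, theta_bins=260))
        assert probs[1] > independent_posterior_prob(0, 12, 0.10)

    def test_monotone_in_responders(self):
        specs = _specs([0.10])
        cfg = BHMConfig(grid_resolution=101, theta_bins=260)
        probs = [
            posterior_exceedance([CohortData("C0", 10, x)], specs, cfg)[0]
            for x in range(11)
        ]
        assert np.all(np.diff(probs) > 0)

    def test_prior_only_cohort(self):
        specs = _specs([0.10])
        summary = fit_bhm([CohortData("C0", 0, 0)], specs, BHMConfig(grid_resolution=101, theta_bins=260))
        p = summary["C0"].prob_exceed_historical
        # prior predictive: theta ~ N(0, tau^2+mu_sd^2) truncated to the span,
        # slightly above 1/2 because of the symmetric-span truncation around 0
        assert 0.45 < p < 0.55

    def test_credible_interval_brackets_mean(self, specs):
        data = [CohortData(s.cohort_id, 15, 6) for s in specs]
        summary = fit_bhm(data, specs, BHMConfig(grid_resolution=101, theta_bins=260))
        for s in specs:
            cp = summary[s.cohort_id]
            lo, hi = cp.credible_95
            assert lo <= cp.post_mean_p <= hi
            assert 0.0 <= cp.prob_exceed_historical <= 1.0


class TestAccessor:
    def test_accessor_returns_stored_value(self):
        specs = _specs([0.10])
        summary = fit_bhm([CohortData("C0", 10, 7)], specs, BHMConfig(grid_resolution=101, theta_bins=260))
        assert posterior_prob_exceeds(summary, "C0") == summary["C0"].prob_exceed_historical

    def test_accessor_unknown_cohort(self):
        specs = _specs([0.10])
        summary = fit_bhm([CohortData("C0", 10, 7)], specs, BHMConfig(grid_resolution=101, theta_bins=260))
        with pytest.raises(KeyError):
            posterior_prob_exceeds(summary, "C9")


class TestMCMC:
    def test_quadrature_mcmc_agreement(self):
        # 3-cohort grid of (x, n): the two routes agree to 0.01
        specs = _specs([0.10, 0.15, 0.25])
        cases = [
            [(12, 5), (12, 2), (12, 7)],
            [(8, 0), (20, 10), (15, 4)],
            [(25, 13), (10, 1), (5, 3)],
        ]
        quad = BHMConfig(grid_resolution=101, theta_bins=260)
        for xn in cases:
            data = [
                CohortData(f"C{i}", n, x) for i, (n, x) in enumerate(xn)
            ]
            pq = posterior_exceedance(data, specs, quad)
            sm = fit_bhm(data, specs, BHMConfig(method="mcmc", n_draws=48000, n_burn=6000, seed=5))
            for i in range(3):
                assert sm[f"C{i}"].prob_exceed_historical == pytest.approx(
                    pq[i], abs=0.01
                )

    def test_mcmc_seeded_reproducibility(self):
        specs = _specs([0.10, 0.10])
        data = [CohortData("C0", 12, 4), CohortData("C1", 12, 8)]
        cfg = BHMConfig(method="mcmc", n_draws=3000, n_burn=500, seed=123)
        a = fit_bhm(data, specs, cfg)
        b = fit_bhm(data, specs, cfg)
        assert a.cohorts == b.cohorts

    def test_mcmc_diagnostics_present(self):
        specs = _specs([0.10])
        sm = fit_bhm(
            [CohortData("C0", 12, 4)],
            specs,
            BHMConfig(method="mcmc", n_draws=4000, n_burn=1000, seed=2),
        )
        assert "acceptance_theta" in sm.diagnostics
        assert "ess" in sm.diagnostics

    def test_short_chain_warns(self):
        specs = _specs([0.10])
        with pytest.warns(RuntimeWarning):
            fit_bhm(
                [CohortData("C0", 12, 4)],
                specs,
                BHMConfig(method="mcmc", n_draws=150, n_burn=10, seed=2),
            )


def test_config_validation():
    with pytest.raises(ValueError):
        BHMConfig(mu_prior_sd=0.0)
    with pytest.raises(ValueError):
        BHMConfig(tau_prior_family="cauchy")
    with pytest.raises(ValueError):
        BHMConfig(n_draws=100, n_burn=100)
    with pytest.raises(ValueError):
        CohortData("C", 5, 6)
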