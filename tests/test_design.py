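"""Interim decision engine and whole-trial simulation."""

import numpy as np
import pytest

from baskettrial import (
    BHMConfig,
    CohortSpec,
    DesignRules,
    TrialScenario,
    evaluate_interim,
    independent_posterior_prob,
    operating_characteristics,
    simulate_trial,
)
from baskettrial.simulate import generate_accrual

SIM_BHM = BHMConfig(grid_resolution=101, theta_bins=260)
# coarser still for replication-heavy property checks
COARSE_BHM = BHMConfig(grid_resolution=61, theta_bins=200)


def expected_decision(n, prob, rules):
    """Direct restatement of the published gates, kept independent of the
    implementation's control flow."""
    if n >= rules.min_n_efficacy and prob > rules.efficacy_prob:
        return "stop_efficacy"
    if n >= rules.min_n_futility and prob < rules.futility_prob:
        return "stop_futility"
    if n >= rules.max_n_primary:
        return "cap_reached"
    return "continue"


class TestEvaluateInterim:
    def test_exhaustive_grid(self):
        rules = DesignRules()
        for n in range(0, 31):
            for prob in (0.0, 0.29, 0.30, 0.31, 0.94, 0.95, 0.96, 1.0):
                dec = evaluate_interim(n, prob, rules)
                assert dec.decision == expected_decision(n, prob, rules), (n, prob)

    @pytest.mark.parametrize(
        "n, prob, expected",
        [
            (4, 0.05, "continue"),  # below the 5-patient futility gate
            (12, 0.97, "stop_efficacy"),
            (25, 0.60, "cap_reached"),
            (6, 0.29, "stop_futility"),
            (9, 0.99, "continue"),  # below the 10-patient efficacy gate
        ],
    )
    def test_published_gate_constants(self, n, prob, expected):
        assert evaluate_interim(n, prob, DesignRules()).decision == expected

    def test_closed_cohort_unchanged(self):
        dec = evaluate_interim(
            20, 0.99, DesignRules(), already_closed=True, closed_state="stop_futility"
        )
        assert dec.decision == "stop_futility"

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            evaluate_interim(5, 1.2, DesignRules())

    def test_rules_validation(self):
        with pytest.raises(ValueError):
            DesignRules(futility_prob=0.96)
        with pytest.raises(ValueError):
            DesignRules(min_n_futility=11, min_n_efficacy=10)


def _small_specs():
    return [
        CohortSpec("A", 0.10),
        CohortSpec("B", 0.15),
        CohortSpec("C", 0.25),
    ]


def _scenario(specs, orr, seed=0):
    ids = [s.cohort_id for s in specs]
    if isinstance(orr, str) and orr == "null":
        orr = {s.cohort_id: s.historical_rate for s in specs}
    return TrialScenario(cohort_ids=ids, true_orr=orr, seed=seed)


class TestSimulateTrial:
    def test_determinism(self, specs, alt_scenario):
        a = simulate_trial(alt_scenario, specs, DesignRules(), SIM_BHM, seed=4)
        b = simulate_trial(alt_scenario, specs, DesignRules(), SIM_BHM, seed=4)
        assert a == b

    def test_unattainable_thresholds_never_stop_early(self):
        specs = _small_specs()
        rules = DesignRules(futility_prob=1e-9, efficacy_prob=1 - 1e-9)
        out = simulate_trial(_scenario(specs, 0.5, seed=8), specs, rules, SIM_BHM)
        for oc in out.values():
            assert oc.decision == "cap_reached"
            assert oc.n_enrolled == rules.max_n_primary

    def test_certain_response_always_stops_for_efficacy(self):
        # with every patient responding, the posterior exceedance reaches 1
        # and each replicate ends in an early efficacy stop
        specs = _small_specs()
        for seed in range(150):
            out = simulate_trial(
                _scenario(specs, 1.0, seed=seed), specs, DesignRules(), COARSE_BHM
            )
            assert all(oc.decision == "stop_efficacy" for oc in out.values())

    def test_outcome_bookkeeping(self, specs, null_scenario):
        out = simulate_trial(null_scenario, specs, DesignRules(), SIM_BHM, seed=10)
        rules = DesignRules()
        for oc in out.values():
            assert 0 <= oc.x_responders <= oc.n_evaluable <= oc.n_enrolled <= rules.max_n_primary
            assert oc.decision in ("stop_futility", "stop_efficacy", "cap_reached")
            assert oc.assessable == (oc.n_evaluable >= rules.min_n_final)
            if oc.decision == "stop_futility":
                assert not oc.efficacy_declared


class TestOperatingCharacteristics:
    def test_degenerate_rules_zero_efficacy(self):
        specs = _small_specs()
        rules = DesignRules(efficacy_prob=1 - 1e-12)
        oc = operating_characteristics(
            _scenario(specs, "null"), specs, rules, COARSE_BHM, n_sims=100, seed=1
        )
        for row in oc.cohorts.values():
            assert row["prob_declare_efficacy"] == 0.0

    def test_power_monotone_in_true_orr(self):
        specs = _small_specs()
        rules = DesignRules()
        power = []
        ses = []
        for orr in (0.1, 0.3, 0.5, 0.7):
            oc = operating_characteristics(
                _scenario(specs, orr), specs, rules, COARSE_BHM, n_sims=250, seed=14
            )
            power.append(oc.cohorts["A"]["prob_declare_efficacy"])
            ses.append(oc.cohorts["A"]["mc_se_efficacy"])
        for k in range(3):
            slack = 2 * np.hypot(ses[k], ses[k + 1])
            assert power[k + 1] >= power[k] - slack

    def test_strong_futility_cuts_sample_size(self):
        # true ORR of 1% against a 10% null: most cohorts stop early, far
        # below the 25-patient cap
        specs = [CohortSpec("A", 0.10)]
        oc = operating_characteristics(
            _scenario(specs, 0.01), specs, DesignRules(), COARSE_BHM, n_sims=500, seed=15
        )
        assert oc.cohorts["A"]["expected_n"] < 15

    def test_independence_limit_matches_single_cohort_simulator(self):
        # with borrowing disabled, the trial machinery reduces to a
        # single-cohort design monitored with the Beta-Binomial-like
        # logit-normal posterior; replicate that design directly
        from scipy.special import expit, logit
        from scipy.stats import binom, norm

        tau = 8.0
        cfg = BHMConfig(
            tau_prior_family="fixed",
            tau_prior_scale=tau,
            grid_resolution=61,
            theta_span=30.0,
            theta_bins=600,
        )
        spec = CohortSpec("A", 0.10)
        rules = DesignRules()
        sc = _scenario([spec], 0.5)

        sd = np.hypot(tau, 2.0)
        th = np.linspace(-12 * sd, 12 * sd, 20001)
        prior = norm.pdf(th, 0.0, sd)
        pgrid = expit(th + logit(0.10))

        def oracle_prob(x, n):
            post = prior * binom.pmf(x, n, pgrid)
            post /= post.sum()
            return float(post[th > 0].sum())

        def oracle_trial(seed):
            times = generate_accrual(sc.accrual_rate["A"], rules.max_n_primary, seed=seed)
            rng = np.random.default_rng(seed + 10_000_019)
            resp = rng.random(rules.max_n_primary) < 0.5
            state = "continue"
            t = n = x = 0
            while state == "continue":
                t += rules.interim_period_weeks
                ev = times <= t - rules.first_assessment_weeks
                n, x = int(ev.sum()), int(resp[ev].sum())
                dec = evaluate_interim(n, oracle_prob(x, n), rules)
                state = dec.decision
            if state == "stop_efficacy":
                return True
            if state == "cap_reached":
                # final-analysis rule on complete data
                return oracle_prob(int(resp.sum()), rules.max_n_primary) > rules.efficacy_prob
            return False

        n_sims = 200
        oc = operating_characteristics(sc, [spec], rules, cfg, n_sims=n_sims, seed=16)
        pkg = oc.cohorts["A"]["prob_declare_efficacy"]
        oracle = np.mean([oracle_trial(s) for s in range(n_sims)])
        se = np.sqrt(pkg * (1 - pkg) / n_sims + oracle * (1 - oracle) / n_sims + 1e-9)
        assert abs(pkg - oracle) <= max(2 * se, 0.02)

    def test_nsims_floor(self, specs, null_scenario):
        with pytest.raises(ValueError):
            operating_characteristics(
                null_scenario, specs, DesignRules(), SIM_BHM, n_sims=50
            )
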