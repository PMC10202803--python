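"""Interim decision rules and whole-trial simulation of the basket design.

The design: interim analyses every 12 weeks on a global calendar.  At each
look the hierarchical model is refit on all primary-cohort evaluable data and
each open cohort's posterior probability of exceeding its historical response
rate gates the decision — stop for futility when it falls below 0.30 with at
least 5 evaluable patients, stop for efficacy when it exceeds 0.95 with at
least 10, cap primary enrollment at 25 per cohort, and require at least 2
evaluable patients for a cohort to be assessable at the final analysis.
Cohorts closed early for efficacy may re-open as expansion cohorts in real
trials; expansion patients never contribute to the model, so the simulator
tracks primary enrollment only.

Operating characteristics (power when every true ORR sits at the clinically
meaningful 50%, type I error when every true ORR sits at its historical null,
expected sample size, stopping probabilities, ORR estimation error) are
estimated by replicating whole trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bhm import BHMConfig, CohortData, posterior_exceedance
from .cohorts import CohortSpec
from .response import RULE_REGISTRY, classify_responder
from .simulate import TrialScenario, generate_patients

__all__ = [
    "DesignRules",
    "InterimDecision",
    "CohortOutcome",
    "OperatingCharacteristics",
    "evaluate_interim",
    "simulate_trial",
    "operating_characteristics",
]

_OPEN = "continue"
_CLOSED_STATES = ("stop_futility", "stop_efficacy", "cap_reached")


@dataclass(frozen=True)
class DesignRules:
    """Gate constants of the adaptive design."""

    interim_period_weeks: float = 12.0
    futility_prob: float = 0.30
    efficacy_prob: float = 0.95
    min_n_futility: int = 5
    min_n_efficacy: int = 10
    max_n_primary: int = 25
    min_n_final: int = 2
    #: first disease assessment this many weeks after enrollment; a patient
    #: contributes interim response data only once assessed
    first_assessment_weeks: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 < self.futility_prob < self.efficacy_prob < 1.0:
            raise ValueError("need 0 < futility_prob < efficacy_prob < 1")
        if not self.min_n_futility <= self.min_n_efficacy <= self.max_n_primary:
            raise ValueError("need min_n_futility <= min_n_efficacy <= max_n_primary")
        if self.min_n_final < 1:
            raise ValueError("min_n_final must be >= 1")
        if self.interim_period_weeks <= 0:
            raise ValueError("interim_period_weeks must be positive")


@dataclass(frozen=True)
class InterimDecision:
    cohort_id: str
    decision: str
    n_evaluable: int
    prob_exceed: float
    interim_index: int


def evaluate_interim(
    n_evaluable: int,
    prob_exceed: float,
    rules: DesignRules,
    already_closed: bool = False,
    closed_state: str = "stop_futility",
    cohort_id: str = "",
    interim_index: int = 0,
) -> InterimDecision:
    """Apply the interim gates to one cohort's (n, posterior exceedance).

    Efficacy is checked before futility; a cohort at its enrollment cap with
    neither stop firing is reported ``cap_reached``.  Closed cohorts return
    their closed state unchanged.
    """
    if not 0.0 <= prob_exceed <= 1.0:
        raise ValueError(f"prob_exceed must lie in [0, 1], got {prob_exceed}")
    if n_evaluable < 0:
        raise ValueError("n_evaluable must be nonnegative")
    if already_closed:
        decision = closed_state
    elif n_evaluable >= rules.min_n_efficacy and prob_exceed > rules.efficacy_prob:
        decision = "stop_efficacy"
    elif n_evaluable >= rules.min_n_futility and prob_exceed < rules.futility_prob:
        decision = "stop_futility"
    elif n_evaluable >= rules.max_n_primary:
        decision = "cap_reached"
    else:
        decision = _OPEN
    return InterimDecision(
        cohort_id=cohort_id,
        decision=decision,
        n_evaluable=n_evaluable,
        prob_exceed=prob_exceed,
        interim_index=interim_index,
    )


@dataclass
class CohortOutcome:
    cohort_id: str
    decision: str
    n_enrolled: int
    n_evaluable: int
    x_responders: int
    interim_closed: Optional[int]
    final_prob_exceed: float
    efficacy_declared: bool
    assessable: bool


def _responder_flags(
    scenario: TrialScenario, specs: Sequence[CohortSpec], rules: DesignRules, seed: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Enrollment times and responder indicators per cohort for one replicate."""
    sim_scenario = TrialScenario(
        cohort_ids=scenario.cohort_ids,
        true_orr=scenario.true_orr,
        response_split=scenario.response_split,
        accrual_rate=scenario.accrual_rate,
        median_dor_weeks=scenario.median_dor_weeks,
        median_ttp_weeks=scenario.median_ttp_weeks,
        median_os_weeks=scenario.median_os_weeks,
        rater_agreement=scenario.rater_agreement,
        # design simulation follows the trial to completion: no administrative
        # cutoff truncates responder status
        cutoff_weeks=1e9,
        seed=seed,
        cohort_sizes={c: rules.max_n_primary for c in scenario.cohort_ids},
        category_weights=scenario.category_weights,
    )
    spec_by_id = {s.cohort_id: s for s in specs}
    records = generate_patients(sim_scenario, specs, seed=seed)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cid in scenario.cohort_ids:
        recs = [r for r in records if r.cohort_id == cid]
        times = np.array([r.enrollment_week for r in recs])
        klass = spec_by_id[cid].cohort_class
        resp = np.array(
            [classify_responder(r.best_response_inv, klass) for r in recs], dtype=bool
        )
        out[cid] = (times, resp)
    return out


def simulate_trial(
    scenario: TrialScenario,
    specs: Sequence[CohortSpec],
    rules: DesignRules,
    bhm_config: Optional[BHMConfig] = None,
    seed: Optional[int] = None,
    max_interims: int = 400,
) -> dict[str, CohortOutcome]:
    """Run one replicate of the basket trial and return per-cohort outcomes.

    Accrual and responses come from the synthetic-data generator; at every
    12-week calendar tick the hierarchical model is refit jointly on the
    evaluable primary data of all cohorts (closed cohorts keep contributing
    their frozen data to the borrowing) and the interim gates are applied to
    open cohorts.  After all cohorts have closed and every enrolled patient
    has been assessed, a final joint fit decides the final-analysis success
    rule for cohorts that reached the cap without stopping; a cohort with
    fewer than ``min_n_final`` evaluable patients is flagged not assessable.
    """
    bhm_config = bhm_config or BHMConfig()
    seed = scenario.seed if seed is None else seed
    spec_by_id = {s.cohort_id: s for s in specs}
    cohort_ids = list(scenario.cohort_ids)
    sim = _responder_flags(scenario, specs, rules, seed)

    state = {c: _OPEN for c in cohort_ids}
    close_time = {c: math.inf for c in cohort_ids}  # enrollment closes here
    interim_closed: dict[str, Optional[int]] = {c: None for c in cohort_ids}
    lag = rules.first_assessment_weeks

    def counts_at(t: float) -> list[CohortData]:
        data = []
        for cid in cohort_ids:
            times, resp = sim[cid]
            enrolled = times <= min(t, close_time[cid])
            evaluable = enrolled & (times <= t - lag)
            data.append(
                CohortData(
                    cohort_id=cid,
                    n_evaluable=int(evaluable.sum()),
                    x_responders=int(resp[evaluable].sum()),
                )
            )
        return data

    def all_assessed(t: float) -> bool:
        for cid in cohort_ids:
            times, _ = sim[cid]
            enrolled = times <= min(t, close_time[cid])
            if np.any(times[enrolled] > t - lag):
                return False
        return True

    t = 0.0
    k = 0
    probs = np.full(len(cohort_ids), np.nan)
    while k < max_interims:
        k += 1
        t = k * rules.interim_period_weeks
        data = counts_at(t)
        probs = posterior_exceedance(data, specs, bhm_config)
        for i, cid in enumerate(cohort_ids):
            if state[cid] != _OPEN:
                continue
            dec = evaluate_interim(
                data[i].n_evaluable, float(probs[i]), rules, cohort_id=cid, interim_index=k
            )
            if dec.decision in ("stop_futility", "stop_efficacy"):
                state[cid] = dec.decision
                close_time[cid] = t
                interim_closed[cid] = k
            elif dec.decision == "cap_reached":
                state[cid] = "cap_reached"
                interim_closed[cid] = k
                # cap closes enrollment only; data are already complete
        if all(s != _OPEN for s in state.values()) and all_assessed(t):
            break

    # final joint analysis on complete data
    final_data = counts_at(t)
    final_probs = posterior_exceedance(final_data, specs, bhm_config)
    outcomes: dict[str, CohortOutcome] = {}
    for i, cid in enumerate(cohort_ids):
        d = final_data[i]
        times, _ = sim[cid]
        n_enrolled = int((times <= min(t, close_time[cid])).sum())
        assessable = d.n_evaluable >= rules.min_n_final
        if state[cid] == "stop_efficacy":
            declared = True
        elif state[cid] == "stop_futility":
            declared = False
        else:  # cap_reached (or accrual exhausted): final-analysis rule
            declared = assessable and float(final_probs[i]) > rules.efficacy_prob
        outcomes[cid] = CohortOutcome(
            cohort_id=cid,
            decision=state[cid],
            n_enrolled=n_enrolled,
            n_evaluable=d.n_evaluable,
            x_responders=d.x_responders,
            interim_closed=interim_closed[cid],
            final_prob_exceed=float(final_probs[i]),
            efficacy_declared=declared,
            assessable=assessable,
        )
    return outcomes


@dataclass
class OperatingCharacteristics:
    """Per-cohort frequentist properties of the design, with MC errors."""

    n_sims: int
    cohorts: dict[str, dict[str, float]]

    def table(self):
        import pandas as pd

        return pd.DataFrame(self.cohorts).T


def operating_characteristics(
    scenario: TrialScenario,
    specs: Sequence[CohortSpec],
    rules: DesignRules,
    bhm_config: Optional[BHMConfig] = None,
    n_sims: int = 500,
    seed: int = 0,
) -> OperatingCharacteristics:
    """Estimate the design's operating characteristics by replication.

    ``prob_declare_efficacy`` counts early efficacy stops and final-analysis
    successes; with all true ORRs at the 50% target it estimates power, and
    with all true ORRs at the historical nulls it estimates type I error.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100 for meaningful MC estimates")
    bhm_config = bhm_config or BHMConfig()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    cohort_ids = list(scenario.cohort_ids)
    declared = {c: 0 for c in cohort_ids}
    futility = {c: 0 for c in cohort_ids}
    enrolled = {c: [] for c in cohort_ids}
    orr_err = {c: [] for c in cohort_ids}
    for s in rep_seeds:
        outcomes = simulate_trial(scenario, specs, rules, bhm_config, seed=int(s))
        for cid, oc in outcomes.items():
            declared[cid] += oc.efficacy_declared
            futility[cid] += oc.decision == "stop_futility"
            enrolled[cid].append(oc.n_enrolled)
            if oc.n_evaluable > 0:
                orr_err[cid].append(
                    oc.x_responders / oc.n_evaluable - scenario.true_orr[cid]
                )
    out: dict[str, dict[str, float]] = {}
    for cid in cohort_ids:
        p_eff = declared[cid] / n_sims
        p_fut = futility[cid] / n_sims
        errs = np.array(orr_err[cid])
        out[cid] = {
            "prob_declare_efficacy": p_eff,
            "prob_stop_futility": p_fut,
            "expected_n": float(np.mean(enrolled[cid])),
            "orr_bias": float(errs.mean()) if errs.size else float("nan"),
            "orr_rmse": float(np.sqrt((errs**2).mean())) if errs.size else float("nan"),
            "mc_se_efficacy": math.sqrt(max(p_eff * (1 - p_eff), 1e-12) / n_sims),
            "mc_se_futility": math.sqrt(max(p_fut * (1 - p_fut), 1e-12) / n_sims),
        }
    return OperatingCharacteristics(n_sims=n_sims, cohorts=out)
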