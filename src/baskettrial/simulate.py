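"""Synthetic patient-level basket-trial data with the structure the analyses assume.

The generator emulates, per cohort: Bernoulli responder status at a stated
true ORR; categorical best responses with frequencies defaulting to the
published trial proportions; homogeneous-Poisson accrual; exponential event
times parameterized by their medians, with death generated as progression
plus an exponential post-progression increment (so overall survival never
precedes progression); administrative right-censoring at an analysis cutoff;
and an independent reviewer who reproduces the investigator's category with a
stated agreement probability.

Time unit is weeks throughout; reports use 1 month = 4.348 weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .cohorts import CohortSpec, reported_best_response_counts, reported_enrollment
from .records import PatientRecord
from .response import RULE_REGISTRY, classify_responder, is_evaluable

__all__ = [
    "TrialScenario",
    "generate_accrual",
    "generate_patients",
    "WEEKS_PER_MONTH",
    "FIRST_ASSESSMENT_WEEKS",
    "ConfigurationError",
]

WEEKS_PER_MONTH = 4.348
#: disease assessments occur every 8 weeks, the first 8 weeks after first dose
FIRST_ASSESSMENT_WEEKS = 8.0
# floor on the post-progression survival increment's median, in weeks
_MIN_POST_PROGRESSION_MEDIAN = 4.0

PerCohort = Union[float, Mapping[str, float]]


class ConfigurationError(ValueError):
    """Scenario/design configuration mismatch (e.g. unknown cohort id)."""


def _broadcast(value: PerCohort, cohort_ids: Sequence[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [c for c in cohort_ids if c not in value]
        if missing:
            raise ConfigurationError(f"{name} missing cohorts {missing}")
        return {c: float(value[c]) for c in cohort_ids}
    return {c: float(value) for c in cohort_ids}


@dataclass
class TrialScenario:
    """Simulation truth for one basket trial.

    Defaults state a plausible trial-like world: accrual of one patient per
    four weeks per cohort, a 60% investigator/independent agreement (the
    published concordances span 46–67%), exponential duration-of-response,
    time-to-progression and overall-survival medians of 52, 30 and 78 weeks
    (roughly the published 12-, 7- and 18-month scales), and a five-year
    administrative cutoff.  Cohort sizes default to the published enrollment
    where the cohort id is known, otherwise to 25 (the primary-cohort cap).
    """

    cohort_ids: Sequence[str]
    true_orr: PerCohort
    response_split: PerCohort = 0.15
    accrual_rate: PerCohort = 0.25
    median_dor_weeks: PerCohort = 52.0
    median_ttp_weeks: PerCohort = 30.0
    median_os_weeks: PerCohort = 78.0
    rater_agreement: float = 0.60
    cutoff_weeks: float = 260.0
    seed: int = 0
    cohort_sizes: Optional[Mapping[str, int]] = None
    #: optional per-cohort {category: weight}; overrides the published defaults
    category_weights: Optional[Mapping[str, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        self.cohort_ids = tuple(self.cohort_ids)
        if not self.cohort_ids:
            raise ConfigurationError("scenario needs at least one cohort")
        self.true_orr = _broadcast(self.true_orr, self.cohort_ids, "true_orr")
        self.response_split = _broadcast(self.response_split, self.cohort_ids, "response_split")
        self.accrual_rate = _broadcast(self.accrual_rate, self.cohort_ids, "accrual_rate")
        self.median_dor_weeks = _broadcast(self.median_dor_weeks, self.cohort_ids, "median_dor_weeks")
        self.median_ttp_weeks = _broadcast(self.median_ttp_weeks, self.cohort_ids, "median_ttp_weeks")
        self.median_os_weeks = _broadcast(self.median_os_weeks, self.cohort_ids, "median_os_weeks")
        for name in ("true_orr", "response_split"):
            for c, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"{name}[{c}]={v} outside [0, 1]")
        for name in ("median_dor_weeks", "median_ttp_weeks", "median_os_weeks"):
            for c, v in getattr(self, name).items():
                if v <= 0:
                    raise ConfigurationError(f"{name}[{c}]={v} must be positive")
        for c, v in self.accrual_rate.items():
            if v <= 0:
                raise ConfigurationError(f"accrual_rate[{c}]={v} must be positive")
        if not 0.0 <= self.rater_agreement <= 1.0:
            raise ConfigurationError("rater_agreement outside [0, 1]")
        if self.cutoff_weeks <= 0:
            raise ConfigurationError("cutoff_weeks must be positive")
        if self.cohort_sizes is None:
            known = reported_enrollment()
            self.cohort_sizes = {c: known.get(c, 25) for c in self.cohort_ids}
        else:
            self.cohort_sizes = {c: int(self.cohort_sizes[c]) for c in self.cohort_ids}


def generate_accrual(
    rate: float, n_max: int, seed: Union[int, np.random.Generator, None] = None
) -> np.ndarray:
    """Enrollment times (weeks) of a homogeneous Poisson process.

    Runs the process until exactly ``n_max`` arrivals; inter-arrival times are
    i.i.d. Exponential(rate).
    """
    if rate <= 0:
        raise ConfigurationError(f"accrual rate must be positive, got {rate}")
    if n_max < 0:
        raise ConfigurationError(f"n_max must be nonnegative, got {n_max}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.cumsum(rng.exponential(1.0 / rate, size=int(n_max)))


def _split_weights(
    counts_or_weights: Mapping[str, float], rule, response_split: float
) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
    """Normalize weights separately over responder and non-responder categories."""
    resp_cats = [c for c in rule.vocabulary if c in rule.responder_set]
    non_cats = [c for c in rule.vocabulary if c not in rule.responder_set]
    rw = np.array([float(counts_or_weights.get(c, 0.0)) for c in resp_cats])
    nw = np.array([float(counts_or_weights.get(c, 0.0)) for c in non_cats])
    if rw.sum() <= 0:
        # fallback: response_split mass spread over the CR-like categories,
        # the remainder on PR
        rw = np.array(
            [
                (response_split / max(len(resp_cats) - 1, 1)) if c != "PR" else (1 - response_split)
                for c in resp_cats
            ]
        )
        if len(resp_cats) == 1:
            rw = np.ones(1)
    if nw.sum() <= 0:
        nw = np.array([{"SD": 0.5, "PD": 0.4, "NE": 0.1}.get(c, 0.0) for c in non_cats])
    return resp_cats, rw / rw.sum(), non_cats, nw / nw.sum()


def _default_weights(cohort_id: str, cohort_class: str) -> Optional[Mapping[str, float]]:
    fixtures = reported_best_response_counts()
    if cohort_id in fixtures:
        counts = fixtures[cohort_id]["counts"]
        rule = RULE_REGISTRY[cohort_class]
        if set(counts) <= set(rule.vocabulary):
            return counts
    return None


def generate_patients(
    scenario: TrialScenario,
    specs: Sequence[CohortSpec],
    seed: Optional[int] = None,
) -> list[PatientRecord]:
    """Draw one patient-level dataset under the scenario.

    Per cohort: enrollment via Poisson accrual; responder status Bernoulli at
    the true ORR; best-response categories from the (responder- or
    non-responder-conditional) category weights; response onset at the first
    scheduled assessment; exponential duration of response, time to
    progression and post-progression survival; administrative censoring at
    ``scenario.cutoff_weeks``.  Patients enrolled after the cutoff are
    dropped.  An independent-review category is generated for solid-tumor and
    glioma cohorts only, matching the investigator with probability
    ``rater_agreement`` and resampled uniformly from the non-matching
    categories otherwise.
    """
    spec_by_id = {s.cohort_id: s for s in specs}
    unknown = [c for c in scenario.cohort_ids if c not in spec_by_id]
    if unknown:
        raise ConfigurationError(f"scenario cohorts without specs: {unknown}")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    ln2 = math.log(2.0)
    records: list[PatientRecord] = []
    cutoff = scenario.cutoff_weeks

    for cid in scenario.cohort_ids:
        spec = spec_by_id[cid]
        rule = RULE_REGISTRY[spec.cohort_class]
        n = int(scenario.cohort_sizes[cid])
        enroll = generate_accrual(scenario.accrual_rate[cid], n, rng)
        weights = None
        if scenario.category_weights and cid in scenario.category_weights:
            weights = scenario.category_weights[cid]
        if weights is None:
            weights = _default_weights(cid, spec.cohort_class)
        if weights is None:
            weights = {}
        resp_cats, rw, non_cats, nw = _split_weights(
            weights, rule, scenario.response_split[cid]
        )
        p = scenario.true_orr[cid]
        dor_scale = scenario.median_dor_weeks[cid] / ln2
        ttp_scale = scenario.median_ttp_weeks[cid] / ln2
        post_scale = (
            max(
                scenario.median_os_weeks[cid] - scenario.median_ttp_weeks[cid],
                _MIN_POST_PROGRESSION_MEDIAN,
            )
            / ln2
        )
        has_independent_review = spec.cohort_class == "solid_glioma"

        for i in range(n):
            t0 = float(enroll[i])
            if t0 >= cutoff:
                continue
            is_resp = rng.random() < p
            if is_resp:
                category = resp_cats[rng.choice(len(resp_cats), p=rw)]
                onset = t0 + FIRST_ASSESSMENT_WEEKS
                progression = onset + rng.exponential(dor_scale)
            else:
                category = non_cats[rng.choice(len(non_cats), p=nw)]
                onset = None
                progression = t0 + rng.exponential(ttp_scale)
            death = progression + rng.exponential(post_scale)

            # administrative censoring: unobserved events become None and the
            # best response downgrades to what the cutoff could have shown
            if is_resp and onset is not None and onset > cutoff:
                category, onset, is_resp = "NE", None, False
                progression = None
            if progression is not None and progression > cutoff:
                progression = None
                if category == "PD":
                    category = "SD"
            if progression is None or death > cutoff:
                death_obs = None
            else:
                death_obs = death

            if category == "NE":
                last = t0
                onset = progression = death_obs = None
                n_post = 0
            else:
                last = min(cutoff, death_obs) if death_obs is not None else cutoff
                n_post = max(int((last - t0) // FIRST_ASSESSMENT_WEEKS), 0)
                if is_resp:
                    n_post = max(n_post, 1)

            ind = None
            if has_independent_review:
                if rng.random() < scenario.rater_agreement:
                    ind = category
                else:
                    others = [c for c in rule.vocabulary if c != category]
                    ind = others[rng.choice(len(others))]

            arm = "primary" if i < spec.max_primary_n else "expansion"
            rec = PatientRecord(
                patient_id=f"{cid}-{i + 1:04d}",
                cohort_id=cid,
                arm=arm,
                enrollment_week=t0,
                evaluable=True,
                best_response_inv=category,
                best_response_ind=ind,
                response_onset_week=onset,
                progression_week=progression,
                death_week=death_obs,
                last_assessment_week=last,
                n_post_baseline_assessments=n_post,
            )
            rec.evaluable = is_evaluable(rec)
            records.append(rec)
    return records
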