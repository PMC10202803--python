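"""Frequentist efficacy analysis: exact binomial ORR intervals, endpoint
derivation under right-censoring, and the per-cohort response table.

ORR confidence intervals are exact two-sided Clopper–Pearson intervals
(binomial tail inversion, computed via beta quantiles).  Duration of response
(DoR), progression-free survival (PFS) and overall survival (OS) are derived
from patient records: DoR runs from the first documented response to
progression or death and exists only for responders; PFS runs from first dose
to progression or death from any cause; OS runs from first dose to death.
An endpoint not observed during follow-up is right-censored at the last
disease assessment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .cohorts import CohortSpec
from .records import PatientRecord
from .response import RULE_REGISTRY, classify_responder

__all__ = [
    "BinomialCI",
    "TimeToEventRecord",
    "clopper_pearson",
    "derive_endpoint",
    "orr_report",
    "orr_report_from_counts",
    "DataIntegrityError",
]

ENDPOINTS = ("DoR", "PFS", "OS")


class DataIntegrityError(ValueError):
    """Raised when a record violates a structural assumption of an analysis."""


@dataclass(frozen=True)
class BinomialCI:
    """Responders x of n with an exact two-sided confidence interval."""

    x: int
    n: int
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def as_percent(self) -> tuple[int, float, float]:
        """(ORR% rounded to integer, lower%, upper% to one decimal)."""
        return (
            int(round(100.0 * self.point)),
            round(100.0 * self.lower, 1),
            round(100.0 * self.upper, 1),
        )


def clopper_pearson(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact two-sided Clopper–Pearson interval for a binomial proportion.

    lower = Beta quantile(alpha/2; x, n-x+1), 0 when x = 0;
    upper = Beta quantile(1-alpha/2; x+1, n-x), 1 when x = n.
    """
    if n < 1:
        raise ValueError("Clopper-Pearson interval undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return BinomialCI(x=x, n=n, point=x / n, lower=lower, upper=upper, level=level)


@dataclass(frozen=True)
class TimeToEventRecord:
    patient_id: str
    time_weeks: float
    event: bool
    endpoint: str

    def __post_init__(self) -> None:
        if self.time_weeks < 0:
            raise ValueError("time_weeks must be nonnegative")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")


def _first_event_week(rec: PatientRecord) -> Optional[float]:
    """Earliest of progression and death, None if neither observed."""
    times = [t for t in (rec.progression_week, rec.death_week) if t is not None]
    return min(times) if times else None


def derive_endpoint(
    patients: Sequence[PatientRecord],
    endpoint: str,
    cutoff_weeks: Optional[float] = None,
    cohort_class: str = "solid_glioma",
) -> list[TimeToEventRecord]:
    """Build time-to-event records for one endpoint from patient records.

    The enrollment week stands in for the first-dose time.  Patients whose
    event was not observed are censored at their last disease assessment
    (capped at ``cutoff_weeks`` when given).  DoR records exist only for
    responders; a responder without a documented response onset is a data
    integrity error.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    out: list[TimeToEventRecord] = []
    for rec in patients:
        origin = rec.enrollment_week
        censor_at = rec.last_assessment_week
        if censor_at is None:
            censor_at = rec.enrollment_week
        if cutoff_weeks is not None:
            censor_at = min(censor_at, cutoff_weeks)
        if endpoint == "DoR":
            if not classify_responder(rec.best_response_inv, cohort_class):
                continue
            if rec.response_onset_week is None:
                raise DataIntegrityError(
                    f"{rec.patient_id}: responder without a response onset time"
                )
            origin = rec.response_onset_week
            event_week = _first_event_week(rec)
        elif endpoint == "PFS":
            event_week = _first_event_week(rec)
        else:  # OS
            event_week = rec.death_week
        if event_week is not None:
            time = event_week - origin
            event = True
        else:
            time = censor_at - origin
            event = False
        out.append(
            TimeToEventRecord(
                patient_id=rec.patient_id,
                time_weeks=max(float(time), 0.0),
                event=event,
                endpoint=endpoint,
            )
        )
    return out


def orr_report(
    patients: Sequence[PatientRecord],
    specs: Sequence[CohortSpec],
    level: float = 0.95,
    assessment: str = "inv",
) -> pd.DataFrame:
    """Per-cohort best-response table with exact confidence intervals.

    Semantics follow the published table: best-response category counts; the
    responder count x under the cohort's responder rule (minor responses and
    non-evaluable patients never count as responders but stay in the
    denominator); ORR as an integer percentage; exact CI bounds to one
    decimal.  Cohorts with no records are omitted with a warning.
    """
    import warnings as _w

    attr = {"inv": "best_response_inv", "ind": "best_response_ind"}[assessment]
    rows = []
    for spec in specs:
        recs = [p for p in patients if p.cohort_id == spec.cohort_id]
        if assessment == "ind":
            recs = [p for p in recs if p.best_response_ind is not None]
        if not recs:
            _w.warn(f"cohort {spec.cohort_id}: no records, omitted from ORR report")
            continue
        rule = RULE_REGISTRY[spec.cohort_class]
        counts = {cat: 0 for cat in rule.vocabulary}
        x = 0
        for p in recs:
            cat = getattr(p, attr)
            if cat is not None:
                counts[cat] += 1
            x += classify_responder(cat, spec.cohort_class)
        ci = clopper_pearson(x, len(recs), level)
        orr_pct, lo, hi = ci.as_percent()
        rows.append(
            {
                "cohort_id": spec.cohort_id,
                **counts,
                "x": x,
                "n": len(recs),
                "orr_pct": orr_pct,
                "ci_lower_pct": lo,
                "ci_upper_pct": hi,
            }
        )
    return pd.DataFrame(rows).set_index("cohort_id") if rows else pd.DataFrame()


def orr_report_from_counts(
    counts_by_cohort: dict[str, dict],
    specs: Sequence[CohortSpec],
    level: float = 0.95,
) -> pd.DataFrame:
    """ORR table computed directly from per-category count vectors.

    Accepts the structure returned by
    :func:`baskettrial.cohorts.reported_best_response_counts`.
    """
    spec_by_id = {s.cohort_id: s for s in specs}
    rows = []
    for cid, entry in counts_by_cohort.items():
        spec = spec_by_id[cid]
        rule = RULE_REGISTRY[spec.cohort_class]
        counts = entry["counts"]
        x = sum(c for cat, c in counts.items() if cat in rule.responder_set)
        n = sum(counts.values())
        ci = clopper_pearson(x, n, level)
        orr_pct, lo, hi = ci.as_percent()
        rows.append(
            {
                "cohort_id": cid,
                "x": x,
                "n": n,
                "orr_pct": orr_pct,
                "ci_lower_pct": lo,
                "ci_upper_pct": hi,
            }
        )
    return pd.DataFrame(rows).set_index("cohort_id")
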