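"""Kaplan-Meier estimation with Greenwood variance, complementary log-log
pointwise intervals, and Brookmeyer-Crowley confidence intervals for the
median survival time.

The median interval inverts a test of S(t) = 0.5 on the cloglog scale
g(S) = log(-log S): the interval collects the event times t where
|g(S(t)) - g(0.5)| <= z * SE_g(t), with SE from Greenwood's formula via the
delta method.  A side that the follow-up cannot bound is reported as
NOT_REACHED, as is a median the curve never crosses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy.stats import norm

from .efficacy import TimeToEventRecord

__all__ = ["NOT_REACHED", "SurvivalEstimate", "km_fit", "median_ci_brookmeyer_crowley"]


class _NotReached:
    """Sentinel for survival quantities beyond the observed follow-up."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_REACHED"


NOT_REACHED = _NotReached()
MaybeTime = Union[float, _NotReached]


@dataclass
class SurvivalEstimate:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: MaybeTime
    median_ci: Tuple[MaybeTime, MaybeTime]
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _extract(records) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise ValueError("need at least one record")
    if isinstance(records[0], TimeToEventRecord):
        times = np.array([r.time_weeks for r in records], dtype=float)
        events = np.array([r.event for r in records], dtype=bool)
    else:
        times, events = records
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    return times, events


def km_fit(records, level: float = 0.95) -> SurvivalEstimate:
    """Kaplan-Meier fit from time-to-event records (or a (times, events) pair).

    Ties are resolved with events before censorings at equal times (the
    standard product-limit convention).  Pointwise confidence bounds use the
    cloglog transformation S^(exp(+-z*se)), with se the delta-method standard
    error of log(-log S).
    """
    times, events = _extract(records)
    n = len(times)
    uniq = np.unique(times[events])
    surv = []
    gvar = []
    lo = []
    hi = []
    nrisk = []
    nevent = []
    s = 1.0
    cumvar = 0.0  # sum d / (n (n - d))
    z = norm.ppf(0.5 + level / 2.0)
    for t in uniq:
        at_risk = int(np.sum(times >= t))  # events at t count as at risk
        d = int(np.sum(times[events] == t))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            cumvar += d / (at_risk * (at_risk - d))
        else:
            cumvar = math.inf
        nrisk.append(at_risk)
        nevent.append(d)
        surv.append(s)
        gvar.append(s * s * cumvar if math.isfinite(cumvar) else math.inf)
        if 0.0 < s < 1.0 and math.isfinite(cumvar):
            se_cll = math.sqrt(cumvar) / abs(math.log(s))
            lo.append(s ** math.exp(z * se_cll))
            hi.append(s ** math.exp(-z * se_cll))
        else:
            lo.append(0.0 if s <= 0.0 else s)
            hi.append(1.0 if s >= 1.0 else s)
    surv = np.array(surv)
    est = SurvivalEstimate(
        event_times=uniq,
        n_risk=np.array(nrisk),
        n_event=np.array(nevent),
        survival=surv,
        greenwood_var=np.array(gvar),
        ci_lower=np.array(lo),
        ci_upper=np.array(hi),
        median=NOT_REACHED,
        median_ci=(NOT_REACHED, NOT_REACHED),
        n_total=n,
    )
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    est.median = float(uniq[below[0]]) if below.size else NOT_REACHED
    est.median_ci = median_ci_brookmeyer_crowley(est, level)[1:]
    return est


def median_ci_brookmeyer_crowley(
    est: SurvivalEstimate, level: float = 0.95
) -> Tuple[MaybeTime, MaybeTime, MaybeTime]:
    """(median, lower, upper) via Brookmeyer-Crowley test inversion.

    Collects event times whose cloglog-scale distance from S = 0.5 is within
    z standard errors (equivalently: times whose pointwise band contains
    one half).  The lower limit is the first qualifying event time; the
    upper limit is the first event time beyond the qualifying set, where the
    whole band has fallen below one half — the standard inversion
    convention.  A side the follow-up cannot bound is NOT_REACHED; with no
    qualifying times both sides are NOT_REACHED.
    """
    z = norm.ppf(0.5 + level / 2.0)
    g_half = math.log(-math.log(0.5))
    qualify = []
    for t, s, v in zip(est.event_times, est.survival, est.greenwood_var):
        if not (0.0 < s < 1.0) or not math.isfinite(v) or v <= 0.0:
            continue
        # delta method: Var g(S) = Var(S) / (S log S)^2
        se_g = math.sqrt(v) / abs(s * math.log(s))
        if abs(math.log(-math.log(s)) - g_half) <= z * se_g:
            qualify.append(float(t))
    median = est.median
    if not qualify:
        return (median, NOT_REACHED, NOT_REACHED)
    lower: MaybeTime = min(qualify)
    last_qualifying = max(qualify)
    beyond = est.event_times[est.event_times > last_qualifying]
    upper: MaybeTime = float(beyond[0]) if beyond.size else NOT_REACHED
    return (median, lower, upper)
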