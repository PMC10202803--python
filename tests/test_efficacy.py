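"""Exact binomial intervals, endpoint derivation, and the ORR table."""

import numpy as np
import pytest
from scipy.stats import binom

from baskettrial import (
    PatientRecord,
    classify_responder,
    clopper_pearson,
    default_cohort_specs,
    derive_endpoint,
    orr_report,
    orr_report_from_counts,
    reported_best_response_counts,
)
from baskettrial.efficacy import DataIntegrityError

# published (x, n) pairs with their printed ORR% and one-decimal CI bounds
PUBLISHED = [
    ("ATC", 20, 36, 56, 38.1, 72.1),
    ("BTC", 23, 43, 53, 37.7, 68.8),
    ("ASI", 2, 3, 67, 9.4, 99.2),
    ("LGG", 7, 13, 54, 25.1, 80.8),
    ("HGG", 15, 45, 33, 20.0, 49.0),
    ("HCL", 49, 55, 89, 77.8, 95.9),
    ("MM", 5, 10, 50, 18.7, 81.3),
]


@pytest.mark.parametrize("cohort,x,n,orr,lo,hi", PUBLISHED)
def test_clopper_pearson_published_values(cohort, x, n, orr, lo, hi):
    got_orr, got_lo, got_hi = clopper_pearson(x, n).as_percent()
    assert (got_orr, got_lo, got_hi) == (orr, lo, hi)


def test_boundaries():
    assert clopper_pearson(0, 10).lower == 0.0
    assert clopper_pearson(10, 10).upper == 1.0
    ci = clopper_pearson(0, 10)
    assert 0.0 <= ci.lower <= ci.point <= ci.upper <= 1.0


def test_undefined_for_empty_sample():
    with pytest.raises(ValueError):
        clopper_pearson(0, 0)


def test_tail_inversion_oracle():
    # the exact interval inverts binomial tail tests: for 0 < x the lower
    # bound p_lo solves P(X >= x | p_lo) = alpha/2, and for x < n the upper
    # bound solves P(X <= x | p_hi) = alpha/2; verify by brute-force bisection
    from scipy.optimize import brentq

    alpha = 0.05
    for n in (1, 2, 5, 11, 17, 23, 30):
        for x in range(n + 1):
            ci = clopper_pearson(x, n)
            if x > 0:
                root = brentq(lambda p: binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
                assert ci.lower == pytest.approx(root, abs=1e-8)
            if x < n:
                root = brentq(lambda p: binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
                assert ci.upper == pytest.approx(root, abs=1e-8)


def test_statsmodels_cross_check():
    from statsmodels.stats.proportion import proportion_confint

    for x, n in [(20, 36), (0, 10), (49, 55), (5, 10)]:
        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        ci = clopper_pearson(x, n)
        assert ci.lower == pytest.approx(lo, abs=1e-10)
        assert ci.upper == pytest.approx(hi, abs=1e-10)


# ---------------------------------------------------------------------------
# endpoint derivation
# ---------------------------------------------------------------------------


def _patient(**kw):
    base = dict(patient_id="p1", cohort_id="BTC", enrollment_week=0.0)
    base.update(kw)
    return PatientRecord(**base)


class TestDeriveEndpoint:
    def test_dor_is_onset_to_progression(self):
        rec = _patient(
            best_response_inv="PR",
            response_onset_week=8.0,
            progression_week=30.0,
            last_assessment_week=30.0,
        )
        (tte,) = derive_endpoint([rec], "DoR")
        assert tte.time_weeks == pytest.approx(22.0)
        assert tte.event is True

    def test_pfs_censored_at_last_assessment(self):
        rec = _patient(best_response_inv="SD", last_assessment_week=40.0)
        (tte,) = derive_endpoint([rec], "PFS")
        assert tte.time_weeks == pytest.approx(40.0)
        assert tte.event is False

    def test_non_responders_have_no_dor(self):
        rec = _patient(best_response_inv="SD", last_assessment_week=40.0)
        assert derive_endpoint([rec], "DoR") == []

    def test_death_is_pfs_and_os_event(self):
        rec = _patient(
            best_response_inv="SD",
            progression_week=None,
            death_week=25.0,
            last_assessment_week=25.0,
        )
        (pfs,) = derive_endpoint([rec], "PFS")
        (os_,) = derive_endpoint([rec], "OS")
        assert pfs.event and pfs.time_weeks == pytest.approx(25.0)
        assert os_.event and os_.time_weeks == pytest.approx(25.0)

    def test_responder_without_onset_is_integrity_error(self):
        rec = _patient(best_response_inv="CR", last_assessment_week=20.0)
        with pytest.raises(DataIntegrityError):
            derive_endpoint([rec], "DoR")

    def test_pfs_never_exceeds_os_and_dor_counts_responders(self, synthetic_records, specs):
        by_class = {s.cohort_id: s.cohort_class for s in specs}
        for s in specs:
            recs = [r for r in synthetic_records if r.cohort_id == s.cohort_id]
            if not recs:
                continue
            pfs = derive_endpoint(recs, "PFS", cohort_class=s.cohort_class)
            os_ = derive_endpoint(recs, "OS", cohort_class=s.cohort_class)
            dor = derive_endpoint(recs, "DoR", cohort_class=s.cohort_class)
            pfs_by = {t.patient_id: t for t in pfs}
            for t in os_:
                assert pfs_by[t.patient_id].time_weeks <= t.time_weeks + 1e-9
            n_resp = sum(
                classify_responder(r.best_response_inv, s.cohort_class) for r in recs
            )
            assert len(dor) == n_resp


# ---------------------------------------------------------------------------
# ORR table
# ---------------------------------------------------------------------------


def test_orr_report_from_published_counts():
    specs = default_cohort_specs()
    table = orr_report_from_counts(reported_best_response_counts(), specs)
    assert table.loc["ATC", "orr_pct"] == 56
    assert (table.loc["ATC", "ci_lower_pct"], table.loc["ATC", "ci_upper_pct"]) == (38.1, 72.1)
    assert table.loc["HGG", "orr_pct"] == 33
    assert (table.loc["HGG", "ci_lower_pct"], table.loc["HGG", "ci_upper_pct"]) == (20.0, 49.0)
    assert table.loc["GIST", "orr_pct"] == 0


def test_orr_report_consistent_with_classifier(synthetic_records, specs):
    # table x equals the sum of per-row responder classifications; MR/NE stay
    # in the denominator
    table = orr_report(synthetic_records, specs)
    for s in specs:
        recs = [r for r in synthetic_records if r.cohort_id == s.cohort_id]
        if not recs:
            assert s.cohort_id not in table.index
            continue
        x = sum(classify_responder(r.best_response_inv, s.cohort_class) for r in recs)
        assert table.loc[s.cohort_id, "x"] == x
        assert table.loc[s.cohort_id, "n"] == len(recs)


def test_orr_report_empty_cohort_omitted(specs):
    with pytest.warns(UserWarning):
        table = orr_report([], specs)
    assert table.empty
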