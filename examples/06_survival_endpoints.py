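"""Derive censored time-to-event endpoints and fit survival curves.

Duration of response runs from response onset to progression or death (among
responders only); progression-free survival from first dose to progression
or death; overall survival from first dose to death.  Unobserved events are
right-censored at the last assessment.  Medians carry Brookmeyer-Crowley 95%
intervals on the complementary log-log scale; sides the follow-up cannot
bound print as NOT_REACHED.
"""

from baskettrial import (
    TrialScenario,
    default_cohort_specs,
    derive_endpoint,
    generate_patients,
    km_fit,
)
from baskettrial.simulate import WEEKS_PER_MONTH

specs = default_cohort_specs(["BTC", "HGG", "HCL"])
scenario = TrialScenario(
    cohort_ids=["BTC", "HGG", "HCL"],
    true_orr={"BTC": 0.53, "HGG": 0.33, "HCL": 0.89},
    median_dor_weeks=39.0,   # ~9 months
    median_ttp_weeks=30.0,   # ~7 months
    median_os_weeks=65.0,    # ~15 months
    cutoff_weeks=208.0,
    seed=3,
)
records = generate_patients(scenario, specs)

def fmt(v):
    return f"{v / WEEKS_PER_MONTH:5.1f} mo" if isinstance(v, float) else "NR"

for s in specs:
    recs = [r for r in records if r.cohort_id == s.cohort_id]
    print(f"\n{s.cohort_id} (n={len(recs)})")
    for endpoint in ("DoR", "PFS", "OS"):
        tte = derive_endpoint(recs, endpoint, cohort_class=s.cohort_class)
        if not tte:
            continue
        est = km_fit(tte)
        lo, hi = est.median_ci
        print(
            f"  {endpoint:>3}: n={len(tte):3d} events={int(est.n_event.sum()):3d} "
            f"median {fmt(est.median)} (95% CI {fmt(lo)}, {fmt(hi)})"
        )
print(
    "\nMedians sit near the stated exponential truths; endpoints with few "
    "events report NOT_REACHED (NR) sides."
)
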