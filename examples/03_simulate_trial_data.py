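"""Generate a synthetic patient-level basket-trial dataset.

The scenario states the simulation truth: per-cohort true response rates,
Poisson accrual, exponential event-time medians (weeks) and an
investigator/independent rater agreement probability.  Category frequencies
default to the published per-cohort proportions.  The table is written as
CSV and summarized with exact intervals.
"""

from baskettrial import (
    TrialScenario,
    default_cohort_specs,
    generate_patients,
    orr_report,
    write_patients,
)

specs = default_cohort_specs()
scenario = TrialScenario(
    cohort_ids=[s.cohort_id for s in specs],
    true_orr=0.5,
    rater_agreement=0.60,
    cutoff_weeks=260.0,
    seed=11,
)
records = generate_patients(scenario, specs)
write_patients(records, "synthetic_patients.csv")
print(f"wrote {len(records)} records to synthetic_patients.csv")
print(orr_report(records, specs)[["x", "n", "orr_pct", "ci_lower_pct", "ci_upper_pct"]])
print(
    "\nEmpirical ORRs scatter around the stated 50% truth; cohort sizes follow "
    "the published enrollment."
)
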