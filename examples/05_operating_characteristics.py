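"""Estimate the design's operating characteristics by trial replication.

With every true ORR at the clinically meaningful 50%, the per-cohort
probability of declaring efficacy estimates power; re-running with true ORRs
at the historical nulls estimates type I error.  100 replicates keep this
example quick — the acceptance script runs thousands.
"""

from baskettrial import (
    BHMConfig,
    DesignRules,
    TrialScenario,
    default_cohort_specs,
    operating_characteristics,
)

specs = default_cohort_specs()
ids = [s.cohort_id for s in specs]
cfg = BHMConfig(grid_resolution=101, theta_bins=260)

power = operating_characteristics(
    TrialScenario(cohort_ids=ids, true_orr=0.5), specs, DesignRules(), cfg,
    n_sims=100, seed=1,
)
null = operating_characteristics(
    TrialScenario(cohort_ids=ids, true_orr={s.cohort_id: s.historical_rate for s in specs}),
    specs, DesignRules(), cfg, n_sims=100, seed=2,
)
table = power.table()[["prob_declare_efficacy", "expected_n"]].rename(
    columns={"prob_declare_efficacy": "power"}
)
table["type_i_error"] = null.table()["prob_declare_efficacy"]
table["expected_n_null"] = null.table()["expected_n"]
print(table.round(3))
print(
    "\nPower stays near 1 with a homogeneous 50% effect; under the global null "
    "few replicates declare efficacy and futility stops cut the sample size."
)
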