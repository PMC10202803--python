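import numpy as np
import pytest

from baskettrial import (
    BHMConfig,
    DesignRules,
    TrialScenario,
    default_cohort_specs,
    generate_patients,
)

# scaled-down quadrature for simulation-heavy tests; agrees with the full
# 201-node grid to ~1e-4 on exceedance probabilities
SIM_BHM = BHMConfig(grid_resolution=101, theta_bins=260)


@pytest.fixture(scope="session")
def specs():
    return default_cohort_specs()


@pytest.fixture(scope="session")
def cohort_ids(specs):
    return [s.cohort_id for s in specs]


@pytest.fixture(scope="session")
def null_scenario(specs, cohort_ids):
    return TrialScenario(
        cohort_ids=cohort_ids,
        true_orr={s.cohort_id: s.historical_rate for s in specs},
        seed=0,
    )


@pytest.fixture(scope="session")
def alt_scenario(cohort_ids):
    return TrialScenario(cohort_ids=cohort_ids, true_orr=0.5, seed=0)


@pytest.fixture(scope="session")
def synthetic_records(alt_scenario, specs):
    return generate_patients(alt_scenario, specs, seed=42)
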