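"""Cohort design specifications and the reported trial data used as fixtures.

The reference trial (ROAR, NCT02034110) enrolled nine histologic cohorts of
BRAF V600E-mutated rare cancers under one adaptive basket design: anaplastic
thyroid carcinoma (ATC), biliary tract cancer (BTC), gastrointestinal stromal
tumor (GIST), adenocarcinoma of the small intestine (ASI), low- and high-grade
glioma (LGG, HGG), non-seminomatous/non-germinomatous germ cell tumors
(NSGCT — which enrolled no patients), hairy cell leukemia (HCL) and multiple
myeloma (MM).  Each cohort carries a historical (null) response rate it must
exceed to be declared active — 10% for most, 15% for ATC and MM, 25% for
NSGCT — and a 50% rate regarded as clinically meaningful.

``reported_best_response_counts`` returns the published final investigator-
assessed best-response counts, which serve as a deterministic fixture for the
exact-CI analysis and as default category frequencies for the synthetic-data
generator.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CohortSpec",
    "default_cohort_specs",
    "reported_best_response_counts",
    "reported_enrollment",
    "REPORTED_CONCORDANCE_PCT",
]


@dataclass(frozen=True)
class CohortSpec:
    """Design parameters for one basket cohort.

    historical_rate
        Null objective response rate q_j the cohort must exceed.
    target_rate
        Clinically meaningful response rate (alternative hypothesis).
    max_primary_n
        Enrollment cap for the primary analysis cohort.
    cohort_class
        Key into the responder-rule registry (vocabulary + responder set).
    """

    cohort_id: str
    historical_rate: float
    target_rate: float = 0.50
    max_primary_n: int = 25
    cohort_class: str = "solid_glioma"

    def __post_init__(self) -> None:
        if not 0.0 < self.historical_rate < self.target_rate < 1.0:
            raise ValueError(
                "need 0 < historical_rate < target_rate < 1, got "
                f"q={self.historical_rate}, target={self.target_rate}"
            )
        if self.max_primary_n < 2:
            raise ValueError("max_primary_n must be at least 2")


#: cohort -> (historical rate, cohort class)
_DEFAULTS = {
    "ATC": (0.15, "solid_glioma"),
    "BTC": (0.10, "solid_glioma"),
    "GIST": (0.10, "solid_glioma"),
    "ASI": (0.10, "solid_glioma"),
    "LGG": (0.10, "solid_glioma"),
    "HGG": (0.10, "solid_glioma"),
    "NSGCT": (0.25, "solid_glioma"),
    "HCL": (0.10, "hcl"),
    "MM": (0.15, "mm"),
}


def default_cohort_specs(cohort_ids: tuple[str, ...] | None = None) -> list[CohortSpec]:
    """Specs for the nine reference cohorts (or a subset, in the given order)."""
    ids = tuple(_DEFAULTS) if cohort_ids is None else tuple(cohort_ids)
    specs = []
    for cid in ids:
        if cid not in _DEFAULTS:
            raise KeyError(f"no default design registered for cohort {cid!r}")
        q, klass = _DEFAULTS[cid]
        specs.append(CohortSpec(cohort_id=cid, historical_rate=q, cohort_class=klass))
    return specs


# Final published investigator-assessed best-response counts.  The HCL CR
# column prints CR without and with minimal residual disease separately
# (10 and 26); the MM PR column's footnote splits out 3 VGPR, and no MM
# patient had sCR or CR.  With those splits every cohort's categories sum to
# its enrolled n and the responder counts follow from the responder rules.
_REPORTED_COUNTS: dict[str, dict[str, int]] = {
    "ATC": {"CR": 3, "PR": 17, "SD": 11, "PD": 4, "NE": 1, "MR": 0},
    "BTC": {"CR": 0, "PR": 23, "SD": 16, "PD": 3, "NE": 1, "MR": 0},
    "GIST": {"CR": 0, "PR": 0, "SD": 1, "PD": 0, "NE": 0, "MR": 0},
    "ASI": {"CR": 0, "PR": 2, "SD": 0, "PD": 1, "NE": 0, "MR": 0},
    "LGG": {"CR": 1, "PR": 6, "SD": 3, "PD": 1, "NE": 0, "MR": 2},
    "HGG": {"CR": 3, "PR": 12, "SD": 10, "PD": 20, "NE": 0, "MR": 0},
    "HCL": {
        "CR_MRD_NEG": 10,
        "CR_MRD_POS": 26,
        "PR": 13,
        "MR": 4,
        "SD": 0,
        "PD": 1,
        "NE": 1,
    },
    "MM": {"sCR": 0, "CR": 0, "VGPR": 3, "PR": 2, "MR": 0, "SD": 1, "PD": 4, "NE": 0},
}

#: published concordance (%) of investigator vs independent best response
REPORTED_CONCORDANCE_PCT = {
    "ATC": 66.7,
    "BTC": 58.1,
    "ASI": 66.7,
    "LGG": 46.2,
    "HGG": 66.7,
}


def reported_best_response_counts() -> dict[str, dict]:
    """Published per-cohort best-response count vectors and (x, n) margins.

    Returns ``{cohort_id: {"counts": {category: count}, "responders": x,
    "n": n}}`` where ``x``/``n`` follow from the cohort's responder rule and
    the category sums.  Static trial data, useful as a deterministic fixture.
    """
    from .response import RULE_REGISTRY

    out: dict[str, dict] = {}
    for cid, counts in _REPORTED_COUNTS.items():
        klass = _DEFAULTS[cid][1]
        rule = RULE_REGISTRY[klass]
        x = sum(c for cat, c in counts.items() if cat in rule.responder_set)
        n = sum(counts.values())
        out[cid] = {"counts": dict(counts), "responders": x, "n": n}
    return out


def reported_enrollment() -> dict[str, int]:
    """Total enrolled per cohort (primary + expansion) in the reference trial."""
    return {cid: sum(counts.values()) for cid, counts in _REPORTED_COUNTS.items()}
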