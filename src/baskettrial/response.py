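"""Best-response vocabularies, responder rules, evaluability and rater concordance.

Best responses enter the package as categorical labels (the imaging- or
marrow-level response criteria that produce them — RECIST 1.1, RANO, IMWG,
HCL consensus criteria — are out of scope).  Each cohort *class* registers a
vocabulary and the subset of categories that count as a response:

* ``solid_glioma`` — CR/PR respond; minor response (MR) never counts.
* ``hcl``          — CR without MRD, CR with MRD, and PR respond.
* ``mm``           — sCR, CR, VGPR and PR respond.

The registry ships as JSON (``response_rules.json``) so additional cohort
classes can be registered without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence, Tuple

from .records import PatientRecord

__all__ = [
    "ResponderRule",
    "RULE_REGISTRY",
    "cohort_classes",
    "classify_responder",
    "is_evaluable",
    "concordance_rate",
    "ClassificationError",
]

# categories that must never qualify as a response, in any cohort class
_NEVER_RESPONDERS = frozenset({"MR", "SD", "PD", "NE"})


class ClassificationError(ValueError):
    """Raised when a category does not belong to a cohort class vocabulary."""


@dataclass(frozen=True)
class ResponderRule:
    cohort_class: str
    vocabulary: Tuple[str, ...]
    responder_set: frozenset

    def __post_init__(self) -> None:
        bad = self.responder_set & _NEVER_RESPONDERS
        if bad:
            raise ValueError(f"responder_set may not contain {sorted(bad)}")
        if not self.responder_set <= set(self.vocabulary):
            raise ValueError("responder_set must be a subset of the vocabulary")


def _load_registry() -> dict[str, ResponderRule]:
    raw = json.loads(
        resources.files(__package__).joinpath("response_rules.json").read_text()
    )
    return {
        name: ResponderRule(
            cohort_class=name,
            vocabulary=tuple(entry["vocabulary"]),
            responder_set=frozenset(entry["responders"]),
        )
        for name, entry in raw.items()
    }


RULE_REGISTRY: dict[str, ResponderRule] = _load_registry()


def cohort_classes() -> Tuple[str, ...]:
    return tuple(RULE_REGISTRY)


def get_rule(cohort_class: str) -> ResponderRule:
    try:
        return RULE_REGISTRY[cohort_class]
    except KeyError:
        raise ClassificationError(
            f"unknown cohort class {cohort_class!r}; "
            f"registered: {sorted(RULE_REGISTRY)}"
        ) from None


def classify_responder(category: Optional[str], cohort_class: str) -> bool:
    """True iff ``category`` counts as an objective response for the class.

    A missing (None) category is treated as a non-response: patients with an
    unknown or missing best response stay in the denominator as
    non-responders.
    """
    rule = get_rule(cohort_class)
    if category is None:
        return False
    if category not in rule.vocabulary:
        raise ClassificationError(
            f"category {category!r} is not in the {cohort_class!r} vocabulary "
            f"{rule.vocabulary}"
        )
    return category in rule.responder_set


def is_evaluable(record: PatientRecord, first_dose_week: Optional[float] = None) -> bool:
    """Decide membership in the efficacy-evaluable population.

    A patient is evaluable when any of the following holds: documented
    progressive disease; initiation of new anti-cancer therapy; consent
    withdrawal; death; stable disease documented at least 6 weeks after the
    first dose; or at least two post-baseline disease assessments.  Missing
    fields count as the condition not being met.
    """
    if first_dose_week is None:
        first_dose_week = record.enrollment_week
    if record.best_response_inv == "PD" or record.progression_week is not None:
        return True
    if record.new_anticancer_therapy or record.withdrew_consent:
        return True
    if record.death_week is not None:
        return True
    if (
        record.best_response_inv == "SD"
        and record.last_assessment_week is not None
        and record.last_assessment_week - first_dose_week >= 6.0
    ):
        return True
    if record.n_post_baseline_assessments >= 2:
        return True
    return False


def concordance_rate(
    pairs: Iterable[Tuple[Optional[str], Optional[str]]],
) -> float:
    """Fraction of (investigator, independent) best-response pairs that agree.

    Pairs with a missing independent assessment must be excluded upstream;
    an empty input has no defined rate and raises ``ValueError``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("concordance rate undefined for an empty set of pairs")
    agree = sum(1 for a, b in pairs if a == b)
    return agree / len(pairs)
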