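"""Patient-level record type shared by the generator, classifiers and analyses."""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

ARMS = ("primary", "expansion")


@dataclass
class PatientRecord:
    """One enrolled subject.

    Times are absolute study weeks (week 0 = first enrollment in the trial).
    ``enrollment_week`` doubles as the first-dose time: the generator does not
    model a separate dosing visit.  Optional event times are ``None`` when the
    event was not observed before the analysis cutoff.
    """

    patient_id: str
    cohort_id: str
    arm: str = "primary"
    enrollment_week: float = 0.0
    evaluable: bool = True
    best_response_inv: Optional[str] = None
    best_response_ind: Optional[str] = None
    response_onset_week: Optional[float] = None
    progression_week: Optional[float] = None
    death_week: Optional[float] = None
    last_assessment_week: Optional[float] = None
    # assessability flags; inputs, never inferred (see response.is_evaluable)
    new_anticancer_therapy: bool = False
    withdrew_consent: bool = False
    n_post_baseline_assessments: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.enrollment_week < 0:
            raise ValueError("enrollment_week must be nonnegative")
        o, p, d = self.response_onset_week, self.progression_week, self.death_week
        if o is not None and p is not None and o > p + 1e-9:
            raise ValueError("response onset must not follow progression")
        if p is not None and d is not None and p > d + 1e-9:
            raise ValueError("progression must precede or coincide with death")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
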