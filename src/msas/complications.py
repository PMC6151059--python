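"""Perioperative complication coding and tabulation.

Adverse events are coded into a fixed taxonomy split by timing:
intraoperative (transfusion within 72 h, blood loss >= 300 mL, organ
injury) versus postoperative (fever > 37.8 C for > 24 h, urinary
distention, ileus, vault bleeding, readmission within 30 days,
lymphedema, dysrhythmia, nerve palsy, wound dehiscence, fistula,
peritonitis).  Severity uses the Clavien-Dindo classification, graded
by the intensity of the treatment the event required; grades IIIa/IIIb
are collapsed to III.

Tabulation uses two denominators: per-code percentages are relative to
the number of patients, per-grade percentages relative to the number of
complications.  A patient may carry several events; the patient-level
"any complication" flags count each patient once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "ComplicationCode",
    "TimingClass",
    "ClavienGrade",
    "ComplicationEvent",
    "ComplicationSummary",
    "classify_event",
    "derive_bleeding_event",
    "grade_clavien",
    "summarize_complications",
    "parse_event_token",
    "format_event_token",
]


class ComplicationCode(str, Enum):
    BLEEDING_GE_300 = "bleeding_ge_300"
    TRANSFUSION_72H = "transfusion_72h"
    BOWEL_INJURY = "bowel_injury"
    BLADDER_URETER_INJURY = "bladder_ureter_injury"
    FEVER_GT_24H = "fever_gt_24h"
    URINARY_DISTENTION = "urinary_distention"
    ILEUS = "ileus"
    VAULT_BLEEDING = "vault_bleeding"
    READMISSION_30D = "readmission_30d"
    LYMPHEDEMA = "lymphedema"
    DYSRHYTHMIA = "dysrhythmia"
    NERVE_PALSY = "nerve_palsy"
    WOUND_DEHISCENCE = "wound_dehiscence"
    FISTULA = "fistula"
    PERITONITIS = "peritonitis"


class TimingClass(str, Enum):
    INTRAOPERATIVE = "intraoperative"
    POSTOPERATIVE = "postoperative"


_INTRAOPERATIVE = frozenset(
    {
        ComplicationCode.BLEEDING_GE_300,
        ComplicationCode.TRANSFUSION_72H,
        ComplicationCode.BOWEL_INJURY,
        ComplicationCode.BLADDER_URETER_INJURY,
    }
)


def classify_event(code: ComplicationCode | str) -> TimingClass:
    """Timing class is a pure function of the event code."""
    try:
        code = ComplicationCode(code)
    except ValueError:
        valid = ", ".join(c.value for c in ComplicationCode)
        raise ValueError(
            f"unknown complication code {code!r}; valid codes: {valid}"
        ) from None
    if code in _INTRAOPERATIVE:
        return TimingClass.INTRAOPERATIVE
    return TimingClass.POSTOPERATIVE


class ClavienGrade(str, Enum):
    I = "I"
    II = "II"
    III = "III"  # IIIa/IIIb collapsed
    IV = "IV"
    V = "V"


# standard Clavien-Dindo rule: grade = intensity of treatment required
_TREATMENT_TO_GRADE = {
    "none_or_bedside": ClavienGrade.I,
    "pharmacological": ClavienGrade.II,
    "intervention": ClavienGrade.III,
    "icu_life_threatening": ClavienGrade.IV,
    "death": ClavienGrade.V,
}
_GRADE_TO_TREATMENT = {g: t for t, g in _TREATMENT_TO_GRADE.items()}


def grade_clavien(treatment_level: str) -> ClavienGrade:
    """Map the treatment an event required to its Clavien-Dindo grade."""
    try:
        return _TREATMENT_TO_GRADE[treatment_level]
    except KeyError:
        valid = ", ".join(_TREATMENT_TO_GRADE)
        raise ValueError(
            f"unknown treatment level {treatment_level!r}; valid levels: {valid}"
        ) from None


@dataclass(frozen=True)
class ComplicationEvent:
    """A coded adverse event with derived timing and severity grade."""

    code: ComplicationCode
    clavien_grade: ClavienGrade = ClavienGrade.I

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", ComplicationCode(self.code))
        object.__setattr__(self, "clavien_grade", ClavienGrade(self.clavien_grade))

    @property
    def timing_class(self) -> TimingClass:
        return classify_event(self.code)


def derive_bleeding_event(ebl: float) -> Optional[ComplicationEvent]:
    """Bleeding complication implied by the blood-loss measurement.

    The >= 300 mL threshold is inclusive: a case at exactly 300 mL has a
    bleeding complication even though 300 mL still earns 1 MSAS point
    (the 0-point bin is strictly > 300).  Both printed rules are applied
    literally rather than harmonized.
    """
    if ebl < 0:
        raise ValueError(f"negative EBL {ebl}")
    if ebl >= 300:
        return ComplicationEvent(ComplicationCode.BLEEDING_GE_300)
    return None


# ---------------------------------------------------------------------------
# event token serialization (cohort CSV dialect)

def parse_event_token(token: str) -> ComplicationEvent:
    """Parse ``code[:treatment_level]``; treatment omitted means grade I."""
    token = token.strip()
    if not token:
        raise ValueError("empty event token")
    code_s, _, level = token.partition(":")
    classify_event(code_s)  # raises with the list of valid codes
    grade = grade_clavien(level) if level else ClavienGrade.I
    return ComplicationEvent(ComplicationCode(code_s), grade)


def format_event_token(event: ComplicationEvent) -> str:
    if event.clavien_grade is ClavienGrade.I:
        return event.code.value
    return f"{event.code.value}:{_GRADE_TO_TREATMENT[event.clavien_grade]}"


# ---------------------------------------------------------------------------
# tabulation

@dataclass(frozen=True)
class ComplicationSummary:
    """Counts and percentages with the two denominators.

    ``code_pct`` uses the patient denominator; ``grade_pct`` uses the
    complication denominator, so grade percentages sum to 100 up to
    rounding whenever any event occurred.
    """

    n_patients: int
    n_events: int
    code_counts: dict
    code_pct: dict
    grade_counts: dict
    grade_pct: dict
    n_any: int
    n_intraoperative: int
    n_postoperative: int
    n_both: int

    @property
    def any_pct(self) -> float:
        return 100.0 * self.n_any / self.n_patients

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "code_counts": {c.value: v for c, v in self.code_counts.items()},
            "code_pct": {c.value: v for c, v in self.code_pct.items()},
            "grade_counts": {g.value: v for g, v in self.grade_counts.items()},
            "grade_pct": {g.value: v for g, v in self.grade_pct.items()},
            "n_any": self.n_any,
            "n_intraoperative": self.n_intraoperative,
            "n_postoperative": self.n_postoperative,
            "n_both": self.n_both,
        }


def summarize_complications(cohort: Sequence) -> ComplicationSummary:
    """Tabulate coded events over a cohort of patient records.

    ``cohort`` is any sequence of objects with an ``events`` attribute
    (an iterable of :class:`ComplicationEvent`).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    n_patients = len(cohort)
    code_counts: Counter = Counter({c: 0 for c in ComplicationCode})
    grade_counts: Counter = Counter({g: 0 for g in ClavienGrade})
    n_any = n_intra = n_post = n_both = 0
    n_events = 0
    for rec in cohort:
        has_intra = has_post = False
        for ev in rec.events:
            if not isinstance(ev, ComplicationEvent):
                raise TypeError(f"uncoded event {ev!r}")
            n_events += 1
            code_counts[ev.code] += 1
            grade_counts[ev.clavien_grade] += 1
            if ev.timing_class is TimingClass.INTRAOPERATIVE:
                has_intra = True
            else:
                has_post = True
        n_any += has_intra or has_post
        n_intra += has_intra
        n_post += has_post
        n_both += has_intra and has_post
    code_pct = {c: 100.0 * v / n_patients for c, v in code_counts.items()}
    grade_pct = {
        g: (100.0 * v / n_events if n_events else 0.0)
        for g, v in grade_counts.items()
    }
    return ComplicationSummary(
        n_patients=n_patients,
        n_events=n_events,
        code_counts=dict(code_counts),
        code_pct=code_pct,
        grade_counts=dict(grade_counts),
        grade_pct=grade_pct,
        n_any=n_any,
        n_intraoperative=n_intra,
        n_postoperative=n_post,
        n_both=n_both,
    )
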