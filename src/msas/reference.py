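"""Published summary counts of the reference cohort, as analysis inputs.

The study this package operationalizes reported only summary tables,
not patient-level data.  The counts here are those printed summaries,
kept as constants so the count-level analyses (trend tests, the
dichotomized 2x2, crude odds ratios, the complication tabulation) can
be recomputed exactly, and so tests can engineer synthetic cohorts that
hit the printed margins.

Known internal inconsistencies of the printed tables are preserved as
printed, not harmonized: the risk-stratum sizes (15/90/33) are
incompatible with the dichotomized low-score group size (52), and the
running text reports 21/52 intraoperative events where the table prints
26/52.  Count-level entry points analyze each table as given.
"""

from __future__ import annotations

from .complications import ClavienGrade, ComplicationCode, ComplicationEvent

N_PATIENTS = 138
N_EVENTS = 67

# risk-stratified counts (low / moderate / high), events out of stratum n
STRATUM_SIZES = (15, 90, 33)
INTRAOP_BY_STRATUM = (0, 15, 10)
PERIOP_BY_STRATUM = (7, 32, 14)

# dichotomized analysis (MSAS > 6, n=86 vs MSAS <= 6, n=52)
DICHOTOMIZED_GROUP_SIZES = (86, 52)
PERIOP_BY_GROUP = (13, 40)
INTRAOP_BY_GROUP = (1, 26)
POSTOP_BY_GROUP = (13, 25)

# patient-level prevalence counts
N_ANY = 53
N_INTRAOPERATIVE = 27
N_POSTOPERATIVE = 38
N_BOTH = 12

# per-event-code counts (patient denominator N_PATIENTS)
EVENT_COUNTS: dict[ComplicationCode, int] = {
    ComplicationCode.BLEEDING_GE_300: 16,
    ComplicationCode.TRANSFUSION_72H: 10,
    ComplicationCode.BOWEL_INJURY: 1,
    ComplicationCode.BLADDER_URETER_INJURY: 1,
    ComplicationCode.FEVER_GT_24H: 17,
    ComplicationCode.URINARY_DISTENTION: 6,
    ComplicationCode.ILEUS: 3,
    ComplicationCode.VAULT_BLEEDING: 2,
    ComplicationCode.READMISSION_30D: 2,
    ComplicationCode.LYMPHEDEMA: 2,
    ComplicationCode.DYSRHYTHMIA: 2,
    ComplicationCode.NERVE_PALSY: 2,
    ComplicationCode.WOUND_DEHISCENCE: 1,
    ComplicationCode.FISTULA: 1,
    ComplicationCode.PERITONITIS: 1,
}

# Clavien-Dindo grade counts (complication denominator N_EVENTS)
GRADE_COUNTS: dict[ClavienGrade, int] = {
    ClavienGrade.I: 49,
    ClavienGrade.II: 13,
    ClavienGrade.III: 5,
    ClavienGrade.IV: 0,
    ClavienGrade.V: 0,
}


class _EventHolder:
    """Minimal record: just an ``events`` attribute for tabulation."""

    __slots__ = ("events",)

    def __init__(self, events):
        self.events = tuple(events)


def build_reference_cohort() -> list[_EventHolder]:
    """Engineer a 138-patient event layout hitting every printed margin.

    The layout realizes: 27 patients with intraoperative events (28
    events; one patient carries two), 38 with postoperative events (39
    events; one carries two), 12 with both, 53 with any, per-code
    counts as printed, and grades 49/13/5/0/0 assigned over the 67
    events in order.  Only the ``events`` field is populated — enough
    for :func:`msas.complications.summarize_complications`.
    """
    intra_codes = [
        c
        for c in (
            ComplicationCode.BLEEDING_GE_300,
            ComplicationCode.TRANSFUSION_72H,
            ComplicationCode.BOWEL_INJURY,
            ComplicationCode.BLADDER_URETER_INJURY,
        )
        for _ in range(EVENT_COUNTS[c])
    ]  # 28 events
    post_codes = [
        c
        for c in (
            ComplicationCode.FEVER_GT_24H,
            ComplicationCode.URINARY_DISTENTION,
            ComplicationCode.ILEUS,
            ComplicationCode.VAULT_BLEEDING,
            ComplicationCode.READMISSION_30D,
            ComplicationCode.LYMPHEDEMA,
            ComplicationCode.DYSRHYTHMIA,
            ComplicationCode.NERVE_PALSY,
            ComplicationCode.WOUND_DEHISCENCE,
            ComplicationCode.FISTULA,
            ComplicationCode.PERITONITIS,
        )
        for _ in range(EVENT_COUNTS[c])
    ]  # 39 events

    per_patient: list[list[ComplicationCode]] = [[] for _ in range(N_PATIENTS)]
    # patients 0..26 intraoperative; patient 0 carries the extra event
    per_patient[0].append(intra_codes[0])
    per_patient[0].append(intra_codes[1])
    for i, code in enumerate(intra_codes[2:], start=1):
        per_patient[i].append(code)
    # patients 15..26 also postoperative ("both", 12 patients);
    # patients 27..52 postoperative only (26 patients); patient 15
    # carries the extra postoperative event
    post_patients = list(range(15, 27)) + list(range(27, 53))
    per_patient[post_patients[0]].append(post_codes[0])
    for pid, code in zip(post_patients, post_codes[1:]):
        per_patient[pid].append(code)

    grades = (
        [ClavienGrade.I] * GRADE_COUNTS[ClavienGrade.I]
        + [ClavienGrade.II] * GRADE_COUNTS[ClavienGrade.II]
        + [ClavienGrade.III] * GRADE_COUNTS[ClavienGrade.III]
    )
    gi = iter(grades)
    cohort = [
        _EventHolder(ComplicationEvent(code, next(gi)) for code in codes)
        for codes in per_patient
    ]
    return cohort
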