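"""Patient-level cohort I/O in a documented CSV schema.

One row per patient in ``cohort.csv``; an optional long-format
``vitals.csv`` (``patient_id,time_min,map_mmHg,hr_bpm``) carries the
intraoperative series.  A record must provide either a vitals series or
precomputed lowest MAP/HR; scoring additionally requires EBL.  Missing
numeric covariates are empty cells and load as ``None`` — records with
incomplete scoring inputs are kept at load time and rejected only when
scored, mirroring a registry that excludes incomplete charts from
analysis rather than from storage.

Units are fixed: mL, mmHg, beats/min, minutes, g/dL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .complications import ComplicationEvent, format_event_token, parse_event_token
from .scoring import VitalsSeries, extract_minima

__all__ = ["PatientRecord", "read_cohort", "write_cohort", "read_vitals", "write_vitals"]

PROCEDURES = ("radical_trachelectomy", "radical_hysterectomy")

SCHEMA_VERSION = "1"

COLUMNS = [
    "patient_id",
    "age_years",
    "bmi_kg_m2",
    "underlying_disease",
    "previous_pelvic_surgery",
    "nac",
    "procedure",
    "surgical_time_min",
    "preop_hb_g_dl",
    "postop_hb_g_dl",
    "ebl_ml",
    "lowest_map_mmHg",
    "lowest_hr_bpm",
    "events",
]

VITALS_COLUMNS = ["patient_id", "time_min", "map_mmHg", "hr_bpm"]


@dataclass(frozen=True)
class PatientRecord:
    """One surgical case: covariates, blood loss, vitals, coded events."""

    patient_id: str
    age_years: Optional[float] = None
    bmi_kg_m2: Optional[float] = None
    underlying_disease: Optional[bool] = None
    previous_pelvic_surgery: Optional[bool] = None
    nac: Optional[bool] = None
    procedure: Optional[str] = None
    surgical_time_min: Optional[float] = None
    preop_hb_g_dl: Optional[float] = None
    postop_hb_g_dl: Optional[float] = None
    ebl_ml: Optional[float] = None
    vitals: Optional[VitalsSeries] = None
    lowest_map_mmHg: Optional[float] = None
    lowest_hr_bpm: Optional[float] = None
    events: tuple[ComplicationEvent, ...] = ()

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.procedure is not None and self.procedure not in PROCEDURES:
            raise ValueError(
                f"{self.patient_id}: procedure {self.procedure!r} not one of {PROCEDURES}"
            )
        if self.ebl_ml is not None and self.ebl_ml < 0:
            raise ValueError(f"{self.patient_id}: negative EBL {self.ebl_ml}")
        if self.surgical_time_min is not None and self.surgical_time_min <= 0:
            raise ValueError(
                f"{self.patient_id}: non-positive surgical time {self.surgical_time_min}"
            )
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def has_minima(self) -> bool:
        return (
            self.vitals is not None
            or (self.lowest_map_mmHg is not None and self.lowest_hr_bpm is not None)
        )

    def minima(self) -> tuple[float, float]:
        """(lowest MAP, lowest HR), precomputed or taken from the series."""
        if self.lowest_map_mmHg is not None and self.lowest_hr_bpm is not None:
            return self.lowest_map_mmHg, self.lowest_hr_bpm
        if self.vitals is not None:
            return extract_minima(self.vitals)
        raise ValueError(
            f"{self.patient_id}: neither vitals series nor precomputed minima present"
        )


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def _parse_float(cell, row_no: int, col: str) -> Optional[float]:
    if cell is None or cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"row {row_no}: cannot parse {col}={cell!r} as number") from None


def _parse_bool(cell, row_no: int, col: str) -> Optional[bool]:
    if cell is None or cell == "":
        return None
    s = str(cell).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"row {row_no}: cannot parse {col}={cell!r} as boolean")


def read_vitals(path) -> dict[str, VitalsSeries]:
    """Load the long-format vitals companion file, one series per patient."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(VITALS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"vitals file missing column(s): {sorted(missing)}")
    out: dict[str, VitalsSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        rows = grp[["time_min", "map_mmHg", "hr_bpm"]].to_numpy(dtype=float)
        out[str(pid)] = VitalsSeries.from_rows(rows)
    return out


def write_vitals(series: dict[str, VitalsSeries], path) -> None:
    rows = [
        (pid, _fmt(float(s.time_min)), _fmt(float(s.map_mmHg)), _fmt(float(s.hr_bpm)))
        for pid, vs in series.items()
        for s in vs.samples
    ]
    pd.DataFrame(rows, columns=VITALS_COLUMNS).to_csv(path, index=False)


def read_cohort(path, vitals_path=None, schema_version: str = SCHEMA_VERSION) -> list[PatientRecord]:
    """Read and validate a cohort CSV (plus optional vitals companion).

    Raises ``ValueError`` naming the offending row for a missing
    required column, a duplicate patient_id, or an unparseable cell or
    event token.
    """
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing column(s): {sorted(missing)}")
    vitals = read_vitals(vitals_path) if vitals_path is not None else {}

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        row_no = int(i) + 2  # header is line 1
        pid = row["patient_id"]
        if pid in seen:
            raise ValueError(f"row {row_no}: duplicate patient_id {pid!r}")
        seen.add(pid)
        try:
            events = tuple(
                parse_event_token(tok)
                for tok in str(row["events"]).split(";")
                if tok.strip()
            )
        except ValueError as exc:
            raise ValueError(f"row {row_no}: bad event token ({exc})") from None
        records.append(
            PatientRecord(
                patient_id=pid,
                age_years=_parse_float(row["age_years"], row_no, "age_years"),
                bmi_kg_m2=_parse_float(row["bmi_kg_m2"], row_no, "bmi_kg_m2"),
                underlying_disease=_parse_bool(
                    row["underlying_disease"], row_no, "underlying_disease"
                ),
                previous_pelvic_surgery=_parse_bool(
                    row["previous_pelvic_surgery"], row_no, "previous_pelvic_surgery"
                ),
                nac=_parse_bool(row["nac"], row_no, "nac"),
                procedure=row["procedure"] or None,
                surgical_time_min=_parse_float(
                    row["surgical_time_min"], row_no, "surgical_time_min"
                ),
                preop_hb_g_dl=_parse_float(row["preop_hb_g_dl"], row_no, "preop_hb_g_dl"),
                postop_hb_g_dl=_parse_float(
                    row["postop_hb_g_dl"], row_no, "postop_hb_g_dl"
                ),
                ebl_ml=_parse_float(row["ebl_ml"], row_no, "ebl_ml"),
                vitals=vitals.get(pid),
                lowest_map_mmHg=_parse_float(
                    row["lowest_map_mmHg"], row_no, "lowest_map_mmHg"
                ),
                lowest_hr_bpm=_parse_float(row["lowest_hr_bpm"], row_no, "lowest_hr_bpm"),
                events=events,
            )
        )
    return records


def write_cohort(records: Sequence[PatientRecord], path, vitals_path=None) -> None:
    """Write a cohort CSV re-readable by :func:`read_cohort`.

    Numbers are written with 6 significant digits.  With ``vitals_path``
    the per-record series (when present) go to the companion file.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age_years": _fmt(r.age_years),
                "bmi_kg_m2": _fmt(r.bmi_kg_m2),
                "underlying_disease": _fmt(r.underlying_disease),
                "previous_pelvic_surgery": _fmt(r.previous_pelvic_surgery),
                "nac": _fmt(r.nac),
                "procedure": _fmt(r.procedure),
                "surgical_time_min": _fmt(r.surgical_time_min),
                "preop_hb_g_dl": _fmt(r.preop_hb_g_dl),
                "postop_hb_g_dl": _fmt(r.postop_hb_g_dl),
                "ebl_ml": _fmt(r.ebl_ml),
                "lowest_map_mmHg": _fmt(r.lowest_map_mmHg),
                "lowest_hr_bpm": _fmt(r.lowest_hr_bpm),
                "events": ";".join(format_event_token(e) for e in r.events),
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
    if vitals_path is not None:
        write_vitals(
            {r.patient_id: r.vitals for r in records if r.vitals is not None},
            vitals_path,
        )
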