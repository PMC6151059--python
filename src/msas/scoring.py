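"""Surgical Apgar scoring for open and minimally invasive surgery.

The surgical Apgar score (SAS) grades intraoperative physiology on a
10-point scale from three quantities: estimated blood loss (EBL, mL),
the lowest mean arterial pressure (MAP, mmHg) and the lowest heart rate
(HR, beats/min) recorded on the anesthesia chart.  The modified score
(MSAS) keeps the MAP and HR components and compresses the EBL bins
(<=50 / 51-150 / 151-300 / >300 mL) to suit the low blood loss of
robotic procedures.

Rubrics are data objects (ordered interval lists per component), so the
built-in SAS and MSAS tables, and custom variants, share one lookup
path.  Boundary conventions: printed ranges "a-b" are closed, ">x" is
strict, "<=x"/">=x" are inclusive.  The HR table prints both "55-65"
(3 points) and "<=55" (4 points); HR = 55 earns 4 points and the
3-point bin is read as (55, 65], matching the original SAS convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "VitalsSample",
    "VitalsSeries",
    "Interval",
    "ScoreRubric",
    "ScoreResult",
    "RiskStratum",
    "extract_minima",
    "score_component",
    "compute_score",
    "is_low_msas",
    "stratify_risk",
    "builtin_rubric",
    "load_rubric",
    "save_rubric",
]


# ---------------------------------------------------------------------------
# vitals

@dataclass(frozen=True)
class VitalsSample:
    """One anesthesia-chart reading (nominally every 5 minutes)."""

    time_min: float
    map_mmHg: float
    hr_bpm: float

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError(f"negative time offset {self.time_min}")
        if self.map_mmHg <= 0 or self.hr_bpm <= 0:
            raise ValueError(
                f"non-positive vital sign at t={self.time_min}: "
                f"MAP={self.map_mmHg}, HR={self.hr_bpm}"
            )


@dataclass(frozen=True)
class VitalsSeries:
    """Ordered intraoperative MAP/HR series.

    Time offsets must be strictly increasing; the nominal 5-minute
    sampling interval is not enforced, so gaps are allowed.
    """

    samples: tuple[VitalsSample, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("vitals series must contain at least one sample")
        times = [s.time_min for s in self.samples]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("vitals time offsets must be strictly increasing")

    @classmethod
    def from_rows(cls, rows: Iterable[Sequence[float]]) -> "VitalsSeries":
        """Build from (time_min, map_mmHg, hr_bpm) triples."""
        return cls(tuple(VitalsSample(t, m, h) for t, m, h in rows))

    def __len__(self) -> int:
        return len(self.samples)


def extract_minima(vitals: VitalsSeries) -> tuple[float, float]:
    """Lowest MAP and lowest HR over the record.

    The two minima may occur at different times.  Emits a warning when
    fewer than 3 samples are available, since a sparse record gives a
    fragile minimum; no imputation is attempted.
    """
    if not isinstance(vitals, VitalsSeries):
        vitals = VitalsSeries.from_rows(vitals)
    if len(vitals) < 3:
        warnings.warn(
            f"vitals series has only {len(vitals)} sample(s); "
            "minima may be unreliable",
            stacklevel=2,
        )
    lowest_map = min(s.map_mmHg for s in vitals.samples)
    lowest_hr = min(s.hr_bpm for s in vitals.samples)
    return lowest_map, lowest_hr


# ---------------------------------------------------------------------------
# rubric

@dataclass(frozen=True)
class Interval:
    """Score bin over one measurement: lo/hi may be infinite."""

    lo: float
    hi: float
    lo_incl: bool
    hi_incl: bool
    points: int

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValueError("bin points must be >= 0")
        if self.lo > self.hi:
            raise ValueError(f"empty interval: lo={self.lo} > hi={self.hi}")

    def contains(self, value: float) -> bool:
        above = value > self.lo or (self.lo_incl and value == self.lo)
        below = value < self.hi or (self.hi_incl and value == self.hi)
        return above and below

    def to_dict(self) -> dict:
        return {
            "lo": None if math.isinf(self.lo) else self.lo,
            "hi": None if math.isinf(self.hi) else self.hi,
            "lo_incl": self.lo_incl,
            "hi_incl": self.hi_incl,
            "points": self.points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Interval":
        lo = -math.inf if d.get("lo") is None else float(d["lo"])
        hi = math.inf if d.get("hi") is None else float(d["hi"])
        return cls(lo, hi, bool(d["lo_incl"]), bool(d["hi_incl"]), int(d["points"]))


_COMPONENTS = ("ebl", "map", "hr")
# physical domain lower edge per component: EBL >= 0 (0 allowed),
# MAP > 0 and HR > 0 (0 excluded)
_DOMAIN_MIN = {"ebl": (0.0, True), "map": (0.0, False), "hr": (0.0, False)}


def _validate_component(name: str, bins: Sequence[Interval]) -> tuple[Interval, ...]:
    """Bins must be disjoint and jointly cover the physical domain."""
    if not bins:
        raise ValueError(f"{name}: component has no bins")
    ordered = sorted(bins, key=lambda b: (b.lo, not b.lo_incl))
    dmin, dmin_incl = _DOMAIN_MIN[name]
    first = ordered[0]
    if first.lo != dmin or first.lo_incl != dmin_incl:
        raise ValueError(
            f"{name}: first bin must start exactly at the physical domain "
            f"edge ({dmin}, inclusive={dmin_incl})"
        )
    for a, b in zip(ordered, ordered[1:]):
        if a.hi != b.lo or (a.hi_incl == b.lo_incl):
            raise ValueError(
                f"{name}: bins ({a.lo},{a.hi}) and ({b.lo},{b.hi}) "
                "are not contiguous and disjoint"
            )
    if not math.isinf(ordered[-1].hi):
        raise ValueError(f"{name}: bins do not cover large values")
    return tuple(ordered)


@dataclass(frozen=True)
class ScoreRubric:
    """Per-component binning scheme mapping (EBL, MAP, HR) to points."""

    name: str
    ebl_bins: tuple[Interval, ...]
    map_bins: tuple[Interval, ...]
    hr_bins: tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ebl_bins", _validate_component("ebl", self.ebl_bins))
        object.__setattr__(self, "map_bins", _validate_component("map", self.map_bins))
        object.__setattr__(self, "hr_bins", _validate_component("hr", self.hr_bins))

    @property
    def max_total(self) -> int:
        return sum(
            max(b.points for b in bins)
            for bins in (self.ebl_bins, self.map_bins, self.hr_bins)
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "ebl_bins": [b.to_dict() for b in self.ebl_bins],
            "map_bins": [b.to_dict() for b in self.map_bins],
            "hr_bins": [b.to_dict() for b in self.hr_bins],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreRubric":
        return cls(
            name=str(d["name"]),
            ebl_bins=tuple(Interval.from_dict(b) for b in d["ebl_bins"]),
            map_bins=tuple(Interval.from_dict(b) for b in d["map_bins"]),
            hr_bins=tuple(Interval.from_dict(b) for b in d["hr_bins"]),
        )


@lru_cache(maxsize=None)
def builtin_rubric(name: str) -> ScoreRubric:
    """Load a bundled rubric: ``"sas"`` (open surgery) or ``"msas"``."""
    key = name.lower()
    if key not in ("sas", "msas"):
        raise ValueError(f"unknown built-in rubric {name!r}; choose 'sas' or 'msas'")
    text = resources.files("msas.data").joinpath(f"{key}.yaml").read_text()
    return ScoreRubric.from_dict(yaml.safe_load(text))


def load_rubric(path) -> ScoreRubric:
    with open(path) as fh:
        return ScoreRubric.from_dict(yaml.safe_load(fh))


def save_rubric(rubric: ScoreRubric, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(rubric.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# scoring

def score_component(value: float, bins: Sequence[Interval]) -> int:
    """Points of the unique bin containing ``value``.

    Values outside the component's physical domain (negative EBL,
    non-positive MAP/HR) fall in no bin and raise ``ValueError``.
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite measurement {value}")
    for b in bins:
        if b.contains(value):
            return b.points
    raise ValueError(f"value {value} outside the rubric's valid domain")


@dataclass(frozen=True)
class ScoreResult:
    ebl_points: int
    map_points: int
    hr_points: int
    total: int
    rubric_name: str

    def __post_init__(self) -> None:
        if self.total != self.ebl_points + self.map_points + self.hr_points:
            raise ValueError("total must equal the sum of component points")


def compute_score(
    ebl: float, lowest_map: float, lowest_hr: float, rubric: ScoreRubric
) -> ScoreResult:
    """Score one case from EBL, lowest MAP and lowest HR."""
    ep = score_component(ebl, rubric.ebl_bins)
    mp = score_component(lowest_map, rubric.map_bins)
    hp = score_component(lowest_hr, rubric.hr_bins)
    return ScoreResult(ep, mp, hp, ep + mp + hp, rubric.name)


def _check_total(total: int) -> int:
    if total != int(total):
        raise ValueError(f"score total must be an integer, got {total}")
    total = int(total)
    if not 0 <= total <= 10:
        raise ValueError(f"score total {total} outside [0, 10]")
    return total


def is_low_msas(total: int) -> bool:
    """Dichotomization used for the 2-group analysis: low means <= 6."""
    return _check_total(total) <= 6


class RiskStratum(Enum):
    """Three-level risk stratification: 7-10 low, 5-6 moderate, 0-4 high."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


def stratify_risk(total: int) -> RiskStratum:
    total = _check_total(total)
    if total >= 7:
        return RiskStratum.LOW
    if total >= 5:
        return RiskStratum.MODERATE
    return RiskStratum.HIGH
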