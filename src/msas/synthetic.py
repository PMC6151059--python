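"""Synthetic surgical cohorts with the structure the analysis assumes.

No patient-level data accompany the study design this package
implements, so this module generates cohorts whose marginals and
score-outcome coupling match the printed cohort summaries: Normal
covariates (age, BMI, surgical time, preoperative hemoglobin),
log-normal blood loss, AR(1) intraoperative MAP/HR series sampled every
5 minutes around patient-specific baselines, and logistic complication
links on the modified surgical Apgar score (MSAS).

Mechanics, in generation order per cohort:

* covariates drawn independently (no correlation structure is assumed);
* vitals as truncated AR(1) processes (MAP >= 20 mmHg, HR >= 30 bpm)
  over the drawn surgical time; the score uses their minima;
* EBL log-normal, with the log-sd chosen so P(EBL >= 300 mL) matches
  the target bleeding prevalence;
* the definitional coupling EBL >= 300 => a coded bleeding event
  (switchable for null simulations);
* transfusion ~ Bernoulli(logistic(intercept + slope * (6.5 - MSAS)));
* organ injuries as rare independent Bernoullis;
* postoperative events ~ Bernoulli(logistic in standardized surgical
  time and MSAS), the specific code drawn from the empirical
  postoperative frequency profile;
* every event given a Clavien-Dindo grade from a multinomial whose
  default is (0.731, 0.194, 0.075, 0, 0).

Everything is reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .complications import (
    ClavienGrade,
    ComplicationCode,
    ComplicationEvent,
    derive_bleeding_event,
)
from .cohort_io import PatientRecord
from .scoring import VitalsSeries, builtin_rubric, compute_score
from . import stats as _stats

__all__ = [
    "SimulationConfig",
    "default_config",
    "generate_vitals",
    "generate_cohort",
    "trend_rejection_rate",
]

# empirical postoperative code profile (event counts in the reference
# tabulation: fever 17, urinary distention 6, ileus 3, then rarer codes)
POSTOP_PROFILE: tuple[tuple[ComplicationCode, float], ...] = (
    (ComplicationCode.FEVER_GT_24H, 17),
    (ComplicationCode.URINARY_DISTENTION, 6),
    (ComplicationCode.ILEUS, 3),
    (ComplicationCode.VAULT_BLEEDING, 2),
    (ComplicationCode.READMISSION_30D, 2),
    (ComplicationCode.LYMPHEDEMA, 2),
    (ComplicationCode.DYSRHYTHMIA, 2),
    (ComplicationCode.NERVE_PALSY, 2),
    (ComplicationCode.WOUND_DEHISCENCE, 1),
    (ComplicationCode.FISTULA, 1),
    (ComplicationCode.PERITONITIS, 1),
)

_GRADES = (ClavienGrade.I, ClavienGrade.II, ClavienGrade.III, ClavienGrade.IV, ClavienGrade.V)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort model parameters; defaults target the reference cohort.

    Covariate means/SDs target the no-complication column of the
    printed characteristics table; the EBL log-sd is the closed-form
    solution putting 16/138 of the mass at >= 300 mL given the median;
    the logistic intercepts/slopes are calibrated so the low-MSAS (<=6)
    fraction sits near 52/138 and intraoperative prevalence near 27/138
    at n = 138.
    """

    n_patients: int = 138
    seed: int = 0
    # covariates
    age_mean: float = 44.1
    age_sd: float = 10.1
    bmi_mean: float = 22.9
    bmi_sd: float = 3.0
    surgical_time_mean: float = 190.0
    surgical_time_sd: float = 70.9
    surgical_time_floor: float = 60.0
    preop_hb_mean: float = 13.0
    preop_hb_sd: float = 1.2
    hb_drop_mean: float = 1.0
    hb_drop_sd: float = 0.8
    trachelectomy_fraction: float = 21 / 138
    nac_fraction: float = 7 / 138
    underlying_disease_fraction: float = 24 / 138
    previous_pelvic_surgery_fraction: float = 53 / 138
    # vitals model
    map_baseline_mean: float = 84.0
    map_baseline_sd: float = 8.0
    hr_baseline_mean: float = 72.0
    hr_baseline_sd: float = 9.0
    ar1_coef: float = 0.8
    map_innovation_sd: float = 6.0
    hr_innovation_sd: float = 4.5
    sampling_interval_min: float = 5.0
    map_floor: float = 20.0
    hr_floor: float = 30.0
    # EBL model (log-normal); log_sd solves P(EBL >= 300) = 16/138
    ebl_log_median: float = 120.0
    ebl_log_sd: float = 0.7663
    # complication model
    score_center: float = 6.5
    transfusion_intercept: float = -2.7
    transfusion_slope: float = 0.8
    organ_injury_prob: float = 1 / 138
    postop_intercept: float = -1.0
    postop_time_slope: float = 0.30
    postop_msas_slope: float = 0.15
    grade_probs: tuple[float, ...] = (0.731, 0.194, 0.075, 0.0, 0.0)
    couple_bleeding: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9 or any(
            p < 0 for p in self.grade_probs
        ):
            raise ValueError("grade_probs must be a probability vector summing to 1")
        for name in ("organ_injury_prob", "trachelectomy_fraction", "nac_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def default_config(n_patients: int = 138, seed: int = 0) -> SimulationConfig:
    """The calibrated reference configuration (see class docstring)."""
    return SimulationConfig(n_patients=n_patients, seed=seed)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_vitals(
    duration_min: float, config: SimulationConfig, rng: np.random.Generator
) -> VitalsSeries:
    """One intraoperative MAP/HR series sampled at t = 0, 5, ... <= duration.

    The patient's baselines are drawn from the config; both channels
    follow independent AR(1) processes around them, truncated to
    physiologic floors.
    """
    if duration_min <= 0:
        raise ValueError(f"non-positive duration {duration_min}")
    dt = config.sampling_interval_min
    n_steps = int(math.floor(duration_min / dt)) + 1
    map_base = rng.normal(config.map_baseline_mean, config.map_baseline_sd)
    hr_base = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd)
    phi = config.ar1_coef
    m, h = map_base, hr_base
    rows = [(0.0, max(m, config.map_floor), max(h, config.hr_floor))]
    for k in range(1, n_steps):
        m = map_base + phi * (m - map_base) + rng.normal(0.0, config.map_innovation_sd)
        h = hr_base + phi * (h - hr_base) + rng.normal(0.0, config.hr_innovation_sd)
        m = max(m, config.map_floor)
        h = max(h, config.hr_floor)
        rows.append((k * dt, m, h))
    return VitalsSeries.from_rows(rows)


def _simulate_arrays(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Vectorized cohort draw; returns plain arrays plus per-patient events.

    Used both by :func:`generate_cohort` (which wraps records around it)
    and by the replicate studies, which need only the arrays.
    """
    n = config.n_patients
    age = rng.normal(config.age_mean, config.age_sd, n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)
    surg_time = np.maximum(
        rng.normal(config.surgical_time_mean, config.surgical_time_sd, n),
        config.surgical_time_floor,
    )
    preop_hb = rng.normal(config.preop_hb_mean, config.preop_hb_sd, n)
    postop_hb = preop_hb - np.maximum(
        rng.normal(config.hb_drop_mean, config.hb_drop_sd, n), 0.0
    )
    trach = rng.random(n) < config.trachelectomy_fraction
    nac = rng.random(n) < config.nac_fraction
    underlying = rng.random(n) < config.underlying_disease_fraction
    prev_surgery = rng.random(n) < config.previous_pelvic_surgery_fraction

    # vitals: AR(1) paths over each patient's surgical time
    dt = config.sampling_interval_min
    steps = np.floor(surg_time / dt).astype(int) + 1
    max_steps = int(steps.max())
    map_base = rng.normal(config.map_baseline_mean, config.map_baseline_sd, n)
    hr_base = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd, n)
    phi = config.ar1_coef
    map_paths = np.empty((n, max_steps))
    hr_paths = np.empty((n, max_steps))
    map_paths[:, 0] = np.maximum(map_base, config.map_floor)
    hr_paths[:, 0] = np.maximum(hr_base, config.hr_floor)
    m = map_paths[:, 0].copy()
    h = hr_paths[:, 0].copy()
    for k in range(1, max_steps):
        m = map_base + phi * (m - map_base) + rng.normal(0.0, config.map_innovation_sd, n)
        h = hr_base + phi * (h - hr_base) + rng.normal(0.0, config.hr_innovation_sd, n)
        m = np.maximum(m, config.map_floor)
        h = np.maximum(h, config.hr_floor)
        map_paths[:, k] = m
        hr_paths[:, k] = h
    col = np.arange(max_steps)
    valid = col[None, :] < steps[:, None]
    min_map = np.where(valid, map_paths, np.inf).min(axis=1)
    min_hr = np.where(valid, hr_paths, np.inf).min(axis=1)

    # blood loss
    ebl = config.ebl_log_median * np.exp(config.ebl_log_sd * rng.standard_normal(n))

    # scores
    msas_rubric = builtin_rubric("msas")
    sas_rubric = builtin_rubric("sas")
    msas = np.array(
        [
            compute_score(e, mm, hh, msas_rubric).total
            for e, mm, hh in zip(ebl, min_map, min_hr)
        ]
    )
    sas = np.array(
        [
            compute_score(e, mm, hh, sas_rubric).total
            for e, mm, hh in zip(ebl, min_map, min_hr)
        ]
    )

    # complication draws (fixed order for reproducibility)
    centered = config.score_center - msas
    p_transfusion = _logistic(config.transfusion_intercept + config.transfusion_slope * centered)
    transfusion = rng.random(n) < p_transfusion
    bowel = rng.random(n) < config.organ_injury_prob
    bladder = rng.random(n) < config.organ_injury_prob
    t_std = (surg_time - config.surgical_time_mean) / config.surgical_time_sd
    p_postop = _logistic(
        config.postop_intercept
        + config.postop_time_slope * t_std
        + config.postop_msas_slope * centered
    )
    postop = rng.random(n) < p_postop
    weights = np.array([w for _, w in POSTOP_PROFILE], dtype=float)
    weights /= weights.sum()
    postop_code_idx = np.searchsorted(np.cumsum(weights), rng.random(n))
    grade_cum = np.cumsum(config.grade_probs)
    grade_draws = np.minimum(
        np.searchsorted(grade_cum, rng.random((n, 5))), len(_GRADES) - 1
    )

    bleeding = config.couple_bleeding & (ebl >= 300)
    events: list[list[ComplicationEvent]] = []
    for i in range(n):
        evs: list[ComplicationEvent] = []
        slot = 0
        if bleeding[i]:
            evs.append(
                ComplicationEvent(ComplicationCode.BLEEDING_GE_300, _GRADES[grade_draws[i, slot]])
            )
            slot += 1
        if transfusion[i]:
            evs.append(
                ComplicationEvent(ComplicationCode.TRANSFUSION_72H, _GRADES[grade_draws[i, slot]])
            )
            slot += 1
        if bowel[i]:
            evs.append(
                ComplicationEvent(ComplicationCode.BOWEL_INJURY, _GRADES[grade_draws[i, slot]])
            )
            slot += 1
        if bladder[i]:
            evs.append(
                ComplicationEvent(
                    ComplicationCode.BLADDER_URETER_INJURY, _GRADES[grade_draws[i, slot]]
                )
            )
            slot += 1
        if postop[i]:
            code = POSTOP_PROFILE[postop_code_idx[i]][0]
            evs.append(ComplicationEvent(code, _GRADES[grade_draws[i, slot]]))
        events.append(evs)

    intraop_any = bleeding | transfusion | bowel | bladder
    return {
        "age": age,
        "bmi": bmi,
        "underlying": underlying,
        "prev_surgery": prev_surgery,
        "nac": nac,
        "trach": trach,
        "surg_time": surg_time,
        "preop_hb": preop_hb,
        "postop_hb": postop_hb,
        "ebl": ebl,
        "min_map": min_map,
        "min_hr": min_hr,
        "msas": msas,
        "sas": sas,
        "events": events,
        "intraop_any": intraop_any,
        "postop_any": postop,
        "map_paths": map_paths,
        "hr_paths": hr_paths,
        "steps": steps,
    }


def generate_cohort(
    config: SimulationConfig, keep_vitals: bool = True
) -> list[PatientRecord]:
    """Draw a full cohort of patient records from ``config.seed``.

    With ``keep_vitals=False`` records carry precomputed minima only,
    which keeps large calibration runs cheap; the vitals model is the
    same either way.
    """
    rng = np.random.default_rng(config.seed)
    arr = _simulate_arrays(config, rng)
    n = config.n_patients
    dt = config.sampling_interval_min
    records = []
    for i in range(n):
        vitals = None
        if keep_vitals:
            k = int(arr["steps"][i])
            vitals = VitalsSeries.from_rows(
                zip(
                    np.arange(k) * dt,
                    arr["map_paths"][i, :k],
                    arr["hr_paths"][i, :k],
                )
            )
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                age_years=float(arr["age"][i]),
                bmi_kg_m2=float(arr["bmi"][i]),
                underlying_disease=bool(arr["underlying"][i]),
                previous_pelvic_surgery=bool(arr["prev_surgery"][i]),
                nac=bool(arr["nac"][i]),
                procedure=(
                    "radical_trachelectomy" if arr["trach"][i] else "radical_hysterectomy"
                ),
                surgical_time_min=float(arr["surg_time"][i]),
                preop_hb_g_dl=float(arr["preop_hb"][i]),
                postop_hb_g_dl=float(arr["postop_hb"][i]),
                ebl_ml=float(arr["ebl"][i]),
                vitals=vitals,
                lowest_map_mmHg=float(arr["min_map"][i]),
                lowest_hr_bpm=float(arr["min_hr"][i]),
                events=tuple(arr["events"][i]),
            )
        )
    return records


def trend_rejection_rate(
    config: SimulationConfig,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    outcome: str = "intraoperative",
) -> float:
    """Fraction of seeded replicates whose risk-stratified trend test
    rejects at ``alpha``.

    Each replicate draws a fresh cohort, stratifies patients by MSAS
    (7-10 / 5-6 / 0-4), and runs the linear-by-linear test of the chosen
    outcome against the stratum.  Replicates where the test is undefined
    (an empty stratum dimension or constant outcome) count as
    non-rejections.
    """
    if outcome not in ("intraoperative", "postoperative", "perioperative"):
        raise ValueError(f"unknown outcome {outcome!r}")
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        arr = _simulate_arrays(config, rng)
        if outcome == "intraoperative":
            flag = arr["intraop_any"]
        elif outcome == "postoperative":
            flag = arr["postop_any"]
        else:
            flag = arr["intraop_any"] | arr["postop_any"]
        msas = arr["msas"]
        strata = np.where(msas >= 7, 0, np.where(msas >= 5, 1, 2))
        events = [int(flag[strata == s].sum()) for s in (0, 1, 2)]
        nonevents = [int(((strata == s) & ~flag).sum()) for s in (0, 1, 2)]
        keep = [i for i in range(3) if events[i] + nonevents[i] > 0]
        if len(keep) < 2:
            continue
        table = _stats.ContingencyTable.from_counts(
            [events[i] for i in keep],
            [nonevents[i] for i in keep],
            scores=[i + 1 for i in keep],
        )
        try:
            res = _stats.linear_by_linear(table)
        except ValueError:
            continue
        rejections += res.p_value < alpha
    return rejections / n_replicates
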