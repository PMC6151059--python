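"""End-to-end association analysis of a scored cohort.

``run_analysis`` takes validated patient records and produces a
structured report with:

* the complication tabulation (per-code and per-grade, two denominators);
* covariate comparisons between patients with and without any
  complication (pooled t for continuous variables; chi-square or Fisher
  per the expected-count rule for categorical ones);
* the same comparison between the low-score (MSAS <= 6) and high-score
  groups, plus the three outcome rows (perioperative / intraoperative /
  postoperative);
* crude odds ratios (Woolf CI) for each outcome against low MSAS,
  explicitly flagged "crude" — no adjustment is attempted;
* risk-stratified (7-10 / 5-6 / 0-4) linear-by-linear trend tests for
  the perioperative and intraoperative outcomes;
* a provenance block (rubric, test selections, version).

``analyze_count_table`` is the count-level entry point: it analyzes an
externally supplied table (for instance a published one) directly,
bypassing the cohort-level consistency checks — published tables are
not always internally consistent, and they are analyzed as given.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .cohort_io import PatientRecord
from .complications import ComplicationSummary, TimingClass, summarize_complications
from .scoring import (
    RiskStratum,
    ScoreRubric,
    builtin_rubric,
    compute_score,
    is_low_msas,
    stratify_risk,
)
from .stats import (
    ContingencyTable,
    chi_square_2x2,
    fisher_exact_2x2,
    linear_by_linear,
    odds_ratio_2x2,
    students_t,
    test_selector,
)

__all__ = ["AnalysisReport", "run_analysis", "analyze_count_table", "render_report", "format_p"]

_CONTINUOUS = [
    ("age_years", "age_years"),
    ("bmi_kg_m2", "bmi_kg_m2"),
    ("surgical_time_min", "surgical_time_min"),
    ("preop_hb_g_dl", "preop_hb_g_dl"),
    ("postop_hb_g_dl", "postop_hb_g_dl"),
]
_CATEGORICAL = [
    ("underlying_disease", lambda r: r.underlying_disease),
    ("previous_pelvic_surgery", lambda r: r.previous_pelvic_surgery),
    ("nac", lambda r: r.nac),
    ("radical_trachelectomy", lambda r: r.procedure == "radical_trachelectomy"),
]
_OUTCOMES = ("perioperative", "intraoperative", "postoperative")


def format_p(p: float) -> str:
    """Display convention: '< 0.001' below 0.001, else two decimals."""
    if p < 0.001:
        return "< 0.001"
    s = f"{p:.2f}"
    return f"{p:.3f}" if s == "0.00" else s


@dataclass(frozen=True)
class AnalysisReport:
    n_patients: int
    complication_summary: dict
    group_comparison: list
    low_msas_comparison: list
    odds_ratios: dict
    trend_panel: dict
    score_summary: dict
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _two_group_tests(records, in_group_b, label_a, label_b) -> list[dict]:
    """Continuous and categorical comparisons between two patient groups."""
    rows: list[dict] = []
    a = [r for r, g in zip(records, in_group_b) if not g]
    b = [r for r, g in zip(records, in_group_b) if g]
    for name, attr in _CONTINUOUS:
        va = [getattr(r, attr) for r in a if getattr(r, attr) is not None]
        vb = [getattr(r, attr) for r in b if getattr(r, attr) is not None]
        row = {
            "variable": name,
            "kind": "continuous",
            f"mean_{label_a}": float(np.mean(va)) if va else None,
            f"sd_{label_a}": float(np.std(va, ddof=1)) if len(va) > 1 else None,
            f"mean_{label_b}": float(np.mean(vb)) if vb else None,
            f"sd_{label_b}": float(np.std(vb, ddof=1)) if len(vb) > 1 else None,
        }
        try:
            res = students_t(va, vb)
            row.update(test="students_t_pooled", statistic=res.statistic, p_value=res.p_value)
        except ValueError as exc:
            row.update(test="students_t_pooled", statistic=None, p_value=None, note=str(exc))
        rows.append(row)
    for name, getter in _CATEGORICAL:
        ca = sum(bool(getter(r)) for r in a)
        cb = sum(bool(getter(r)) for r in b)
        table = ContingencyTable.from_counts(
            [ca, cb], [len(a) - ca, len(b) - cb], labels=[label_a, label_b]
        )
        row = {
            "variable": name,
            "kind": "categorical",
            f"count_{label_a}": ca,
            f"count_{label_b}": cb,
            f"n_{label_a}": len(a),
            f"n_{label_b}": len(b),
        }
        try:
            chosen = test_selector(table)
            res = chi_square_2x2(table) if chosen == "chi_square" else fisher_exact_2x2(table)
            row.update(test=chosen, statistic=res.statistic, p_value=res.p_value)
        except ValueError as exc:
            row.update(test="not_computable", statistic=None, p_value=None, note=str(exc))
        rows.append(row)
    return rows


def _outcome_flags(record: PatientRecord) -> dict[str, bool]:
    intra = any(e.timing_class is TimingClass.INTRAOPERATIVE for e in record.events)
    post = any(e.timing_class is TimingClass.POSTOPERATIVE for e in record.events)
    return {
        "perioperative": intra or post,
        "intraoperative": intra,
        "postoperative": post,
    }


def run_analysis(
    cohort: Sequence[PatientRecord],
    rubric: Optional[ScoreRubric] = None,
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Score every record and run the full association analysis.

    Raises ``ValueError`` naming the patient_id of any record missing
    the scoring inputs (EBL plus vitals or precomputed minima).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rubric = rubric or builtin_rubric("msas")
    sas_rubric = builtin_rubric("sas")

    totals: list[int] = []
    sas_totals: list[int] = []
    for r in cohort:
        if r.ebl_ml is None or not r.has_minima:
            raise ValueError(
                f"record {r.patient_id!r} is not scoreable: needs ebl_ml and "
                "vitals or precomputed minima"
            )
        lo_map, lo_hr = r.minima()
        totals.append(compute_score(r.ebl_ml, lo_map, lo_hr, rubric).total)
        sas_totals.append(compute_score(r.ebl_ml, lo_map, lo_hr, sas_rubric).total)

    low = [is_low_msas(t) for t in totals]
    strata = [stratify_risk(t) for t in totals]
    flags = [_outcome_flags(r) for r in cohort]
    n = len(cohort)

    summary = summarize_complications(cohort)

    any_comp = [f["perioperative"] for f in flags]
    group_comparison = _two_group_tests(cohort, any_comp, "no_complication", "complication")

    low_comparison = _two_group_tests(cohort, low, "msas_gt6", "msas_le6")
    selections: dict[str, str] = {}
    for outcome in _OUTCOMES:
        e_hi = sum(f[outcome] for f, l in zip(flags, low) if not l)
        e_lo = sum(f[outcome] for f, l in zip(flags, low) if l)
        n_hi = sum(not l for l in low)
        n_lo = sum(low)
        table = ContingencyTable.from_counts(
            [e_hi, e_lo], [n_hi - e_hi, n_lo - e_lo], labels=["msas_gt6", "msas_le6"]
        )
        row = {
            "variable": f"{outcome}_complications",
            "kind": "outcome",
            "count_msas_gt6": e_hi,
            "count_msas_le6": e_lo,
            "n_msas_gt6": n_hi,
            "n_msas_le6": n_lo,
        }
        try:
            chosen = test_selector(table)
            selections[outcome] = chosen
            res = chi_square_2x2(table) if chosen == "chi_square" else fisher_exact_2x2(table)
            row.update(test=chosen, statistic=res.statistic, p_value=res.p_value)
        except ValueError as exc:
            row.update(test="not_computable", statistic=None, p_value=None, note=str(exc))
        low_comparison.append(row)

    odds_ratios: dict[str, dict] = {}
    for outcome in _OUTCOMES:
        e_lo = sum(f[outcome] for f, l in zip(flags, low) if l)
        e_hi = sum(f[outcome] for f, l in zip(flags, low) if not l)
        n_lo = sum(low)
        n_hi = n - n_lo
        # exposed (low MSAS) first, so a = low-score patients with the outcome
        table = ContingencyTable.from_counts(
            [e_lo, e_hi], [n_lo - e_lo, n_hi - e_hi], labels=["msas_le6", "msas_gt6"]
        )
        try:
            orr = odds_ratio_2x2(table)
            odds_ratios[outcome] = {
                "estimate_kind": "crude",
                "or": orr.or_estimate,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "continuity_corrected": orr.continuity_corrected,
            }
        except ValueError as exc:
            odds_ratios[outcome] = {"estimate_kind": "crude", "note": str(exc)}

    trend_panel: dict[str, dict] = {}
    order = (RiskStratum.LOW, RiskStratum.MODERATE, RiskStratum.HIGH)
    for outcome in ("perioperative", "intraoperative"):
        per_stratum = []
        events, nonevents = [], []
        for score, stratum in enumerate(order, start=1):
            idx = [i for i, s in enumerate(strata) if s is stratum]
            e = sum(flags[i][outcome] for i in idx)
            per_stratum.append(
                {
                    "stratum": stratum.value,
                    "score": score,
                    "n": len(idx),
                    "events": e,
                    "fraction": (e / len(idx)) if idx else None,
                }
            )
            if idx:
                events.append(e)
                nonevents.append(len(idx) - e)
        panel: dict = {"per_stratum": per_stratum}
        try:
            if len(events) < 2:
                raise ValueError("fewer than 2 non-empty strata")
            res = linear_by_linear(
                ContingencyTable.from_counts(
                    events, nonevents, scores=list(range(1, len(events) + 1))
                )
            )
            panel.update(m2=res.statistic, df=res.df, p_value=res.p_value)
        except ValueError as exc:
            panel.update(m2=None, df=None, p_value=None, note=f"not computable: {exc}")
        trend_panel[outcome] = panel

    stratum_counts = {s.value: sum(st is s for st in strata) for s in order}
    score_summary = {
        "rubric": rubric.name,
        "msas_mean": float(np.mean(totals)),
        "msas_sd": float(np.std(totals, ddof=1)) if n > 1 else None,
        "sas_mean": float(np.mean(sas_totals)),
        "sas_sd": float(np.std(sas_totals, ddof=1)) if n > 1 else None,
        "n_low_msas": int(sum(low)),
        "n_high_msas": int(n - sum(low)),
        "stratum_counts": stratum_counts,
    }
    # internal consistency of a program-generated cohort
    assert sum(stratum_counts.values()) == n
    assert stratum_counts["moderate"] + stratum_counts["high"] == sum(low)

    provenance = {
        "package_version": __version__,
        "rubric": rubric.name,
        "test_selections": selections,
        "seed": seed,
        "n_patients": n,
    }
    return AnalysisReport(
        n_patients=n,
        complication_summary=summary.to_dict(),
        group_comparison=group_comparison,
        low_msas_comparison=low_comparison,
        odds_ratios=odds_ratios,
        trend_panel=trend_panel,
        score_summary=score_summary,
        provenance=provenance,
    )


def analyze_count_table(table: ContingencyTable) -> dict:
    """Analyze an externally supplied count table as given.

    For 2 rows: the selected 2x2 test (chi-square or Fisher) plus the
    crude odds ratio with the first row as the exposed group.  For any
    number of rows with monotone scores: the linear-by-linear trend
    test.  No cohort-level consistency is assumed or checked.
    """
    out: dict = {
        "rows": [
            {"label": r.label, "score": r.score, "events": r.events, "nonevents": r.nonevents}
            for r in table.rows
        ],
        "N": table.N,
    }
    if len(table.rows) == 2:
        try:
            chosen = test_selector(table)
            res = chi_square_2x2(table) if chosen == "chi_square" else fisher_exact_2x2(table)
            out["test"] = {
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "p_display": format_p(res.p_value),
            }
        except ValueError as exc:
            out["test"] = {"note": f"not computable: {exc}"}
        try:
            orr = odds_ratio_2x2(table)
            out["odds_ratio"] = {
                "estimate_kind": "crude",
                "or": orr.or_estimate,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "continuity_corrected": orr.continuity_corrected,
            }
        except ValueError as exc:
            out["odds_ratio"] = {"estimate_kind": "crude", "note": str(exc)}
    try:
        res = linear_by_linear(table)
        out["trend"] = {
            "method": res.method,
            "m2": res.statistic,
            "p_value": res.p_value,
            "p_display": format_p(res.p_value),
        }
    except ValueError as exc:
        out["trend"] = {"note": f"not computable: {exc}"}
    return out


def _flatten(prefix: str, obj, rows: list) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _flatten(f"{prefix}[{i}]", v, rows)
    else:
        rows.append((prefix, obj))


def render_report(report: AnalysisReport, format: str = "text") -> str:
    """Render to ``text`` (human-readable), ``csv`` (flat cells) or
    ``json`` (lossless)."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format == "csv":
        rows: list = []
        _flatten("", report.to_dict(), rows)
        lines = ["cell,value"] + [f"{k},{v}" for k, v in rows]
        return "\n".join(lines) + "\n"
    if format != "text":
        raise ValueError(f"unknown format {format!r}; choose text, csv or json")

    cs = report.complication_summary
    lines = [
        f"Cohort analysis (n = {report.n_patients}, rubric {report.provenance['rubric']})",
        "",
        "Complication tabulation",
        f"  patients with any complication: {cs['n_any']} "
        f"({100 * cs['n_any'] / cs['n_patients']:.1f}%)",
        f"  intraoperative: {cs['n_intraoperative']}  postoperative: "
        f"{cs['n_postoperative']}  both: {cs['n_both']}",
        f"  total complications: {cs['n_events']}",
        "  Clavien-Dindo grades (% of complications):",
    ]
    for g in ("I", "II", "III", "IV", "V"):
        lines.append(
            f"    Grade {g}: {cs['grade_counts'][g]} ({cs['grade_pct'][g]:.1f}%)"
        )
    lines += ["", "Low-MSAS (<=6) comparison"]
    for row in report.low_msas_comparison:
        if row.get("p_value") is not None:
            lines.append(
                f"  {row['variable']}: p = {format_p(row['p_value'])} ({row['test']})"
            )
    lines += ["", "Crude odds ratios for low MSAS"]
    for outcome, orr in report.odds_ratios.items():
        if "or" in orr:
            lines.append(
                f"  {outcome}: OR {orr['or']:.2f} "
                f"(95% CI {orr['ci_low']:.2f}-{orr['ci_high']:.2f}, crude)"
            )
        else:
            lines.append(f"  {outcome}: {orr.get('note', 'not computable')}")
    lines += ["", "Risk-stratified trend (linear-by-linear)"]
    for outcome, panel in report.trend_panel.items():
        if panel.get("p_value") is not None:
            lines.append(
                f"  {outcome}: M2 = {panel['m2']:.3f}, p = {format_p(panel['p_value'])}"
            )
        else:
            lines.append(f"  {outcome}: {panel.get('note', 'not computable')}")
        for s in panel["per_stratum"]:
            frac = "-" if s["fraction"] is None else f"{100 * s['fraction']:.1f}%"
            lines.append(
                f"    {s['stratum']}: {s['events']}/{s['n']} ({frac})"
            )
    return "\n".join(lines) + "\n"
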