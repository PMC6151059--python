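#!/usr/bin/env python
"""Full association analysis of the synthetic cohort.

Scores every patient (MSAS and SAS), compares covariates between
complication groups and between the low-score (MSAS <= 6) and
high-score groups, computes crude odds ratios for each outcome class,
and runs the risk-stratified linear-by-linear trend tests.  Writes
``results/report.json`` (lossless) and ``results/report.txt``
(readable) and prints the latter.
"""

from pathlib import Path

from msas.cohort_io import read_cohort
from msas.pipeline import render_report, run_analysis

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    vitals_path = RESULTS / "vitals.csv"
    cohort = read_cohort(
        RESULTS / "cohort.csv",
        vitals_path=vitals_path if vitals_path.exists() else None,
    )
    report = run_analysis(cohort, seed=7)
    (RESULTS / "report.json").write_text(render_report(report, "json"))
    text = render_report(report, "text")
    (RESULTS / "report.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
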