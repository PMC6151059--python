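# Methods

## Scoring model

The surgical Apgar score sums three component scores — estimated blood
loss (EBL, mL), lowest mean arterial pressure (MAP, mmHg) and lowest
heart rate (HR, beats/min) over the anesthesia record — into a 0–10
total; lower totals indicate worse intraoperative physiology. The
modified score (MSAS) replaces the open-surgery EBL bins with
≤ 50 / 51–150 / 151–300 / > 300 mL, reflecting the lower blood loss of
robotic surgery, and leaves MAP and HR untouched.

Rubrics are interval lists over the reals, validated to be disjoint
and to cover each component's physical domain (EBL ≥ 0, MAP > 0,
HR > 0). Boundary conventions, applied literally to the printed table:
ranges "a–b" are upper-inclusive half-open intervals, "> x" is strict,
"≤ x"/"≥ x" inclusive. Two deliberate edge cases:

- **HR = 55** appears in both the 4-point ("≤ 55") and 3-point
  ("55–65") rows as printed; it earns 4 points here, and the 3-point
  bin is read as (55, 65], the original scoring convention.
- **EBL = 300 mL** earns 1 MSAS point (the 0-point bin is strictly
  > 300) *and* constitutes a bleeding complication (the complication
  threshold is ≥ 300, inclusive). The two printed rules are kept as
  stated rather than harmonized; cases strictly above 300 mL have both
  0 points and a bleeding event.

Dichotomization: total ≤ 6 is the low-score group (a deliberately
higher cutoff than the ≤ 4 used in open-surgery work; a custom rubric
plus cutoff can reproduce that variant). Stratification: 7–10 low,
5–6 moderate, 0–4 high risk. Minima are taken over whatever samples
exist — no imputation, no artifact cleaning — with a warning below
3 samples.

## Complication coding

Events are coded, never inferred: the CSV carries
`code[:treatment_level]` tokens. Timing is a pure function of the code
(transfusion within 72 h, EBL ≥ 300 mL and organ injury are
intraoperative; fever > 24 h, urinary distention, ileus, vault
bleeding, 30-day readmission, lymphedema, dysrhythmia, nerve palsy,
wound dehiscence, fistula and peritonitis are postoperative).
Clavien-Dindo grades derive from treatment intensity — none/bedside →
I, pharmacological → II, surgical/endoscopic/radiological intervention
→ III (IIIa/IIIb collapsed), ICU/life-threatening → IV, death → V.

Tabulation uses two denominators, as is conventional for this design:
per-code percentages against the number of patients, per-grade
percentages against the number of complications. Patient-level flags
(any / intraoperative / postoperative / both) satisfy
inclusion–exclusion: `both = intra + post − any`.

## Statistical procedures

All statistics are computed from their textbook formulas, with
`scipy.stats` supplying only distribution tail functions; scipy's own
tests serve as independent oracles in the test suite.

- **Pearson chi-square (2×2)**: Σ(O−E)²/E, df = 1, no Yates correction
  by default (the value SPSS labels "Pearson Chi-Square"); a flag
  applies the correction. Undefined when a marginal is zero.
- **Fisher exact (2×2)**: two-sided p as the sum of hypergeometric
  probabilities of all tables with the observed margins whose
  probability does not exceed the observed table's (SPSS/R convention;
  a 1 + 1e−7 relative tolerance guards round-off, matching R's
  practice).
- **Linear-by-linear trend**: M² = (N−1)·r² with r the Pearson
  correlation between row score and binary outcome over the N
  individuals, df = 1. Scores default to 1, 2, 3 for low/moderate/high;
  since the statistic is invariant under affine score changes the
  choice is innocuous. On 2 rows M² equals (N−1)/N times the Pearson
  chi-square — checked as a property test. Undefined under zero
  variance in scores or outcome; the pipeline reports such panels as
  "not computable".
- **Odds ratio**: crude cross-product (a·d)/(b·c) with the exposed
  (low-score) row first; 95% CI by the Woolf log method
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). If any cell is zero the
  Haldane–Anscombe 0.5 is added to every cell and the result flagged.
  Every OR in the report is labelled "crude": no adjustment of any kind
  is performed, and externally reported ORs that disagree with the
  crude value computed from the same printed counts are not
  reconciled.
- **Student t**: pooled-variance two-sample t, two-sided.
- **Test selection (2×2)**: Fisher iff any expected cell count is
  below 5, else chi-square; the choice is recorded in the report's
  provenance block.

P-values are kept at full precision and displayed as "< 0.001" below
0.001, otherwise at two decimals (three when two would display 0.00).

## Count-level versus cohort-level analysis

The cohort-level pipeline asserts internal consistency (stratum sizes
sum to the cohort; moderate+high equals the low-score group).
Published summary tables do not always satisfy such identities — in
the motivating study the printed stratum sizes (15/90/33) are
arithmetically incompatible with the printed low-score group size
(52), and the running text disagrees with the table on one count
(21 vs. 26 low-score intraoperative events). The count-table entry
point therefore analyzes each supplied table exactly as given, with no
cross-table reconciliation and no guess as to which printed figure is
correct.

## Synthetic cohort model

No patient-level data are available, so the generator emulates a
cohort with the reported marginal structure. Distribution families are
this package's own modelling choices, picked for simplicity and
closed-form checkability:

| quantity | model | default |
|---|---|---|
| age, BMI, surgical time, preop Hb | independent Normals | 44.1 ± 10.1 y; 22.9 ± 3.0 kg/m²; 190 ± 70.9 min (floor 60); 13.0 ± 1.2 g/dL |
| postop Hb | preop − max(N(1.0, 0.8), 0) | — |
| procedure / NAC / comorbidity / prior surgery | Bernoullis | 21/138, 7/138, 24/138, 53/138 |
| MAP, HR series | independent AR(1) around patient baselines, sampled every 5 min over the surgical time, floored at 20 mmHg / 30 bpm | baselines N(84, 8) and N(72, 9); φ = 0.8; innovation SD 6.0 / 4.5 |
| EBL | log-normal | median 120 mL; log-SD 0.7663 |
| transfusion | Bernoulli(logistic(−2.7 + 0.8·(6.5 − MSAS))) | — |
| organ injury | two independent Bernoullis | 1/138 each |
| postoperative event | Bernoulli(logistic(−1.0 + 0.30·t̃ + 0.15·(6.5 − MSAS))), t̃ standardized surgical time | code drawn from the empirical postoperative frequency profile |
| Clavien grade | multinomial per event | (0.731, 0.194, 0.075, 0, 0); IV/V configurable |

The EBL log-SD is the closed-form solution to
P(EBL ≥ 300) = 16/138 given the median: σ = ln(300/120)/Φ⁻¹(1 −
16/138). The definitional coupling EBL ≥ 300 ⇒ bleeding event is
generated, not sampled, and can be disabled (together with the
transfusion slope) to produce a genuine null for calibration studies.
The MAP baseline/innovation and the logistic intercepts were
calibrated once so that, at large n, the low-score (≤ 6) fraction sits
near 52/138 (simulated 0.379), the MSAS mean in 6.5–7.0 (6.87), and
intraoperative prevalence near 27/138 (0.185); they are fixed
defaults, not fitting knobs.

What the generator does **not** emulate: correlation among covariates
(none is reported; independence is assumed), measurement artifacts in
vitals (cuff errors, gaps), within-patient repeat events of the same
code, and any joint distribution beyond the stated marginals and the
score–outcome links. Passing tests on synthetic data therefore
demonstrate the pipeline's correctness and the test's operating
characteristics under this model — not clinical validity on real
records.

## Operating characteristics

`analysis/05_calibration_power.py` (and the corresponding test) runs
200 seeded replicates at n = 5000: with the calibrated positive
score-outcome slope, the risk-stratified linear-by-linear test on
intraoperative complications rejects at p < 0.001 in 100% of
replicates; with the slope zeroed and the coupling disabled, the
rejection rate at α = 0.05 is 0.06. Replicate counts and n were chosen
to give ~1.5% Monte-Carlo standard error on the null rejection rate
while keeping the study a sub-minute computation; cohorts in these
studies carry precomputed vitals minima rather than materialized
series, which changes nothing statistically.

## Numerical and degenerate-input choices

- Bin lookup accepts non-integer measurements; scores are integers.
- Zero-variance inputs (all-event or no-event tables, constant t-test
  groups) raise rather than return NaN; the pipeline converts these to
  explicit "not computable" entries.
- Cohort CSV numbers round-trip at 6 significant digits.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng` / `SeedSequence.spawn`; rerunning any
  driver with the same seed is byte-identical.

## Known limitations

- Cohort-dependent published quantities (covariate means per group,
  the published adjusted-looking ORs) are not reproducible without the
  original records; the package reproduces structure, printed-count
  statistics, and rubric arithmetic exactly, and everything else on
  synthetic data only.
- The trend test's χ²(1) reference is asymptotic; at very small
  stratum sizes its calibration degrades (the test suite exercises it
  at the printed n = 138 and at n = 5000).
- Only two organ-injury codes are modelled, matching the taxonomy's
  tabulated categories.
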