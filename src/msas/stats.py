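"""Contingency-table and two-sample inference, implemented from formulas.

The procedures here are the ones the dichotomized and risk-stratified
score analyses need:

* Pearson chi-square for a 2x2 table (no Yates continuity correction by
  default, matching the SPSS "Pearson Chi-Square" row; a flag enables it);
* Fisher's exact test, two-sided by summing hypergeometric probabilities
  no larger than the observed table's (the SPSS/R convention, not the
  doubling convention);
* the linear-by-linear association (Mantel-Haenszel trend) test,
  M^2 = (N - 1) r^2 with r the Pearson correlation between the row score
  and the binary outcome over all N individuals, df = 1;
* the crude odds ratio with a Woolf (log-normal) 95% CI, with the
  Haldane-Anscombe 0.5 correction applied to every cell iff any cell is
  zero;
* the pooled-variance two-sample Student t test.

Tail probabilities come from ``scipy.stats`` distributions; the test
statistics themselves are computed here from their textbook formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

__all__ = [
    "ContingencyTable",
    "TestResult",
    "OddsRatioResult",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "linear_by_linear",
    "odds_ratio_2x2",
    "students_t",
    "test_selector",
    "expected_counts",
]


@dataclass(frozen=True)
class Row:
    label: str
    score: float
    events: int
    nonevents: int

    def __post_init__(self) -> None:
        if self.events < 0 or self.nonevents < 0:
            raise ValueError(f"negative count in row {self.label!r}")

    @property
    def n(self) -> int:
        return self.events + self.nonevents


@dataclass(frozen=True)
class ContingencyTable:
    """Exposure levels (rows) cross-classified against a binary outcome."""

    rows: tuple[Row, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("contingency table needs at least 2 rows")
        if self.N == 0:
            raise ValueError("contingency table is empty")

    @classmethod
    def from_counts(
        cls,
        events: Sequence[int],
        nonevents: Sequence[int],
        scores: Optional[Sequence[float]] = None,
        labels: Optional[Sequence[str]] = None,
    ) -> "ContingencyTable":
        if len(events) != len(nonevents):
            raise ValueError("events and nonevents differ in length")
        k = len(events)
        if scores is None:
            scores = list(range(1, k + 1))
        if labels is None:
            labels = [f"level_{i + 1}" for i in range(k)]
        return cls(
            tuple(
                Row(str(l), float(s), int(e), int(ne))
                for l, s, e, ne in zip(labels, scores, events, nonevents)
            )
        )

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        """Read the ``label,score,events,nonevents`` CSV dialect."""
        import pandas as pd

        df = pd.read_csv(path)
        required = {"label", "score", "events", "nonevents"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"counts CSV missing column(s): {sorted(missing)}")
        return cls.from_counts(
            df["events"].tolist(),
            df["nonevents"].tolist(),
            scores=df["score"].tolist(),
            labels=df["label"].tolist(),
        )

    @property
    def N(self) -> int:
        return sum(r.n for r in self.rows)

    @property
    def events_total(self) -> int:
        return sum(r.events for r in self.rows)

    def to_array(self) -> np.ndarray:
        return np.array([[r.events, r.nonevents] for r in self.rows], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    continuity_corrected: bool = False


def _as_2x2(table: ContingencyTable) -> np.ndarray:
    if len(table.rows) != 2:
        raise ValueError(f"expected a 2x2 table, got {len(table.rows)} rows")
    return table.to_array()


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence (row total x col total / N)."""
    obs = table.to_array()
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def chi_square_2x2(table: ContingencyTable, continuity: bool = False) -> TestResult:
    """Pearson chi-square for a 2x2 table, df = 1.

    ``continuity=True`` applies the Yates correction (|O-E| reduced by
    0.5 before squaring); the default reports the uncorrected statistic.
    """
    obs = _as_2x2(table)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a marginal total is zero")
    exp = expected_counts(table)
    dev = np.abs(obs - exp)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / exp).sum())
    p = float(chi2_dist.sf(stat, 1))
    method = "pearson_chi_square" + ("_yates" if continuity else "")
    return TestResult(stat, 1, p, method)


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test, conditional on both margins.

    p = sum of hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's (with a small relative tolerance against round-off).
    """
    obs = _as_2x2(table).astype(int)
    a = obs[0, 0]
    r1 = int(obs[0].sum())
    c1 = int(obs[:, 0].sum())
    n = int(obs.sum())
    if n == 0:
        raise ValueError("empty table")
    rv = hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return TestResult(float(p_obs), 0, min(p, 1.0), "fisher_exact")


def linear_by_linear(
    table: ContingencyTable, scores: Optional[Sequence[float]] = None
) -> TestResult:
    """Linear-by-linear (Mantel-Haenszel) trend test for an ordered
    exposure against a binary outcome.

    M^2 = (N - 1) r^2, r being the Pearson correlation between the row
    score and the 0/1 outcome over the N individuals; p is two-sided
    from chi-square with 1 df.  The statistic is invariant under affine
    transformation of the scores.
    """
    if scores is None:
        scores = [r.score for r in table.rows]
    x = np.asarray(scores, dtype=float)
    if len(x) != len(table.rows):
        raise ValueError("one score per row required")
    if not (np.all(np.diff(x) > 0) or np.all(np.diff(x) < 0)):
        raise ValueError("scores must be strictly monotone across rows")
    n_i = np.array([r.n for r in table.rows], dtype=float)
    e_i = np.array([r.events for r in table.rows], dtype=float)
    N = n_i.sum()
    sx = float(np.dot(n_i, x))
    sxx = float(np.dot(n_i, x * x))
    sy = float(e_i.sum())
    syy = sy  # outcome is 0/1
    sxy = float(np.dot(e_i, x))
    var_x = N * sxx - sx * sx
    var_y = N * syy - sy * sy
    if var_x <= 0 or var_y <= 0:
        raise ValueError(
            "trend test undefined: zero variance in scores or outcome"
        )
    r = (N * sxy - sx * sy) / math.sqrt(var_x * var_y)
    m2 = (N - 1) * r * r
    p = float(chi2_dist.sf(m2, 1))
    return TestResult(float(m2), 1, p, "linear_by_linear")


def odds_ratio_2x2(table: ContingencyTable, alpha: float = 0.05) -> OddsRatioResult:
    """Crude odds ratio (a d)/(b c) with Woolf log-interval CI.

    The first row is the exposed group and the events column is the
    outcome, so ``a`` is the exposed-event cell.  If any cell is zero
    the Haldane-Anscombe 0.5 correction is added to every cell and the
    result is flagged.
    """
    obs = _as_2x2(table)
    corrected = bool((obs == 0).any())
    if corrected:
        obs = obs + 0.5
    a, b = obs[0]
    c, d = obs[1]
    if b * c == 0:
        raise ValueError("odds ratio undefined: zero denominator cell")
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    from scipy.stats import norm

    z = float(norm.ppf(1 - alpha / 2))
    lo = or_est * math.exp(-z * se)
    hi = or_est * math.exp(z * se)
    return OddsRatioResult(float(or_est), float(lo), float(hi), alpha, corrected)


def students_t(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample t test, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("t test undefined: zero pooled variance")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * float(t_dist.sf(abs(t), df))
    return TestResult(float(t), df, min(p, 1.0), "students_t_pooled")


def test_selector(table: ContingencyTable) -> str:
    """Choose the 2x2 test: Fisher iff any expected cell count < 5."""
    exp = expected_counts(table)
    if exp.shape != (2, 2):
        raise ValueError("test selection applies to 2x2 tables")
    return "fisher" if (exp < 5).any() else "chi_square"
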