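"""Contingency-table inference against independent oracles.

Oracles: scipy's reference tests, a combinatorial Fisher enumeration
(binomial coefficients, no distribution calls), and an individual-level
Pearson-correlation computation of the trend statistic.
"""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from msas.stats import (
    ContingencyTable,
    chi_square_2x2,
    expected_counts,
    fisher_exact_2x2,
    linear_by_linear,
    odds_ratio_2x2,
    students_t,
)
from msas.stats import test_selector as choose_test


def t2x2(a, b, c, d):
    return ContingencyTable.from_counts([a, c], [b, d])


def fisher_bruteforce(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    def prob(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def trend_by_expansion(events, nonevents, scores):
    """M^2 from the individual-level correlation, expanded explicitly."""
    x = np.repeat(np.asarray(scores, float), np.asarray(events) + np.asarray(nonevents))
    y = np.concatenate(
        [np.r_[np.ones(e), np.zeros(ne)] for e, ne in zip(events, nonevents)]
    )
    r = np.corrcoef(x, y)[0, 1]
    n = len(x)
    return (n - 1) * r * r


class TestChiSquare:
    def test_identical_proportions(self):
        res = chi_square_2x2(t2x2(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_dichotomized_score_table(self):
        # high-score group 1/86 events vs low-score group 26/52
        res = chi_square_2x2(t2x2(1, 85, 26, 26))
        assert round(res.statistic, 1) == 49.1
        assert res.p_value < 0.001

    def test_hand_computed_statistic(self):
        # sum (O-E)^2/E with expected counts from the margins
        a, b, c, d = 1, 85, 26, 26
        n = a + b + c + d
        exp = [
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n,
        ]
        obs = [a, b, c, d]
        stat = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert chi_square_2x2(t2x2(a, b, c, d)).statistic == pytest.approx(stat)

    @given(st.lists(st.integers(1, 40), min_size=4, max_size=4))
    def test_matches_scipy_uncorrected(self, cells):
        a, b, c, d = cells
        res = chi_square_2x2(t2x2(a, b, c, d))
        ref_stat, ref_p, _, _ = scipy.stats.chi2_contingency(
            [[a, b], [c, d]], correction=False
        )
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)

    @given(st.lists(st.integers(1, 40), min_size=4, max_size=4))
    def test_invariance_under_transpose_and_swaps(self, cells):
        a, b, c, d = cells
        base = chi_square_2x2(t2x2(a, b, c, d)).statistic
        assert chi_square_2x2(t2x2(a, c, b, d)).statistic == pytest.approx(base)
        assert chi_square_2x2(t2x2(d, c, b, a)).statistic == pytest.approx(base)

    def test_yates_correction_flag(self):
        plain = chi_square_2x2(t2x2(5, 10, 12, 4))
        yates = chi_square_2x2(t2x2(5, 10, 12, 4), continuity=True)
        assert yates.statistic < plain.statistic

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2(t2x2(0, 5, 0, 5))


class TestFisher:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((2, 3, 3, 2), 1.0),
            ((5, 0, 0, 5), 2 / math.comb(10, 5)),
            ((0, 5, 0, 5), 1.0),
        ],
    )
    def test_known_tables(self, cells, expected):
        assert fisher_exact_2x2(t2x2(*cells)).p_value == pytest.approx(expected)

    @given(st.lists(st.integers(0, 7), min_size=4, max_size=4))
    def test_matches_bruteforce_enumeration(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(t2x2(a, b, c, d)).p_value
        assert p == pytest.approx(fisher_bruteforce(a, b, c, d))

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    def test_matches_scipy(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(t2x2(a, b, c, d)).p_value
        ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(ref)


class TestLinearByLinear:
    def test_stratified_intraoperative_counts(self):
        res = linear_by_linear(
            ContingencyTable.from_counts([0, 15, 10], [15, 75, 23], scores=[1, 2, 3])
        )
        assert round(res.p_value, 2) == 0.01

    def test_stratified_perioperative_counts(self):
        res = linear_by_linear(
            ContingencyTable.from_counts([7, 32, 14], [8, 58, 19], scores=[1, 2, 3])
        )
        assert round(res.p_value, 2) == 0.98

    def test_zero_correlation(self):
        res = linear_by_linear(
            ContingencyTable.from_counts([5, 5, 5], [5, 5, 5], scores=[1, 2, 3])
        )
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 30), min_size=3, max_size=5),
        st.lists(st.integers(0, 30), min_size=3, max_size=5),
    )
    def test_matches_individual_level_expansion(self, events, nonevents):
        k = min(len(events), len(nonevents))
        events, nonevents = events[:k], nonevents[:k]
        n_i = [e + ne for e, ne in zip(events, nonevents)]
        if any(n == 0 for n in n_i):
            return
        sy = sum(events)
        if sy == 0 or sy == sum(n_i):
            return
        scores = list(range(1, k + 1))
        table = ContingencyTable.from_counts(events, nonevents, scores=scores)
        assert linear_by_linear(table).statistic == pytest.approx(
            trend_by_expansion(events, nonevents, scores)
        )

    @given(st.lists(st.integers(1, 30), min_size=4, max_size=4))
    def test_two_row_identity_with_chi_square(self, cells):
        # on 2 rows the trend statistic is (N-1)/N times Pearson chi-square
        a, b, c, d = cells
        table = t2x2(a, b, c, d)
        n = a + b + c + d
        m2 = linear_by_linear(table).statistic
        chi2 = chi_square_2x2(table).statistic
        assert m2 == pytest.approx((n - 1) / n * chi2)

    @given(
        st.floats(-5, 5),
        st.floats(0.1, 10),
    )
    def test_affine_score_invariance(self, shift, scale):
        table = ContingencyTable.from_counts([2, 9, 8], [13, 66, 25])
        base = linear_by_linear(table, scores=[1, 2, 3]).statistic
        moved = linear_by_linear(
            table, scores=[shift + scale * s for s in (1, 2, 3)]
        ).statistic
        assert moved == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            linear_by_linear(
                ContingencyTable.from_counts([0, 0, 0], [5, 5, 5], scores=[1, 2, 3])
            )
        with pytest.raises(ValueError, match="monotone"):
            linear_by_linear(
                ContingencyTable.from_counts([1, 2, 3], [4, 5, 6], scores=[1, 1, 2])
            )


class TestOddsRatio:
    def test_no_association(self):
        assert odds_ratio_2x2(t2x2(10, 10, 10, 10)).or_estimate == pytest.approx(1.0)

    def test_cross_product(self):
        assert odds_ratio_2x2(t2x2(20, 10, 10, 20)).or_estimate == pytest.approx(4.0)

    def test_crude_or_from_dichotomized_counts(self):
        # low-score row first: (26 events / 26 nonevents) vs (1 / 85)
        res = odds_ratio_2x2(t2x2(26, 26, 1, 85))
        assert res.or_estimate == pytest.approx(85.0)
        assert not res.continuity_corrected

    def test_ci_brackets_estimate(self):
        res = odds_ratio_2x2(t2x2(20, 10, 10, 20))
        assert res.ci_low <= res.or_estimate <= res.ci_high

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_reciprocal_under_row_swap(self, cells):
        a, b, c, d = cells
        orig = odds_ratio_2x2(t2x2(a, b, c, d)).or_estimate
        swapped = odds_ratio_2x2(t2x2(c, d, a, b)).or_estimate
        assert swapped == pytest.approx(1 / orig)

    def test_zero_cell_triggers_haldane(self):
        res = odds_ratio_2x2(t2x2(5, 0, 1, 9))
        assert res.continuity_corrected
        assert res.or_estimate == pytest.approx((5.5 * 9.5) / (0.5 * 1.5))


class TestStudentsT:
    def test_identical_groups(self):
        res = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            students_t([0, 0, 0, 0], [1, 1, 1, 1])

    def test_matches_reference_on_surgical_time_like_samples(self):
        rng = np.random.default_rng(2024)
        a = rng.normal(190, 70.9, 50)
        b = rng.normal(221, 90, 50)
        res = students_t(a, b)
        ref = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestSelector:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((1, 85, 26, 26), "chi_square"),  # min expected ~ 10.2
            ((1, 5, 2, 4), "fisher"),
            ((50, 50, 50, 50), "chi_square"),
        ],
    )
    def test_expected_count_rule(self, cells, expected):
        assert choose_test(t2x2(*cells)) == expected

    def test_expected_counts_match_margins(self):
        exp = expected_counts(t2x2(1, 85, 26, 26))
        # smallest expected cell: low-score row total x event column / N
        assert exp.min() == pytest.approx(52 * 27 / 138)


class TestContainer:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "counts.csv"
        path.write_text(
            "label,score,events,nonevents\nlow,1,0,15\nmoderate,2,15,75\nhigh,3,10,23\n"
        )
        table = ContingencyTable.from_csv(path)
        assert table.N == 138
        assert [r.events for r in table.rows] == [0, 15, 10]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("label,events\nx,1\ny,2\n")
        with pytest.raises(ValueError, match="missing column"):
            ContingencyTable.from_csv(path)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2 rows"):
            ContingencyTable.from_counts([1], [2])
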