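"""Scoring rubric: minima extraction, bin lookup, dichotomy, strata."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msas.scoring import (
    RiskStratum,
    ScoreRubric,
    VitalsSeries,
    builtin_rubric,
    compute_score,
    extract_minima,
    is_low_msas,
    load_rubric,
    save_rubric,
    score_component,
    stratify_risk,
)


# -- independent oracle: the printed score table as literal if/elif rules --

def table_ebl_points_msas(ebl):
    if ebl > 300:
        return 0
    if ebl > 150:
        return 1
    if ebl > 50:
        return 2
    return 3  # <= 50


def table_ebl_points_sas(ebl):
    if ebl > 1000:
        return 0
    if ebl > 600:
        return 1
    if ebl > 100:
        return 2
    return 3  # <= 100


def table_map_points(map_):
    if map_ < 40:
        return 0
    if map_ < 55:
        return 1
    if map_ < 70:
        return 2
    return 3  # >= 70


def table_hr_points(hr):
    # HR = 55 earns 4; the printed 3-point row "55-65" reads as (55, 65]
    if hr <= 55:
        return 4
    if hr <= 65:
        return 3
    if hr <= 75:
        return 2
    if hr <= 85:
        return 1
    return 0


class TestExtractMinima:
    def test_elementwise_minimum(self):
        vs = VitalsSeries.from_rows([(0, 80, 72), (5, 65, 68), (10, 70, 75)])
        assert extract_minima(vs) == (65, 68)

    def test_single_sample_warns(self):
        vs = VitalsSeries.from_rows([(0, 90, 60)])
        with pytest.warns(UserWarning, match="only 1 sample"):
            assert extract_minima(vs) == (90, 60)

    def test_planted_minima_in_long_series(self):
        # 40 samples; minima planted at different times
        rows = []
        for k in range(40):
            t = 5 * k
            m = 52.0 if t == 35 else 70.0 + (k % 5)
            h = 58.0 if t == 120 else 72.0 + (k % 7)
            rows.append((t, m, h))
        vs = VitalsSeries.from_rows(rows)
        brute = (min(r[1] for r in rows), min(r[2] for r in rows))
        assert brute == (52.0, 58.0)
        assert extract_minima(vs) == brute

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="at least one sample"):
            VitalsSeries(())

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            VitalsSeries.from_rows([(0, 80, 70), (0, 75, 72)])


class TestScoreComponent:
    @pytest.mark.parametrize(
        "value,component,expected",
        [
            (300, "ebl", 1),  # 151-300 earns 1; >300 earns 0
            (150, "ebl", 2),
            (70, "map", 3),  # >=70 is inclusive
            (55, "hr", 4),  # boundary overlap resolved to the 4-point bin
            (55, "map", 2),
            (39.999, "map", 0),
            (85, "hr", 1),
            (86, "hr", 0),
        ],
    )
    def test_printed_boundaries_msas(self, msas_rubric, value, component, expected):
        bins = getattr(msas_rubric, f"{component}_bins")
        assert score_component(value, bins) == expected

    def test_domain_errors(self, msas_rubric):
        with pytest.raises(ValueError):
            score_component(-1.0, msas_rubric.ebl_bins)
        with pytest.raises(ValueError):
            score_component(0.0, msas_rubric.map_bins)
        with pytest.raises(ValueError):
            score_component(-5.0, msas_rubric.hr_bins)

    def test_ebl_zero_is_valid(self, msas_rubric):
        assert score_component(0.0, msas_rubric.ebl_bins) == 3


class TestComputeScore:
    @pytest.mark.parametrize(
        "ebl,map_,hr,total",
        [
            (50, 70, 55, 10),  # best bin everywhere: 3 + 3 + 4
            (400, 35, 90, 0),  # worst bin everywhere
            (200, 60, 70, 5),  # 1 + 2 + 2
        ],
    )
    def test_known_totals_msas(self, msas_rubric, ebl, map_, hr, total):
        res = compute_score(ebl, map_, hr, msas_rubric)
        assert res.total == total
        assert res.total == res.ebl_points + res.map_points + res.hr_points

    @given(
        ebl=st.floats(0, 2000),
        map_=st.floats(0.1, 200),
        hr=st.floats(0.1, 200),
    )
    def test_total_in_range_both_rubrics(self, ebl, map_, hr):
        for name in ("msas", "sas"):
            total = compute_score(ebl, map_, hr, builtin_rubric(name)).total
            assert 0 <= total <= 10

    @given(map_=st.floats(0.1, 200), hr=st.floats(0.1, 200), ebl=st.floats(0, 2000))
    def test_rubrics_agree_on_map_and_hr(self, map_, hr, ebl):
        a = compute_score(ebl, map_, hr, builtin_rubric("msas"))
        b = compute_score(ebl, map_, hr, builtin_rubric("sas"))
        assert a.map_points == b.map_points
        assert a.hr_points == b.hr_points

    @given(
        ebl1=st.floats(0, 2000),
        ebl2=st.floats(0, 2000),
        map_=st.floats(0.1, 200),
        hr=st.floats(0.1, 200),
    )
    def test_monotone_nonincreasing_in_ebl(self, ebl1, ebl2, map_, hr):
        lo, hi = sorted([ebl1, ebl2])
        r = builtin_rubric("msas")
        assert compute_score(lo, map_, hr, r).total >= compute_score(hi, map_, hr, r).total

    @given(
        map1=st.floats(0.1, 200),
        map2=st.floats(0.1, 200),
        ebl=st.floats(0, 2000),
        hr=st.floats(0.1, 200),
    )
    def test_monotone_nondecreasing_in_map(self, map1, map2, ebl, hr):
        lo, hi = sorted([map1, map2])
        r = builtin_rubric("msas")
        assert compute_score(ebl, lo, hr, r).total <= compute_score(ebl, hi, hr, r).total


class TestGroupsAndStrata:
    @pytest.mark.parametrize("total,expected", [(6, True), (7, False), (0, True), (10, False)])
    def test_low_score_dichotomy(self, total, expected):
        assert is_low_msas(total) is expected

    @pytest.mark.parametrize(
        "total,stratum",
        [(10, RiskStratum.LOW), (7, RiskStratum.LOW), (6, RiskStratum.MODERATE),
         (5, RiskStratum.MODERATE), (4, RiskStratum.HIGH), (0, RiskStratum.HIGH)],
    )
    def test_stratification(self, total, stratum):
        assert stratify_risk(total) is stratum

    def test_partition_consistent_with_dichotomy(self):
        for total in range(11):
            s = stratify_risk(total)
            if s is RiskStratum.LOW:
                assert not is_low_msas(total)
            else:
                assert is_low_msas(total)

    @pytest.mark.parametrize("bad", [-1, 11, 5.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            is_low_msas(bad)
        with pytest.raises(ValueError):
            stratify_risk(bad)


class TestRubricObject:
    def test_max_total_is_ten(self, msas_rubric, sas_rubric):
        assert msas_rubric.max_total == 10
        assert sas_rubric.max_total == 10

    def test_component_grid_matches_printed_table(self, msas_rubric, sas_rubric):
        for ebl in range(0, 1201):
            assert score_component(ebl, msas_rubric.ebl_bins) == table_ebl_points_msas(ebl)
            assert score_component(ebl, sas_rubric.ebl_bins) == table_ebl_points_sas(ebl)
        for map_ in range(30, 121):
            assert score_component(map_, msas_rubric.map_bins) == table_map_points(map_)
        for hr in range(40, 121):
            assert score_component(hr, msas_rubric.hr_bins) == table_hr_points(hr)

    def test_yaml_round_trip(self, tmp_path, msas_rubric):
        path = tmp_path / "rubric.yaml"
        save_rubric(msas_rubric, path)
        assert load_rubric(path) == msas_rubric

    def test_custom_rubric_from_dict(self, msas_rubric):
        d = msas_rubric.to_dict()
        d["name"] = "custom"
        custom = ScoreRubric.from_dict(d)
        assert custom.name == "custom"
        assert custom.ebl_bins == msas_rubric.ebl_bins

    def test_gapped_bins_rejected(self, msas_rubric):
        d = msas_rubric.to_dict()
        d["ebl_bins"][1]["lo"] = 60  # gap (50, 60)
        with pytest.raises(ValueError, match="contiguous"):
            ScoreRubric.from_dict(d)

    def test_unknown_builtin_rejected(self):
        with pytest.raises(ValueError, match="unknown built-in"):
            builtin_rubric("apgar")

    def test_non_integer_measurements_accepted(self, msas_rubric):
        res = compute_score(50.5, 69.9, 55.1, msas_rubric)
        assert (res.ebl_points, res.map_points, res.hr_points) == (2, 2, 3)
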