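"""Fractionator/Cavalieri estimators, caliper arithmetic and summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from disector import (
    CaliperRecord,
    CountTable,
    SamplingDesign,
    estimate_from_table,
    estimate_total_number,
    estimate_volume,
    group_summary,
    mean_section_thickness,
    rank_correlation,
    round_half_away,
    shrinkage_index,
)
from disector.exceptions import ValidationError


class TestTotalNumber:
    @pytest.mark.parametrize(
        "sum_q, expected",
        [(159, 9938), (180, 11250), (172, 10750)],
    )
    def test_worked_examples(self, sum_q, expected):
        n = estimate_total_number(sum_q, inv_ssf=50, inv_asf=2.50, bidirectional=True)
        assert round_half_away(n) == expected

    def test_zero_counts_zero_estimate(self):
        assert estimate_total_number(0, 50, 2.5) == 0.0

    def test_half_rounds_away_from_zero(self):
        assert round_half_away(9937.5) == 9938
        assert round_half_away(-2.5) == -3

    @given(st.integers(0, 500), st.integers(1, 100))
    def test_linear_in_counts(self, sum_q, k):
        base = estimate_total_number(sum_q, 50, 2.5)
        assert estimate_total_number(k * sum_q, 50, 2.5) == pytest.approx(k * base)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            estimate_total_number(-1, 50, 2.5)


class TestVolume:
    @pytest.mark.parametrize("sum_p, expected", [(181, 6.79), (147, 5.51)])
    def test_worked_examples(self, sum_p, expected):
        v = estimate_volume(sum_p, 387.29, 387.29, 5.0, 50)
        assert round(v, 2) == expected

    def test_zero_points(self):
        assert estimate_volume(0, 387.29, 387.29, 5.0, 50) == 0.0

    def test_unit_round_trip(self):
        # V equals the area represented by the points times t times 1/ssf
        v = estimate_volume(10, 100.0, 200.0, 5.0, 50)
        assert v * 1e9 == pytest.approx(10 * 100.0 * 200.0 * 5.0 * 50)

    def test_bad_thickness_rejected(self):
        with pytest.raises(ValidationError):
            estimate_volume(10, 387.29, 387.29, 0.0, 50)


class TestCaliper:
    def test_thickness_from_block_heights(self):
        rec = CaliperRecord(10.0, 6.5, 700)
        assert mean_section_thickness(rec) == pytest.approx(5.0)
        rec2 = CaliperRecord(10.0, 6.4975, 700)
        assert mean_section_thickness(rec2) == pytest.approx(5.0036, abs=1e-4)

    def test_zero_difference_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t = mean_section_thickness(CaliperRecord(5.0, 5.0, 700))
        assert t == 0.0

    def test_reversed_measurements_rejected(self):
        with pytest.raises(ValidationError):
            CaliperRecord(5.0, 6.0, 700)

    @pytest.mark.parametrize(
        "formalin, paraffin, expected", [(2.0, 2.0, 0.0), (2.0, 1.5, 0.25)]
    )
    def test_shrinkage_index(self, formalin, paraffin, expected):
        rec = CaliperRecord(10.0, 6.5, 700, formalin, paraffin)
        assert shrinkage_index(rec) == pytest.approx(expected)

    def test_weight_gain_flagged(self):
        rec = CaliperRecord(10.0, 6.5, 700, 2.0, 2.2)
        with pytest.warns(UserWarning, match="negative shrinkage"):
            assert shrinkage_index(rec) < 0


class TestGroupSummary:
    def test_single_animal(self):
        gs = group_summary([45.0], [100.0])
        assert gs.percent_reduction_per_animal == pytest.approx(55.0)

    def test_no_lesion_no_reduction(self):
        gs = group_summary([100.0, 80.0], [100.0, 80.0])
        assert gs.percent_reduction_per_animal == pytest.approx(0.0)

    def test_per_animal_mean_of_ratios(self):
        gs = group_summary([40.0, 60.0], [100.0, 100.0])
        assert gs.percent_reduction_per_animal == pytest.approx(50.0)
        assert gs.percent_reduction_of_means == pytest.approx(50.0)

    def test_zero_contra_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero contralateral"):
            gs = group_summary([40.0, 60.0], [100.0, 0.0])
        assert gs.excluded == (1,)
        assert gs.percent_reduction_per_animal == pytest.approx(60.0)


def _oracle_spearman(x, y):
    """Independent brute-force Spearman rho and exact permutation p."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = mid
            i = j + 1
        return r

    def rho_of(rx, ry):
        n = len(rx)
        mx = sum(rx) / n
        my = sum(ry) / n
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
        )
        return num / den

    rx, ry = ranks(x), ranks(y)
    rho = rho_of(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, list(perm))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


class TestRankCorrelation:
    def test_monotone_sequences(self):
        up = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        down = rank_correlation([1, 2, 3, 4], [9, 7, 4, 1])
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "x, y",
        [
            ([3, 1, 4, 1, 5], [2, 7, 1, 8, 2]),
            ([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]),
            ([10, 20, 20, 30, 40], [5, 3, 8, 1, 9]),
        ],
    )
    def test_matches_exhaustive_oracle(self, x, y):
        res = rank_correlation(x, y)
        rho_o, p_o = _oracle_spearman(x, y)
        assert res.method == "exact"
        assert abs(res.rho - rho_o) < 1e-12
        assert abs(res.p_value - p_o) < 1e-12

    def test_constant_vector_flagged(self):
        from disector.exceptions import UndefinedStatisticError

        with pytest.raises(UndefinedStatisticError):
            rank_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_large_n_permutation_p_close_to_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = rank_correlation(x, y, seed=1, n_permutations=4000)
        ref = stats.spearmanr(x, y)
        assert res.method == "permutation"
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=0.02)


class TestTableEstimation:
    def test_full_chain_on_worked_example(self, table2_q, paper_design):
        table = CountTable.from_q_list(table2_q)
        res = estimate_from_table(
            table, paper_design, inv_asf=2.50, label="worked-example"
        )
        assert res.n_reported == round_half_away(50 * 2.50 * 158 / 2)
        assert round(res.precision.ce, 2) == 0.08

    def test_thickness_override_scales_volume(self, paper_design):
        table = CountTable.from_q_list([10, 12], p=[50, 50])
        a = estimate_from_table(table, paper_design)
        b = estimate_from_table(table, paper_design, thickness=10.0)
        assert b.v_mm3 == pytest.approx(2 * a.v_mm3)
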