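"""Fisher exact / rank-sum / Kruskal-Wallis and the group-comparison table."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from brsrisk import (
    DegenerateTableError,
    DomainError,
    TwoByTwo,
    fisher_exact_2x2,
    kruskal_wallis,
    rank_sum_test,
    summarize_table1,
)
from brsrisk.descriptives import round_half_up


def fisher_mass_rule_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: enumerate all tables with the observed
    margins and sum hypergeometric probabilities <= the observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            comb(col1, k, exact=True)
            * comb(n - col1, row1 - k, exact=True)
            / comb(n, row1, exact=True)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return total


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[1, 0], [0, 1]], 1.0),
            ([[3, 1], [1, 3]], 34 / 70),
        ],
    )
    def test_enumerable_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=1e-12)

    def test_accepts_twobytwo(self):
        p = fisher_exact_2x2(TwoByTwo(22, 43, 10, 74))
        assert 0 < p < 0.005

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            got = fisher_exact_2x2([[a, b], [c, d]])
            want = fisher_mass_rule_oracle(a, b, c, d)
            assert got == pytest.approx(want, abs=1e-10)

    def test_empty_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    @given(st.tuples(*[st.integers(1, 15)] * 4))
    def test_invariant_under_double_swap(self, cells):
        a, b, c, d = cells
        p1 = fisher_exact_2x2([[a, b], [c, d]])
        p2 = fisher_exact_2x2([[d, c], [b, a]])
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRankSum:
    def test_exact_small_sample(self):
        _, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            rank_sum_test([], [1.0])

    @given(
        data=st.lists(st.integers(0, 30), min_size=6, max_size=40),
        split=st.integers(3, 20),
    )
    def test_invariant_under_monotone_transform(self, data, split):
        x = [float(v) for v in data[: min(split, len(data) - 3)]]
        y = [float(v) for v in data[len(x):]]
        if not x or not y:
            return
        _, p1 = rank_sum_test(x, y)
        f = lambda arr: [math.exp(0.3 * v) + v**3 for v in arr]
        _, p2 = rank_sum_test(f(x), f(y))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestKruskalWallis:
    def test_all_tied_defines_zero(self):
        h, p = kruskal_wallis([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_four_ranks(self):
        # ranks 1..4 in two groups of two: H = 12/20 * (2*1.5^2 + 2*3.5^2) - 15
        h, p = kruskal_wallis([[1.0, 2.0], [3.0, 4.0]])
        assert h == pytest.approx(2.4, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(2.4, 1), abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            kruskal_wallis([[1.0, 2.0]])

    def test_two_group_agreement_with_rank_sum(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(0.5, 1.2, size=22)
            _, p_kw = kruskal_wallis([x, y])
            _, p_rs = rank_sum_test(x, y, continuity=False)
            assert abs(p_kw - p_rs) < 0.005

    def test_type_i_error_rate(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(size=10) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestGroupSummaryTable:
    def test_syncope_row_matches_published_counts(self, table1_cohort):
        (row,) = summarize_table1(table1_cohort, ["syncope"])
        assert row.formatted() == ("22 (69)", "43 (37)")
        assert 0 < row.p_value < 0.01

    def test_group_sizes_conserved(self, table1_cohort):
        for row in summarize_table1(table1_cohort, ["syncope", "af", "qrs_ms"]):
            if row.kind == "binary":
                assert row.group_pos[2] + row.group_neg[2] == 149

    def test_quartile_convention_reproduces_printed_string(self):
        # a VT/VF-group QRS sample constructed to have exactly the printed
        # order statistics under linear-interpolation quantiles
        from brsrisk import Cohort, PatientRecord

        qrs_vals = [98.0, 98.0, 108.0, 114.0, 114.0]
        records = []
        for i, q in enumerate(qrs_vals):
            records.append(
                PatientRecord(
                    patient_id=f"H{i}", age_years=50, sex="male", syncope=False,
                    initial_type1=False, af=False, pvs_performed=False,
                    icd=False, qrs_ms=q, qtc_ms=410.0, vtvf=True,
                )
            )
        for i in range(5):
            records.append(
                PatientRecord(
                    patient_id=f"L{i}", age_years=50, sex="male", syncope=False,
                    initial_type1=False, af=False, pvs_performed=False,
                    icd=False, qrs_ms=102.0, qtc_ms=410.0, vtvf=False,
                )
            )
        (row,) = summarize_table1(Cohort(records=tuple(records)), ["qrs_ms"])
        assert row.formatted()[0] == "108 (98–114)"

    def test_uniform_cohort_degenerate(self):
        from brsrisk import Cohort, PatientRecord

        records = tuple(
            PatientRecord(
                patient_id=f"P{i}", age_years=50, sex="male", syncope=True,
                initial_type1=True, af=False, pvs_performed=False, icd=False,
                qrs_ms=100.0, qtc_ms=410.0, vtvf=(i < 2),
            )
            for i in range(4)
        )
        rows = summarize_table1(Cohort(records=records), ["syncope", "qrs_ms"])
        assert rows[0].group_pos[1] == 100 and rows[0].group_neg[1] == 100
        assert rows[1].p_value == 1.0

    def test_percent_rounding_half_up(self):
        assert round_half_up(68.75) == 69
        assert round_half_up(36.5) == 37
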