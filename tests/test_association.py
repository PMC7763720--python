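"""Odds ratios from 2x2 tables and the IRLS logistic fit."""

import math

import numpy as np
import pytest

from brsrisk import (
    DomainError,
    LogisticRegressionIRLS,
    SeparationError,
    TwoByTwo,
    ZeroCellError,
    fit_logistic,
    or_from_2x2,
    univariate_or_table,
)


def expand_table(t: TwoByTwo):
    """2x2 table as unit records: x = exposure, y = outcome."""
    x = np.concatenate(
        [np.ones(t.a), np.ones(t.b), np.zeros(t.c), np.zeros(t.d)]
    )
    y = np.concatenate(
        [np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
    )
    return np.column_stack([np.ones(x.size), x]), y


PUBLISHED_ROWS = [
    # (a, b, c, d, OR, lo, hi, p) as printed for the derivation cohort
    (TwoByTwo(22, 43, 10, 74), 3.79, 1.64, 8.74, 0.002),   # syncope
    (TwoByTwo(5, 5, 27, 112), 4.15, 1.12, 15.36, 0.033),   # atrial fibrillation
    (TwoByTwo(21, 58, 11, 59), 1.94, 0.86, 4.39, 0.110),   # initial type 1
    (TwoByTwo(10, 18, 3, 13), 2.41, 0.55, 10.52, 0.243),   # positive PVS
    (TwoByTwo(2, 22, 30, 95), 0.29, 0.06, 1.30, 0.105),    # sex, female coded 1
]


class TestOrFrom2x2:
    @pytest.mark.parametrize("table, or_, lo, hi, p", PUBLISHED_ROWS)
    def test_published_rows_to_printed_precision(self, table, or_, lo, hi, p):
        res = or_from_2x2(table)
        assert res.rounded() == (or_, lo, hi)
        assert round(res.p_value, 3) == p

    def test_symmetric_unit_table(self):
        res = or_from_2x2(TwoByTwo(1, 1, 1, 1))
        z = 1.959963984540054
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(math.exp(-z * 2), rel=1e-9)
        assert res.ci_high == pytest.approx(math.exp(z * 2), rel=1e-9)

    def test_zero_cell_error_names_cell(self):
        with pytest.raises(ZeroCellError, match="b"):
            or_from_2x2(TwoByTwo(3, 0, 2, 5))

    def test_haldane_correction_flag(self):
        res = or_from_2x2(TwoByTwo(3, 0, 2, 5), haldane=True)
        assert res.odds_ratio == pytest.approx((3.5 * 5.5) / (0.5 * 2.5))

    def test_double_swap_invariance(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(1, 40, size=4)
            t = TwoByTwo(int(a), int(b), int(c), int(d))
            r1 = or_from_2x2(t)
            r2 = or_from_2x2(t.swap_rows_and_columns())
            assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-12)
            assert r1.ci_low == pytest.approx(r2.ci_low, rel=1e-12)

    def test_reversed_exposure_gives_reciprocal(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(1, 40, size=4)
            t = TwoByTwo(int(a), int(b), int(c), int(d))
            r1 = or_from_2x2(t)
            r2 = or_from_2x2(t.reverse_exposure())
            assert r2.odds_ratio == pytest.approx(1 / r1.odds_ratio, rel=1e-12)
            assert r2.ci_low == pytest.approx(1 / r1.ci_high, rel=1e-12)
            assert r2.ci_high == pytest.approx(1 / r1.ci_low, rel=1e-12)


class TestIrls:
    def test_intercept_only_is_logit_of_prevalence(self):
        y = np.array([1] * 32 + [0] * 117, dtype=float)
        fit = fit_logistic(np.ones((149, 1)), y)
        assert fit.coef[0] == pytest.approx(math.log(32 / 117), abs=1e-8)

    def test_saturated_2x2_matches_cross_product(self):
        t = TwoByTwo(22, 43, 10, 74)
        X, y = expand_table(t)
        fit = fit_logistic(X, y)
        assert math.exp(fit.coef[1]) == pytest.approx(
            or_from_2x2(t).odds_ratio, rel=1e-6
        )

    def test_constant_outcome_rejected(self):
        with pytest.raises(DomainError):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_perfect_separation_detected(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(np.column_stack([np.ones(20), x]), y)

    def test_matches_statsmodels_on_random_design(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = np.column_stack([np.ones(200), rng.normal(size=(200, 3))])
        eta = X @ np.array([-1.0, 0.8, -0.5, 0.3])
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params, abs=1e-6)
        assert fit.se() == pytest.approx(ref.bse, rel=1e-4)

    def test_estimator_api_predicts_probabilities(self, rng):
        X = rng.normal(size=(120, 2))
        y = (X[:, 0] + rng.normal(scale=2, size=120) > 0).astype(int)
        clf = LogisticRegressionIRLS().fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (120, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert clf.get_params()["max_iter"] == 100
        clone = LogisticRegressionIRLS(**clf.get_params())
        assert clone.get_params() == clf.get_params()


class TestUnivariateTable:
    def test_published_rows_from_fixture(self, table1_cohort):
        rows = univariate_or_table(
            table1_cohort, ["syncope", "af", "initial_type1", "pvs_positive", "sex"]
        )
        expected = {
            "syncope": (3.79, 1.64, 8.74),
            "af": (4.15, 1.12, 15.36),
            "initial_type1": (1.94, 0.86, 4.39),
            "pvs_positive": (2.41, 0.55, 10.52),
            "sex": (0.29, 0.06, 1.30),
        }
        for row in rows:
            assert row.result is not None, row.error
            assert row.result.rounded() == expected[row.variable]

    def test_pvs_positive_restricted_to_tested_subjects(self, table1_cohort):
        (row,) = univariate_or_table(table1_cohort, ["pvs_positive"])
        assert row.n_used == 44

    def test_sex_coded_female_one(self, table1_cohort):
        (row,) = univariate_or_table(table1_cohort, ["sex"])
        assert "female=1" in row.result.coding
        assert row.result.odds_ratio < 1

    def test_constant_predictor_flagged_not_raised(self, table1_cohort):
        df = table1_cohort.to_frame()
        df["flat"] = 1.0
        (row,) = univariate_or_table(df, ["flat"])
        assert row.result is None
        assert row.error
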