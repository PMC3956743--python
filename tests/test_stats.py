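"""Correlation machinery, Williams/Steiger tests, chi-square utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ansdev import (
    CollinearCovariatesError,
    DegenerateInputError,
    InsufficientDataError,
    PartialSpec,
    chi_square_vs_chance,
    contingency_chi_square,
    correlation_table,
    crosslag_analysis,
    paired_t,
    partial_corr,
    pearson_r,
    steiger_z,
    williams_t,
)


def _random_cohort_frame(rng, n=60, k=3):
    cols = {f"c{i}": rng.standard_normal(n) for i in range(k)}
    x = rng.standard_normal(n) + 0.5 * cols["c0"]
    y = rng.standard_normal(n) + 0.4 * cols["c1"] - 0.3 * x
    return pd.DataFrame({"x": x, "y": y, **cols})


def precision_matrix_partial_r(df, x, y, covariates):
    """Independent oracle: partial r from the precision matrix of (x, y, Z)."""
    cols = [x, y, *covariates]
    P = np.linalg.inv(np.corrcoef(df[cols].to_numpy(float).T))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


class TestPearson:
    def test_identity_is_one(self):
        x = np.arange(5.0)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_hand_computed_five_point_value(self):
        # frozen from an independent sum-formula computation
        x = [1.0, 2.0, 4.0, 5.0, 9.0]
        y = [2.0, 1.0, 5.0, 4.0, 8.0]
        assert pearson_r(x, y) == pytest.approx(0.9379366108168787, abs=1e-12)

    def test_independent_normals_near_zero(self, rng):
        x, y = rng.standard_normal(10**5), rng.standard_normal(10**5)
        assert abs(pearson_r(x, y)) < 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self, rng):
        df = _random_cohort_frame(rng)
        r, dof = partial_corr(df, PartialSpec("x", "y"))
        assert r == pytest.approx(pearson_r(df["x"], df["y"]))
        assert dof == len(df) - 2

    def test_matches_precision_matrix_oracle(self, rng):
        for _ in range(200):
            df = _random_cohort_frame(rng, n=int(rng.integers(20, 80)))
            r, dof = partial_corr(df, PartialSpec("x", "y", ("c0", "c1", "c2")))
            oracle = precision_matrix_partial_r(df, "x", "y", ("c0", "c1", "c2"))
            assert r == pytest.approx(oracle, abs=1e-10)
            assert dof == len(df) - 2 - 3

    def test_duplicated_covariate_is_collinear(self, rng):
        df = _random_cohort_frame(rng)
        df["dup"] = df["c0"]
        with pytest.raises(CollinearCovariatesError):
            partial_corr(df, PartialSpec("x", "y", ("c0", "dup")))

    def test_target_as_its_own_covariate_rejected(self):
        with pytest.raises(ValueError):
            PartialSpec("x", "y", ("y",))

    def test_listwise_deletion_and_minimum_n(self, rng):
        df = _random_cohort_frame(rng, n=8)
        df.loc[:3, "c0"] = np.nan
        with pytest.raises(InsufficientDataError):
            partial_corr(df, PartialSpec("x", "y", ("c0", "c1")))

    def test_agreement_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = _random_cohort_frame(rng)
        r, _ = partial_corr(df, PartialSpec("x", "y", ("c0", "c1")))
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c0", "c1"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)


class TestWilliamsT:
    def test_equal_correlations_give_zero(self):
        t, dof, p = williams_t(0.4, 0.4, 0.2, 57)
        assert t == 0.0
        assert dof == 54
        assert p == pytest.approx(0.5)

    def test_frozen_formula_value(self):
        # frozen from an independent hand computation of the formula
        t, dof, p = williams_t(0.6, 0.3, 0.4, 50)
        assert t == pytest.approx(2.3098382853874093, abs=1e-12)
        assert dof == 47
        assert p < 0.05

    @given(
        r_sa=st.floats(min_value=-0.8, max_value=0.8),
        r_as=st.floats(min_value=-0.8, max_value=0.8),
        r_pred=st.floats(min_value=-0.5, max_value=0.5),
        n=st.integers(min_value=10, max_value=500),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry(self, r_sa, r_as, r_pred, n):
        from hypothesis import assume

        det = 1 - r_sa**2 - r_as**2 - r_pred**2 + 2 * r_sa * r_as * r_pred
        assume(det >= 0)  # only consistent (positive-semidefinite) triples
        t1, _, _ = williams_t(r_sa, r_as, r_pred, n)
        t2, _, _ = williams_t(r_as, r_sa, r_pred, n)
        assert t1 == pytest.approx(-t2, abs=1e-12)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError):
            williams_t(0.9, -0.9, 0.9, 50)

    def test_nominal_size_under_shared_variable_null(self, rng):
        """Comparing corr(x,z) and corr(y,z) with equal population values."""
        C = np.array([[1.0, 0.4, 0.3], [0.4, 1.0, 0.3], [0.3, 0.3, 1.0]])
        L = np.linalg.cholesky(C)
        n, reps = 57, 2_000
        rej = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            R = np.corrcoef(X.T)
            _, _, p = williams_t(R[0, 2], R[1, 2], R[0, 1], n)
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z(0.3, 0.3, 0.5, 0.2, 0.2, 0.5, 57)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_antisymmetry(self):
        z1, _ = steiger_z(0.5, 0.2, 0.4, 0.3, 0.3, 0.4, 80)
        z2, _ = steiger_z(0.2, 0.5, 0.4, 0.3, 0.3, 0.4, 80)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_nominal_size_under_no_shared_variable_null(self, rng):
        """The quadrivariate setting Williams only approximates."""
        C = np.array(
            [[1.0, 0.5, 0.6, 0.3], [0.5, 1.0, 0.3, 0.6],
             [0.6, 0.3, 1.0, 0.5], [0.3, 0.6, 0.5, 1.0]]
        )
        L = np.linalg.cholesky(C)
        n, reps = 57, 2_000
        rej = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 4)) @ L.T
            R = np.corrcoef(X.T)
            _, p = steiger_z(R[0, 3], R[1, 2], R[0, 1], R[0, 2], R[3, 1], R[3, 2], n)
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se


class TestChiSquare:
    @pytest.mark.parametrize("k, expected", [(7, 4.5), (6, 2.0), (4, 0.0)])
    def test_values_against_hand_arithmetic(self, k, expected):
        assert chi_square_vs_chance(k, 8) == pytest.approx(expected)

    @given(n=st.integers(min_value=1, max_value=200), data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        assert chi_square_vs_chance(k, n) == pytest.approx(
            chi_square_vs_chance(n - k, n)
        )

    def test_contingency_identical_rows_zero(self):
        stat, dof = contingency_chi_square([[5, 10, 5], [5, 10, 5]])
        assert stat == pytest.approx(0.0)
        assert dof == 2

    def test_contingency_diagonal_table(self):
        stat, dof = contingency_chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_contingency_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            contingency_chi_square([[1, 0], [2, 0]])

    def test_published_knower_table_regression_value(self):
        """Pooled 2x7 level-by-wave counts; frozen from hand arithmetic.

        The standard Pearson statistic on these printed counts is 7.9259
        (recorded as a regression value; it is not the value printed
        alongside the original table, whose construction is unknown).
        """
        t1 = [2, 5, 13, 3, 9, 11, 14]
        t2 = [0, 2, 9, 2, 6, 20, 18]
        stat, dof = contingency_chi_square([t1, t2])
        assert stat == pytest.approx(7.925890238793464, abs=1e-9)
        assert dof == 6


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_hand_checked_fixture(self):
        t, dof = paired_t([10.0, 12.0, 9.0, 14.0, 11.0],
                          [11.0, 14.0, 9.0, 15.0, 13.0])
        assert t == pytest.approx(-3.2071349029490928, abs=1e-12)
        assert dof == 4

    def test_improvement_gives_negative_t(self, rng):
        x1 = rng.normal(0.69, 0.1, 57)
        x2 = x1 + rng.normal(0.11, 0.05, 57)
        t, _ = paired_t(x1, x2)
        assert t < 0


class TestCrossLagAnalysis:
    def _frame(self, rng, n=60, coupled=True):
        age = rng.uniform(36, 57, n)
        s1 = 0.04 * (age - 46) + rng.standard_normal(n)
        a1 = 0.3 * s1 + rng.standard_normal(n)
        a2 = 0.5 * a1 + (0.4 * s1 if coupled else 0.0) + rng.standard_normal(n)
        s2 = 0.6 * s1 + rng.standard_normal(n)
        return pd.DataFrame(
            {"age_months": age, "battery_t1": s1, "battery_t2": s2,
             "accuracy_t1": a1, "accuracy_t2": a2}
        )

    def test_result_fields_and_df_bookkeeping(self, rng):
        df = self._frame(rng)
        res = crosslag_analysis(df, "battery", "accuracy")
        # age + autoregressor partialled: df = n - 3 - 2
        assert res.n == 60
        assert res.df == 60 - 3 - 2
        assert res.direction == int(np.sign(res.r_SA - res.r_AS))
        assert 0 < res.p_one_sided < 1

    def test_coupling_detected_direction(self, rng):
        df = self._frame(rng, n=400, coupled=True)
        res = crosslag_analysis(df, "battery", "accuracy")
        assert res.r_SA > res.r_AS
        assert res.p_one_sided < 0.05

    def test_weber_exclusion_bookkeeping(self, rng):
        df = self._frame(rng)
        df["w_hat_t1"] = -df["accuracy_t1"]
        df["w_hat_t2"] = -df["accuracy_t2"]
        df["w_excluded_t1"] = False
        df["w_excluded_t2"] = False
        df.loc[:4, "w_excluded_t1"] = True  # 5 children flagged
        res = crosslag_analysis(df, "battery", "w_hat")
        assert res.n == 55

    def test_below_chance_children_always_dropped(self, rng):
        df = self._frame(rng)
        df["below_chance_t1"] = False
        df.loc[:2, "below_chance_t1"] = True
        res = crosslag_analysis(df, "battery", "accuracy")
        assert res.n == 57

    def test_steiger_method_agrees_on_direction(self, rng):
        df = self._frame(rng, n=400, coupled=True)
        res_w = crosslag_analysis(df, "battery", "accuracy", method="williams")
        res_s = crosslag_analysis(df, "battery", "accuracy", method="steiger")
        assert np.sign(res_w.t) == np.sign(res_s.t)
        assert res_s.p_one_sided < 0.05

    def test_insufficient_sample_raises(self, rng):
        df = self._frame(rng, n=6)
        with pytest.raises(InsufficientDataError):
            crosslag_analysis(df, "battery", "accuracy")


class TestCorrelationTable:
    def test_dual_triangle_layout(self, rng):
        n = 50
        age = rng.uniform(36, 57, n)
        x = rng.standard_normal(n)
        df = pd.DataFrame(
            {"age_months": age, "a": x, "b": 2 * x, "c": rng.standard_normal(n)}
        )
        table = correlation_table(df, ["a", "b", "c"])
        assert np.isnan(table.loc["a", "a"])
        assert table.loc["b", "a"] == pytest.approx(1.0)  # simple r below diagonal
        assert abs(table.loc["a", "b"]) > 0.99  # partial r above diagonal

    def test_single_column(self, rng):
        df = pd.DataFrame(
            {"age_months": rng.uniform(36, 57, 20), "a": rng.standard_normal(20)}
        )
        table = correlation_table(df, ["a"])
        assert table.shape == (1, 1)
        assert np.isnan(table.loc["a", "a"])
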