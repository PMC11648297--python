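"""Feasibility filtering, per-characteristic tests, FWER, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nmatransit.dataset import TransitivityDataset
from nmatransit.gower import DissimilarityMatrix
from nmatransit.stattests import (
    CONCLUSIVE,
    CONSTANT_EVERYWHERE,
    CONSTANT_WITHIN,
    INCONCLUSIVE,
    INFEASIBLE,
    NOT_COMPARABLE,
    SINGLE_STUDY,
    UNDEFINED_P,
    compare_conclusions,
    familywise_error_rate,
    filter_testable_characteristics,
    run_test_suite,
)
from nmatransit.stattests import test_characteristic as run_characteristic_test
from nmatransit.thresholds import classify


def _dataset(comparisons, type_map=None, **chars):
    df = pd.DataFrame(
        {
            "study_id": [f"s{i}" for i in range(len(comparisons))],
            "comparison": comparisons,
            **chars,
        }
    )
    return TransitivityDataset.from_dataframe(df, type_map=type_map)


TWO_GROUPS = ["A vs B"] * 5 + ["A vs C"] * 5


class TestFiltering:
    def test_single_study_comparison_removes_all_numerics(self):
        ds = _dataset(
            ["A vs B"] * 3 + ["A vs C"],
            n1=[1.0, 2.0, 3.0, 4.0],
            n2=[5.0, 6.0, 7.0, 8.0],
            n3=[1.0, 3.0, 2.0, 4.0],
            c1=["u", "v", "u", "v"],
            c2=["x", "y", "x", "y"],
        )
        filtered, exclusions = filter_testable_characteristics(ds)
        assert {n for n, r in exclusions if r == SINGLE_STUDY} == {"n1", "n2", "n3"}
        assert filtered.characteristic_names == ["c1", "c2"]
        assert run_test_suite(ds).verdict == INFEASIBLE

    def test_constant_characteristic_removed_whatever_its_kind(self):
        ds = _dataset(
            TWO_GROUPS,
            flat=["same"] * 10,
            num=[1.0] * 10,
            ok=list(range(10)),
        )
        _, exclusions = filter_testable_characteristics(ds)
        reasons = dict(exclusions)
        assert reasons["flat"] == CONSTANT_EVERYWHERE
        assert reasons["num"] == CONSTANT_EVERYWHERE
        assert "ok" not in reasons

    def test_numeric_constant_within_one_multistudy_comparison_removed(self):
        ds = _dataset(
            TWO_GROUPS,
            bad=[7.0] * 5 + [1.0, 2.0, 3.0, 4.0, 5.0],
            good=list(range(10)),
        )
        _, exclusions = filter_testable_characteristics(ds)
        assert dict(exclusions)["bad"] == CONSTANT_WITHIN
        assert "good" not in dict(exclusions)

    def test_filtering_is_idempotent(self):
        ds = _dataset(
            TWO_GROUPS,
            bad=[7.0] * 5 + list(range(5)),
            flat=["a"] * 10,
            good=list(range(10)),
            cat=["u", "v"] * 5,
        )
        once, exclusions = filter_testable_characteristics(ds)
        twice, again = filter_testable_characteristics(once)
        assert again == []
        assert twice.characteristic_names == once.characteristic_names


class TestCharacteristicTests:
    def test_chi_squared_on_perfectly_separated_binary(self):
        # 2x2 table (5,0)/(0,5): chi2 = sum (O-E)^2/E = 10, df 1
        ds = _dataset(TWO_GROUPS, x=["yes"] * 5 + ["no"] * 5)
        r = run_characteristic_test(ds, "x")
        assert r.test_used == "chi_squared"
        assert r.statistic == pytest.approx(10.0)
        assert r.df == (1.0,)
        assert r.p_value == pytest.approx(0.001565, abs=1e-6)
        assert r.expected_counts_ok is False

    def test_chi_squared_matches_hand_coded_oracle(self, rng):
        for _ in range(20):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 4)))
            table = rng.integers(1, 30, size=shape).astype(float)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            oracle = ((table - expected) ** 2 / expected).sum()
            labels = []
            values = []
            for (i, j), n in np.ndenumerate(table):
                labels += [f"T{i} vs T{i + 1}"] * int(n)
                values += [f"v{j}"] * int(n)
            ds = _dataset(labels, x=values)
            r = run_characteristic_test(ds, "x")
            assert r.statistic == pytest.approx(oracle, abs=1e-10)

    def test_anova_detects_a_large_mean_shift(self, rng):
        ds = _dataset(
            TWO_GROUPS, x=list(rng.normal(0, 1, 5)) + list(rng.normal(8, 1, 5))
        )
        pooled = run_characteristic_test(ds, "x", equal_var=True)
        welch = run_characteristic_test(ds, "x", equal_var=False)
        assert pooled.test_used == "anova_f"
        assert pooled.p_value < 0.001
        assert welch.p_value < 0.001

    def test_welch_close_to_pooled_on_balanced_homoscedastic_data(self, rng):
        ds = _dataset(
            ["A vs B"] * 40 + ["A vs C"] * 40, x=list(rng.normal(0, 1, 80))
        )
        pooled = run_characteristic_test(ds, "x", equal_var=True)
        welch = run_characteristic_test(ds, "x", equal_var=False)
        assert welch.p_value == pytest.approx(pooled.p_value, abs=0.02)

    def test_zero_within_group_variance_gives_undefined_p(self):
        ds = _dataset(TWO_GROUPS, x=[1.0] * 5 + [2.0] * 5, type_map={"x": "numeric"})
        r = run_characteristic_test(ds, "x")
        assert r.exclusion_reason == UNDEFINED_P
        assert np.isnan(r.p_value)

    def test_single_level_after_missingness_gives_undefined_p(self):
        ds = _dataset(
            TWO_GROUPS,
            x=["u"] * 5 + [np.nan] * 4 + ["u"],
            type_map={"x": "categorical"},
        )
        r = run_characteristic_test(ds, "x")
        assert r.exclusion_reason == UNDEFINED_P


class TestSuiteAndFwer:
    @pytest.mark.parametrize(
        "m,expected", [(1, 0.05), (14, 1 - 0.95**14), (0, 0.0)]
    )
    def test_fwer_values(self, m, expected):
        assert familywise_error_rate(m) == pytest.approx(expected)

    @given(st.integers(1, 60))
    def test_fwer_strictly_increasing_in_m(self, m):
        assert familywise_error_rate(m + 1) > familywise_error_rate(m)
        assert familywise_error_rate(1, 0.05) == pytest.approx(0.05)

    def test_all_null_p_values_give_inconclusive(self, rng):
        chars = {f"x{j}": list(rng.normal(size=10)) for j in range(4)}
        ds = _dataset(TWO_GROUPS, **chars)
        suite = run_test_suite(ds)
        assert suite.m_tests == 4
        if all(r.p_value >= 0.05 for r in suite.results):
            assert suite.verdict == INCONCLUSIVE

    def test_one_small_p_value_is_conclusive(self, rng):
        chars = {f"x{j}": list(rng.normal(size=10)) for j in range(3)}
        chars["shift"] = list(rng.normal(0, 0.1, 5)) + list(rng.normal(9, 0.1, 5))
        suite = run_test_suite(_dataset(TWO_GROUPS, **chars))
        assert suite.verdict == CONCLUSIVE
        assert suite.fwer == pytest.approx(1 - 0.95**4)

    def test_fewer_than_four_survivors_is_infeasible(self, rng):
        ds = _dataset(
            TWO_GROUPS,
            a=list(rng.normal(size=10)),
            b=list(rng.normal(size=10)),
            c=list(rng.normal(size=10)),
        )
        assert run_test_suite(ds).verdict == INFEASIBLE


class TestConcordance:
    def _verdict(self, db):
        dm = DissimilarityMatrix(
            ["A vs B", "A vs C"], np.array([[0.0, db], [db, 0.0]])
        )
        return classify(dm, 0.13)

    def test_cross_classification_cells(self, rng):
        chars = {f"x{j}": list(rng.normal(size=10)) for j in range(3)}
        chars["shift"] = list(rng.normal(0, 0.1, 5)) + list(rng.normal(9, 0.1, 5))
        conclusive = run_test_suite(_dataset(TWO_GROUPS, **chars))
        assert (
            compare_conclusions(self._verdict(0.9), conclusive)
            == "intransitive_conclusive"
        )
        assert (
            compare_conclusions(self._verdict(0.01), conclusive)
            == "transitive_conclusive"
        )

    def test_infeasible_tests_are_not_comparable(self, rng):
        ds = _dataset(TWO_GROUPS, a=list(rng.normal(size=10)))
        infeasible = run_test_suite(ds)
        assert infeasible.verdict == INFEASIBLE
        assert compare_conclusions(self._verdict(0.9), infeasible) == NOT_COMPARABLE

    def test_undetermined_dissimilarity_is_not_comparable(self, rng):
        chars = {f"x{j}": list(rng.normal(size=10)) for j in range(4)}
        suite = run_test_suite(_dataset(TWO_GROUPS, **chars))
        dm = DissimilarityMatrix(
            ["A vs B", "A vs C"], np.array([[0.1, np.nan], [np.nan, 0.1]])
        )
        assert compare_conclusions(classify(dm, 0.13), suite) == NOT_COMPARABLE
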