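import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import brute_force_bh, enumerate_wilcoxon_p, welch_t
from vaxsig.datatypes import ExpressionMatrix, SampleTable, ValidationError
from vaxsig.diffstats import (
    Contrast,
    bh_adjust,
    feature_stats,
    filter_low_expression,
    impute_below_detection,
    log2_ratio,
    wilcoxon_signed_rank,
)
from vaxsig.simulate import null_design, simulate_counts


def _two_group_setup(values_a, values_b):
    """RFU matrix with one feature and two groups at D1/D2."""
    na, nb = len(values_a), len(values_b)
    ids = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    m = ExpressionMatrix(
        feature_ids=["f1"],
        sample_ids=ids,
        values=np.array([list(values_a) + list(values_b)], dtype=float),
        assay_kind="soma_rfu",
    )
    table = SampleTable(
        frame=pd.DataFrame(
            {
                "sample_id": ids,
                "subject_id": ids,
                "timepoint": ["D2"] * na + ["D1"] * nb,
                "group": ["ad26_1e11"] * (na + nb),
                "pair_key": [None] * (na + nb),
            }
        )
    )
    return m, table


class TestFeatureStats:
    def test_identical_groups_give_null_statistic(self):
        m, t = _two_group_setup([2, 4, 8], [2, 4, 8])
        res = feature_stats(m, t, Contrast("ad26_1e11", "D2", "ad26_1e11", "D1"))
        row = res.iloc[0]
        assert row.statistic == 0.0
        assert row.p_value == 1.0
        assert row.log2_fold_change == 0.0

    def test_welch_t_matches_direct_formula(self):
        a = [3.1, 7.4, 5.9, 12.0]
        b = [2.2, 2.9, 4.4, 3.3]
        m, t = _two_group_setup(a, b)
        res = feature_stats(m, t, Contrast("ad26_1e11", "D2", "ad26_1e11", "D1"))
        expected = welch_t(np.log2(np.array(a)), np.log2(np.array(b)))
        assert res.iloc[0].statistic == pytest.approx(expected, abs=1e-10)

    def test_small_group_rejected(self):
        m, t = _two_group_setup([1.0], [2.0, 3.0])
        with pytest.raises(ValidationError, match=">=2 samples"):
            feature_stats(m, t, Contrast("ad26_1e11", "D2", "ad26_1e11", "D1"))

    def test_type_i_error_near_nominal_on_null_design(self):
        """On a no-effect design the Wald-style t test should reject ~5%
        of truly null features at alpha 0.05."""
        sim = simulate_counts(null_design(seed=7, n_features=3000))
        res = feature_stats(
            sim.matrix, sim.samples,
            Contrast("ad26_1e11", "D2", "ad26_1e11", "D1"), paired=True,
        )
        rate = (res["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestFilterLowExpression:
    def test_strict_less_than_removal(self):
        t = pd.DataFrame({"feature_id": ["a", "b", "c"], "base_mean": [5.0, 10.0, 15.0]})
        kept = filter_low_expression(t, 10)
        assert kept["feature_id"].tolist() == ["b", "c"]

    def test_all_below_gives_empty(self):
        t = pd.DataFrame({"feature_id": ["a"], "base_mean": [1.0]})
        assert filter_low_expression(t, 10).empty

    def test_threshold_zero_is_identity(self):
        t = pd.DataFrame({"feature_id": ["a", "b"], "base_mean": [0.0, 5.0]})
        assert len(filter_low_expression(t, 0)) == 2


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 51))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_maximal_shift_n6(self):
        x = np.arange(6, dtype=float)
        w, p = wilcoxon_signed_rank(x + 5.0, x)
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_antisymmetric_pair(self):
        _, p = wilcoxon_signed_rank(np.array([-1.0, 1.0]))
        assert p == 1.0

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.zeros(4))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        # half-integer magnitudes force ties regularly
        d = rng.choice([-3, -2, -1.5, -1, 1, 1.5, 2, 3], size=n)
        w, p = wilcoxon_signed_rank(d)
        w_ref, p_ref = enumerate_wilcoxon_p(d)
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_agrees_with_scipy_on_untied_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.normal(size=12)
            _, p = wilcoxon_signed_rank(d)
            p_ref = sps.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)


class TestLog2Ratio:
    def test_examples(self):
        a = pd.Series({"f1": 4.0, "f2": 3.0, "f3": 5.0})
        b = pd.Series({"f1": 1.0, "f2": 3.0, "f3": 0.0})
        out = log2_ratio(a, b)
        assert out.loc["f1", "log2_ratio"] == pytest.approx(2.0)
        assert out.loc["f2", "log2_ratio"] == pytest.approx(0.0)
        assert bool(out.loc["f3", "flagged"]) and np.isnan(out.loc["f3", "log2_ratio"])

    def test_disjoint_features_rejected(self):
        with pytest.raises(ValidationError):
            log2_ratio(pd.Series({"x": 1.0}), pd.Series({"y": 1.0}))


class TestImputeBelowDetection:
    def _masked(self, col, mask):
        return ExpressionMatrix(
            feature_ids=["f1"], sample_ids=[f"s{i}" for i in range(len(col))],
            values=np.array([col], dtype=float),
            assay_kind="mesoscale_pg_ml",
            below_detection=np.array([mask]),
        )

    def test_masked_cell_takes_column_minimum(self):
        m = self._masked([np.nan, 5.0, 7.0], [True, False, False])
        out = impute_below_detection(m)
        np.testing.assert_array_equal(out.values, [[5.0, 5.0, 7.0]])

    def test_two_masked_cells(self):
        m = self._masked([np.nan, np.nan, 3.0], [True, True, False])
        out = impute_below_detection(m)
        np.testing.assert_array_equal(out.values, [[3.0, 3.0, 3.0]])

    def test_no_mask_is_identity(self):
        m = ExpressionMatrix(["f1"], ["s1"], np.array([[2.0]]), "mesoscale_pg_ml")
        out = impute_below_detection(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_fully_masked_analyte_rejected(self):
        m = self._masked([np.nan, np.nan], [True, True])
        with pytest.raises(ValidationError, match="below detection"):
            impute_below_detection(m)
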