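import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_hypergeom_p
from vaxsig.datatypes import ExpressionMatrix, GeneSetCollection, ValidationError
from vaxsig.simulate import SimulationDesign, simulate_rfu
from vaxsig.tts import (
    baseline_ratio,
    overlap_enrichment,
    sample_zscore,
    select_outliers,
    select_top_percentile,
    union_selection,
)


class TestSampleZscore:
    def test_median_analyte_scores_zero(self):
        z = sample_zscore(np.array([1.0, 2.0, 4.0]))
        assert z[1] == 0.0

    def test_sign_pattern_around_median(self):
        z = sample_zscore(np.array([1.0, 2.0, 4.0]))
        assert z[0] < 0 < z[2]

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        rfu = rng.lognormal(5, 1, size=50)
        np.testing.assert_allclose(
            sample_zscore(rfu), sample_zscore(2.0 * rfu), atol=1e-12
        )

    def test_mad_scale_option(self):
        rng = np.random.default_rng(1)
        rfu = rng.lognormal(5, 1, size=50)
        z_sd = sample_zscore(rfu, scale="sd")
        z_mad = sample_zscore(rfu, scale="mad")
        # same centring, different dispersion estimate
        assert np.argmax(z_sd) == np.argmax(z_mad)
        assert not np.allclose(z_sd, z_mad)

    def test_constant_panel_rejected(self):
        with pytest.raises(ValidationError, match="dispersion"):
            sample_zscore(np.full(10, 3.0))


class TestTopPercentile:
    def test_ten_distinct_values_select_one(self):
        z = np.arange(10, dtype=float)
        mask = select_top_percentile(z, q=0.90)
        assert mask.sum() == 1 and mask[-1]

    def test_hundred_distinct_values_select_ten(self):
        z = np.random.default_rng(2).permutation(100).astype(float)
        mask = select_top_percentile(z, q=0.90)
        assert mask.sum() == 10
        assert set(z[mask]) == set(range(90, 100))

    def test_all_equal_selects_nothing(self):
        assert select_top_percentile(np.zeros(20), q=0.90).sum() == 0

    def test_boundary_ties_all_included(self):
        z = np.array([0.0] * 9 + [5.0, 5.0])
        mask = select_top_percentile(z, q=0.80)
        assert mask.sum() == 2


class TestBaselineRatio:
    def _ref(self, cols):
        arr = np.array(cols, dtype=float).T
        return ExpressionMatrix(
            feature_ids=[f"p{i}" for i in range(arr.shape[0])],
            sample_ids=[f"r{j}" for j in range(arr.shape[1])],
            values=arr,
            assay_kind="soma_rfu",
        )

    def test_boundary_ratio_exactly_two_fails_strict_filter(self):
        ref = self._ref([[4.0], [6.0]])  # one feature, baseline mean 5
        ratio, valid = baseline_ratio(np.array([10.0]), ref)
        assert ratio[0] == pytest.approx(2.0)
        assert not (ratio[0] > 2.0)

    def test_just_above_boundary_passes(self):
        ref = self._ref([[4.0], [6.0]])
        ratio, _ = baseline_ratio(np.array([10.1]), ref)
        assert ratio[0] > 2.0

    def test_identity_ratio(self):
        ref = self._ref([[5.0], [5.0]])
        ratio, _ = baseline_ratio(np.array([5.0]), ref)
        assert ratio[0] == pytest.approx(1.0)

    def test_zero_baseline_flagged(self):
        ref = ExpressionMatrix(
            ["p0"], ["r0"], np.array([[0.0]]), "mesoscale_pg_ml"
        )
        ratio, valid = baseline_ratio(np.array([3.0]), ref)
        assert not valid[0] and np.isnan(ratio[0])


@pytest.fixture(scope="module")
def rfu_study():
    rfu = simulate_rfu(SimulationDesign(seed=19))
    tts = rfu.matrix.subset_samples(rfu.samples.select(group="tts_patient"))
    ref = rfu.matrix.subset_samples(rfu.samples.select(group="healthy_reference"))
    return rfu, tts, ref


class TestSelectOutliers:
    def test_recovers_injected_coagulation_proteins(self, rfu_study):
        rfu, tts, ref = rfu_study
        truth = rfu.activated["COAGULATION_PLATELET"]
        for sel in select_outliers(tts, ref):
            recall = len(set(sel.selected) & truth) / len(truth)
            assert recall >= 0.8
            assert (sel.table["percentile_rank"] >= 0.90).all()
            assert (sel.table["ratio_to_baseline"] > 2.0).all()

    def test_sample_equal_to_reference_mean_selects_nothing(self):
        rng = np.random.default_rng(7)
        base = rng.lognormal(8, 0.5, size=200)
        ref = ExpressionMatrix(
            feature_ids=[f"p{i}" for i in range(200)],
            sample_ids=["r0", "r1"],
            values=np.column_stack([base, base]),
            assay_kind="soma_rfu",
        )
        tts = ExpressionMatrix(
            feature_ids=ref.feature_ids, sample_ids=["t0"],
            values=base[:, None], assay_kind="soma_rfu",
        )
        sels = select_outliers(tts, ref)
        assert sels[0].selected == []

    def test_thresholds_off_select_everything(self, rfu_study):
        _, tts, ref = rfu_study
        sels = select_outliers(tts, ref, q=0.0, ratio_min=0.0)
        assert len(sels[0].selected) == tts.n_features

    def test_selection_monotone_in_thresholds(self, rfu_study):
        _, tts, ref = rfu_study
        sizes = []
        for q, rmin in [(0.5, 1.0), (0.9, 1.0), (0.9, 2.0), (0.95, 3.0)]:
            sels = select_outliers(tts, ref, q=q, ratio_min=rmin)
            sizes.append(len(sels[0].selected))
        assert sizes == sorted(sizes, reverse=True)

    def test_union_orders_by_best_z(self, rfu_study):
        _, tts, ref = rfu_study
        sels = select_outliers(tts, ref)
        union = union_selection(sels)
        assert set(union) == set().union(*(s.selected for s in sels))


class TestOverlapEnrichment:
    def test_perfect_overlap_closed_form(self):
        universe = {f"u{i}" for i in range(10)}
        members = {f"u{i}" for i in range(5)}
        coll = GeneSetCollection(sets={"S": frozenset(members)})
        res = overlap_enrichment(sorted(members), coll, universe)
        assert res.iloc[0].p_value == pytest.approx(1 / 252, rel=1e-12)

    def test_set_equal_to_universe_gives_p_one(self):
        universe = {f"u{i}" for i in range(8)}
        coll = GeneSetCollection(sets={"ALL": frozenset(universe)})
        res = overlap_enrichment(["u0", "u1"], coll, universe)
        assert res.iloc[0].overlap == 2
        assert res.iloc[0].p_value == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection(sets={"S": frozenset({"x"})})
        with pytest.raises(ValidationError):
            overlap_enrichment([], coll, set())

    def test_selection_outside_universe_rejected(self):
        coll = GeneSetCollection(sets={"S": frozenset({"u0"})})
        with pytest.raises(ValidationError, match="outside"):
            overlap_enrichment(["zz"], coll, {"u0", "u1"})

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        universe = {f"u{i}" for i in range(n)}
        sel = set(rng.choice(sorted(universe), size=int(rng.integers(1, n)), replace=False))
        members = set(rng.choice(sorted(universe), size=int(rng.integers(1, n)), replace=False))
        coll = GeneSetCollection(sets={"S": frozenset(members)})
        res = overlap_enrichment(sorted(sel), coll, universe)
        expected = enumerate_hypergeom_p(universe, sel, members)
        assert res.iloc[0].p_value == pytest.approx(expected, rel=1e-9)
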