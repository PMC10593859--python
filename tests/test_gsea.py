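import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_es
from vaxsig.datatypes import GeneSetCollection, ProbeMap, ValidationError
from vaxsig.diffstats import Contrast, feature_stats
from vaxsig.gsea import (
    RankedList,
    collapse_probes,
    enrichment_score,
    nes_ratio,
    preranked_gsea,
)
from vaxsig.simulate import simulate_counts, study_design


def _ranked(stats_by_id: dict[str, float]) -> RankedList:
    return RankedList(list(stats_by_id), np.array(list(stats_by_id.values())))


class TestCollapseProbes:
    def test_abs_max_keeps_extreme_probe(self):
        ranked = _ranked({"A1": 3.0, "A2": -5.0})
        pm = ProbeMap({"A1": "A", "A2": "A"})
        out = collapse_probes(ranked, pm)
        assert out.feature_ids == ["A"]
        assert out.statistics[0] == -5.0

    def test_single_probe_identity(self):
        ranked = _ranked({"B1": 2.0, "C1": -1.0})
        out = collapse_probes(ranked, ProbeMap({"B1": "B", "C1": "C"}))
        assert set(out.feature_ids) == {"B", "C"}

    def test_tie_keeps_lexicographically_smaller_probe(self):
        ranked = _ranked({"A2": -2.0, "A1": 2.0})
        out = collapse_probes(ranked, ProbeMap({"A1": "A", "A2": "A"}))
        assert out.statistics[0] == 2.0  # A1's value

    def test_unmapped_probe_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            collapse_probes(_ranked({"X1": 1.0}), ProbeMap({}))


class TestEnrichmentScore:
    def test_top_two_features_reach_unity(self):
        ranked = _ranked({"a": 3.0, "b": 2.0, "c": 1.0, "d": -1.0, "e": -2.0})
        es, running, le = enrichment_score(ranked, {"a", "b"})
        assert es == pytest.approx(1.0)
        assert le == frozenset({"a", "b"})

    def test_set_covering_everything_rejected(self):
        ranked = _ranked({"a": 1.0, "b": -1.0})
        with pytest.raises(ValidationError, match="whole ranked list"):
            enrichment_score(ranked, {"a", "b"})

    def test_empty_intersection_rejected(self):
        ranked = _ranked({"a": 1.0, "b": -1.0})
        with pytest.raises(ValidationError, match="no member"):
            enrichment_score(ranked, {"zzz"})

    def test_sign_flip_negates_score(self):
        stats_ = {"a": 3.0, "b": 2.0, "c": 0.5, "d": -1.0, "e": -2.5}
        ranked = _ranked(stats_)
        flipped = _ranked({k: -v for k, v in stats_.items()})
        es, _, _ = enrichment_score(ranked, {"a", "b"})
        es_f, _, _ = enrichment_score(flipped, {"a", "b"})
        assert es_f == pytest.approx(-es)

    def test_weight_zero_is_unweighted_ks(self):
        ranked = _ranked({"a": 5.0, "b": 1.0, "c": 0.5, "d": -2.0})
        es, _, _ = enrichment_score(ranked, {"a", "c"}, weight=0.0)
        # unweighted: hits step 1/2, misses step 1/2; running 0.5, 0, 0.5, 0
        assert es == pytest.approx(0.5)

    def test_permuting_non_members_leaves_es_unchanged(self):
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(30)]
        stats_ = dict(zip(ids, rng.normal(size=30)))
        members = {"g3", "g7", "g11", "g20"}
        es, _, _ = enrichment_score(_ranked(stats_), members)
        # swap statistics between two non-members with equal rank effect:
        # relabel non-member ids (stats stay attached to positions)
        non = [g for g in ids if g not in members]
        relabel = dict(zip(non, non[::-1]))
        stats_2 = {relabel.get(g, g): v for g, v in stats_.items()}
        es2, _, _ = enrichment_score(_ranked(stats_2), members)
        assert es2 == pytest.approx(es)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        k = int(rng.integers(1, n))
        ids = [f"g{i:03d}" for i in range(n)]
        stats_ = rng.normal(size=n)
        members = set(rng.choice(ids, size=k, replace=False))
        weight = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
        ranked = RankedList(ids, stats_)
        es, _, _ = enrichment_score(ranked, members, weight=weight)
        hit_mask = np.array([f in members for f in ranked.feature_ids])
        ref = brute_force_es(ranked.statistics, hit_mask, weight)
        assert abs(es) <= 1.0 + 1e-12
        assert es == pytest.approx(ref, abs=1e-12)


@pytest.fixture(scope="module")
def study():
    sim = simulate_counts(study_design(seed=31))
    table = feature_stats(
        sim.matrix, sim.samples,
        Contrast("ad26_1e11", "D2", "ad26_1e11", "D1"), paired=True,
    )
    ranked = RankedList.from_table(table)
    res = preranked_gsea(ranked, sim.collection, n_perm=500, seed=13)
    return sim, ranked, res


class TestPrerankedGsea:
    def test_injected_sets_pass_fdr_threshold(self, study):
        sim, _, res = study
        hits = res.set_index("set_name").loc[list(sim.activated)]
        assert (hits["fdr_q"] < 0.10).all()

    def test_nes_sign_follows_es(self, study):
        _, _, res = study
        ok = res["nes"].notna() & (res["es"] != 0)
        assert (np.sign(res.loc[ok, "nes"]) == np.sign(res.loc[ok, "es"])).all()

    def test_fdr_monotone_in_abs_nes_within_sign(self, study):
        _, _, res = study
        for sign in (1, -1):
            sub = res[np.sign(res["nes"]) == sign].sort_values(
                "nes", key=np.abs, ascending=False
            )
            q = sub["fdr_q"].to_numpy()
            assert (np.diff(q) >= -1e-12).all()

    def test_deterministic_for_fixed_seed(self, study):
        sim, ranked, res = study
        res2 = preranked_gsea(ranked, sim.collection, n_perm=500, seed=13)
        assert res.equals(res2)

    def test_leading_edge_members_come_from_the_set(self, study):
        sim, ranked, res = study
        universe = set(ranked.feature_ids)
        for row in res.itertuples():
            le = set(row.leading_edge.split(",")) if row.leading_edge else set()
            assert le <= (set(sim.collection[row.set_name]) & universe)

    def test_size_filter_excludes_out_of_range_sets(self):
        ranked = _ranked({f"g{i}": float(10 - i) for i in range(10)})
        coll = GeneSetCollection(
            sets={"small": frozenset({"g0", "g1"}),
                  "ok": frozenset({f"g{i}" for i in range(5)})}
        )
        res = preranked_gsea(ranked, coll, n_perm=50, min_size=3, max_size=8, seed=1)
        assert res["set_name"].tolist() == ["ok"]


class TestNesRatio:
    def _frame(self, mapping):
        import pandas as pd

        return pd.DataFrame(
            [{"set_name": k, "nes": v} for k, v in mapping.items()]
        )

    def test_simple_ratio_and_identity(self):
        out = nes_ratio(self._frame({"P": 2.0, "Q": 1.5}), self._frame({"P": 1.0, "Q": 1.5}))
        out = out.set_index("set_name")
        assert out.loc["P", "ratio"] == pytest.approx(2.0)
        assert out.loc["Q", "ratio"] == pytest.approx(1.0)

    def test_opposite_signs_flagged_not_ratioed(self):
        out = nes_ratio(self._frame({"P": 2.0}), self._frame({"P": -1.0}))
        assert out.iloc[0].flag == "opposite_sign"
        assert np.isnan(out.iloc[0].ratio)

    def test_near_zero_denominator_flagged(self):
        out = nes_ratio(self._frame({"P": 2.0}), self._frame({"P": 1e-12}))
        assert out.iloc[0].flag == "denominator_zero"

    def test_no_shared_sets_rejected(self):
        with pytest.raises(ValidationError):
            nes_ratio(self._frame({"P": 1.0}), self._frame({"Q": 1.0}))
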