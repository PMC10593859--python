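"""Preranked pathway enrichment on a simulated vaccine study.

Simulates a two-dose-arm longitudinal study in which three pathways gain
one log2 unit of expression one day post-vaccination (D2), ranks features
by a paired t statistic for D2 vs baseline, and runs weighted-KS
preranked enrichment with a 1000-draw permutation null.
"""

from vaxsig import Contrast, RankedList, feature_stats, preranked_gsea
from vaxsig.simulate import simulate_counts, study_design

sim = simulate_counts(study_design(seed=7))
print(f"simulated {sim.matrix.n_features} features x {sim.matrix.n_samples} samples;"
      f" injected sets: {sorted(sim.activated)}")

table = feature_stats(
    sim.matrix, sim.samples,
    Contrast("ad26_1e11", "D2", "ad26_1e11", "D1"), paired=True,
)
results = preranked_gsea(RankedList.from_table(table), sim.collection,
                         n_perm=1000, seed=1)
top = results.nsmallest(5, "fdr_q")[["set_name", "nes", "p_nominal", "fdr_q"]]
print(top.to_string(index=False))
print(
    "\nNES is the enrichment score over the mean same-sign permutation"
    "\nscore; the injected pathways should lead the table at FDR q < 0.10"
    "\nwhile the null sets stay non-significant."
)
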