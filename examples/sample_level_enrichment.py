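"""Per-sample pathway z-scores (SLEA) tracking activation kinetics.

For each pathway and sample, the mean log expression of the pathway's
members is z-scored against 1000 random same-size feature sets. Median
z per timepoint shows the transient activation: up at D2, back to
baseline by D8, weaker in the lower-dose arm.
"""

import pandas as pd

from vaxsig import median_slea, slea_matrix
from vaxsig.simulate import simulate_counts, study_design

sim = simulate_counts(study_design(seed=3))
rows = []
for arm in ("ad26_5e10", "ad26_1e11"):
    ids = [s for tp in ("D1", "D2", "D8") for s in sim.samples.select(group=arm, timepoint=tp)]
    sm = slea_matrix(sim.matrix.subset_samples(ids), sim.collection,
                     n_random=1000, seed=11)
    for tp in ("D1", "D2", "D8"):
        med = median_slea(sm, sim.samples.select(group=arm, timepoint=tp))
        for name in sim.activated:
            rows.append({"set": name, "arm": arm, "timepoint": tp,
                         "median_z": round(float(med[name]), 2)})

wide = pd.DataFrame(rows).pivot(index=["set", "arm"], columns="timepoint",
                                values="median_z")
print(wide.to_string())
print(
    "\nEach cell is the median per-sample pathway z over one arm and day:"
    "\nactivation peaks at D2, resolves by D8, and the 1e11 arm exceeds"
    "\nthe 5e10 arm."
)
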