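# Methods

`vaxsig` implements the bespoke statistics of a vaccine
systems-serology/transcriptomics workflow: exact adverse-event rate
estimation, preranked gene-set enrichment with a permutation FDR,
per-sample pathway z-scores, an outlier-protein selection scheme for
very small patient groups, SomaScan-style plate QC, and the paired
nonparametric comparisons that tie them together. This note records the
models, the defaults and why, and the design choices that were genuinely
open.

## Adverse-event rates (`vaxsig.rates`)

Events `k` over exposure `D` doses are modelled as Poisson. The rate is
`1e6·k/D` per million doses; the two-sided exact (Garwood) CI uses the
chi-square representation of the Poisson tail:

    lower = ½·χ²(α/2, 2k)        (0 when k = 0)
    upper = ½·χ²(1−α/2, 2k+2)

scaled by `1e6/D`. The exact interval guarantees coverage ≥ 1−α at any
true rate — the relevant regime for events observed a handful of times
over millions of doses, where normal approximations under-cover. Mid-p
and Bayesian variants were considered and excluded: the exact interval
is the convention in vaccine surveillance tables, and the zero-event
upper bound `−ln(α/2)` is well defined. Rounding (2 dp) happens only in
the reporting layer (`rate_table`); internal values keep full precision.

## Per-feature ranking statistics (`vaxsig.diffstats`)

The pipeline deliberately does **not** re-implement negative-binomial
Wald tests or moderated-t models. Downstream enrichment is rank-based,
so the ranking metric only needs a reasonable signed ordering: a Welch
(unpaired) or paired t statistic on log2 expression. Counts are
library-size normalised to counts-per-million and transformed as
`log2(cpm+1)` — a rank-preserving stand-in for median-of-ratios
normalisation at the scales this package targets; intensities (RFU,
pg/mL) are `log2(x)`. Consequences: individual p-values are not
comparable to shrinkage-based tools on real low-replicate data, and the
package makes no claim that they are. `base_mean` (mean normalised value
over all samples) feeds the low-expression filter, which removes
features with `base_mean < 10` — strictly below, so a feature exactly at
the threshold survives.

Ties in the ranking statistic are broken lexicographically by feature ID
so the ordering is total and identical across runs.

The Wilcoxon signed-rank test drops zero differences before ranking
(the classical treatment; n is reported after dropping). For n ≤ 25 the
two-sided p is exact: the null distribution of the positive-rank sum is
built by dynamic programming over doubled midranks, which keeps the p
exact even with tied magnitudes — full 2ⁿ sign enumeration, used as the
independent oracle in the tests, becomes infeasible well before n = 25.
Above n = 25 a normal approximation with continuity and tie corrections
takes over. The two-sided p is twice the smaller tail, capped at 1.

Below-detection cytokine values (cells read as the `#` marker) are
replaced by the minimum *observed* value of the same analyte across
samples; an analyte with no observed value at all is an error rather
than a guess.

## Preranked enrichment (`vaxsig.gsea`)

The enrichment score of a set is the signed extremum of the weighted
Kolmogorov–Smirnov running sum: hits advance by `|s|^w / Σ_hits |s|^w`,
misses retreat by `1/(N−N_hits)`; weight defaults to 1. When the two
extrema tie exactly in magnitude the positive one is reported. Probe
collapsing keeps, per gene, the probe with maximal absolute statistic;
a tie keeps the lexicographically smaller probe (logged).

Because the input is a preranked list, phenotype permutation is
unavailable; the null is `n_perm` random same-size draws from the ranked
universe (the canonical preranked null). Defaults mirror standard
desktop practice: 1000 permutations, sets intersected with the universe
*before* the size filter `[10, 5000]`, so the filter applies to usable
members. Normalisation is meandiv: NES = ES / mean |same-sign null ES|;
a set with no same-sign null draws has undefined NES and is flagged
rather than silently dropped. The nominal p uses the `(r+1)/(n+1)`
estimator so no p is ever exactly zero. The FDR q pools the normalised
null scores across sets within each sign class and compares tail
fractions of null versus observed NES, then enforces monotonicity in
|NES| (step-up: each set takes the smallest raw ratio among sets no more
extreme), clipped to [0, 1]. Significance threshold throughout the
composed analyses: q < 0.10.

NES ratios between two conditions are computed only for sets whose NES
signs agree and whose denominator is non-negligible (|NES| ≥ 1e−9);
everything else is flagged and excluded rather than ratioed.

## Per-sample pathway z-scores (`vaxsig.slea`)

For one pathway with k usable members, the observed score of a sample is
the mean log expression of those members; the null is the mean of
`n_random` (default 1000) random k-subsets of all matrix features, and

    z = (observed − mean(null)) / sd(null).

Choices that were genuinely open:

* **Scale.** Log2 (normalised counts or intensities), so the mean is not
  dominated by a few high-abundance features.
* **Null sharing.** The random subsets are drawn once per pathway and
  reused for every sample of the call; within-row contrasts between
  samples therefore reflect the data, not null-sampling noise.
* **Universe.** All features present in the (filtered) matrix, not the
  union of pathway members.
* **Degenerate nulls** (e.g. a constant matrix) give z = 0 with a flag,
  never NaN, so exported grids are total.
* The alternative reading — z-scoring pathway means across samples after
  null-centering — is noted but not implemented; the per-sample null
  z is the literal procedure described.

Calibration: on an all-null design the pooled z over pathways × samples
is centred with roughly unit spread. The pooled moments carry
set-composition sampling noise of order `1/√n_sets` (each pathway's
membership offsets its whole row), so calibration checks pool over
enough sets (hundreds) to make the estimate sharp.

## Patient outlier proteins (`vaxsig.tts`)

For a patient group too small to test (here, two), selection works
within each sample:

1. `z_i = (log2 x_i − median(log2 x)) / s` across the whole panel, where
   `s` is the standard deviation about the median. The centre is the
   panel median by construction; the scale estimator was unspecified in
   principle, so the normal-consistent MAD is available behind the
   `scale="mad"` flag, with SD-about-the-median as the documented
   default. Using log2 makes the z invariant to a global rescaling of
   the sample.
2. Keep analytes whose percentile rank (fraction of analytes strictly
   below) is ≥ 0.90 — the top decile on all-distinct data, with boundary
   ties included.
3. Keep, of those, analytes whose linear-scale value exceeds twice the
   arithmetic mean of the healthy reference panel (strict > 2; a ratio
   of exactly 2 fails). The percentile cut is applied before the ratio
   filter, following the order in which the procedure is described.

Note the asymmetry: the z stage is invariant to global rescaling of the
patient sample, the ratio stage is not — a deliberate property of the
procedure, documented rather than patched. Per-timepoint selections are
reported separately and as a union (ordered by best z). Overlap of the
selection with annotated pathway sets uses the upper-tail hypergeometric
test against the full panel as universe, BH-adjusted across sets.

## Plate QC (`vaxsig.soma_qc`)

Per SOMAmer, the Calibration Scale Factor is `reference RFU / plate
calibrator-median RFU`; the Plate Scale Factor is the median of that
distribution. Applying the per-feature factors makes plate calibrator
medians equal the reference exactly, and recalibration is idempotent.
QC accuracy ratios are computed post-calibration (QC medians are scaled
before ratioing against the QC reference). The acceptance gate requires
the plate scale factor within the closed interval [0.4, 2.5] **and** at
least 85% of QC ratios within the closed interval [0.8, 1.2];
diagnostics name each failing criterion. Full adaptive
maximum-likelihood normalisation against a population reference is out
of scope; only plate calibration and the acceptance gates are modelled.

## Synthetic data (`vaxsig.simulate`)

The generator emulates the structure the analyses assume, not any real
dataset:

* **Counts**: negative binomial with shared dispersion (size 10;
  variance `μ + μ²/10`), log2-mean = per-feature baseline
  (N(6, 1) log2 units) + subject offset (N(0, 0.2)) + arm×timepoint
  effect for members of activated sets. Subject offsets make paired
  designs meaningful; they cancel in within-subject contrasts.
* **Design constraints**, enforced at construction because they are the
  kinetics the pipeline must detect: all D8 effects are zero (resolution
  one week post-dose) and the lower-dose arm's effect never exceeds the
  higher-dose arm's. The default study: 2 arms × 10 subjects × (D1, D2,
  D8, optionally D58), 2000 features, 50 disjoint 20-feature sets of
  which 3 are activated at +1 log2 (high dose; half in the low-dose arm;
  `boost_fraction` scales the D58 effect).
* **Serum panel**: log-normal intensities, 1000 proteins with per-feature
  baselines of SD 0.5 log2 units and replicate noise of SD 0.5; 20
  disjoint 50-protein sets; two patient samples at day-15/16/19 labels
  carry +2 log2 on the coagulation/platelet set; 10 healthy reference
  samples. Effect sizes have no published estimates, so defaults are
  chosen for test power: the +2 log2 patient effect against the 0.5
  log2 panel spread is the operating point at which the within-sample
  z → top-decile → ratio chain recovers ≥ 80% of injected proteins. A
  raw aptamer panel spans orders of magnitude; the generator emulates a
  normalised panel, and the within-sample z stage would need a wider
  selection window on raw-scale data.
* **Plates**: replicate noise is renormalised to per-feature median one,
  so a simulated global shift `s` yields a plate scale factor of exactly
  `1/s` — the QC gates can be tested at their boundaries.
* All draws come from a seeded numpy `default_rng` (PCG64); a fixed seed
  reproduces matrices bit for bit.

What the generator does **not** emulate — sequencing-depth artifacts,
batch effects, gene–gene correlation beyond set structure, hybridisation
chemistry, heavy-tailed abundance distributions — bounds what passing
tests show: the pipeline recovers the signals it is designed for under
its own model assumptions; performance on real data depends on upstream
normalisation doing its job.

## Problem sizes and numerical choices

The test-suite and reproduction-script simulations use the default study
sizes above (2000 features, 10 subjects/arm, 50 sets, 1000 permutations,
1000 random sets; 20 replicate studies for power estimates) — large
enough that recovery and calibration are stable, small enough to run on
a laptop in minutes. Degenerate cases are errors, not silent defaults:
empty set∩universe intersections, sets covering the whole universe,
all-zero Wilcoxon differences, zero calibrator medians, analytes with no
observed value. Null SD guards use 1e−12; NES denominators 1e−9.

## Known limitations

* The ranking statistic is a plain (Welch/paired) t; no variance
  shrinkage, no covariate adjustment.
* The preranked permutation null ignores inter-gene correlation, as any
  gene-sampling null does; FDR q-values are approximate in the way the
  standard desktop implementation's are.
* The per-sample z and the outlier chain assume comparably scaled
  samples; they do not replace normalisation.
* One printed surveillance bound (the prime-dose event rate's upper CI)
  differs from the exact computation by one unit in the second decimal;
  the exact value 4.5388 per million is reproduced by the same formula
  that matches every other printed bound.
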