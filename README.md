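# vaxsig

Analysis toolkit for vaccine reactogenicity signatures: the statistics
needed to characterise transient activation of platelet/coagulation and
innate immune pathways after vaccination, to contrast it with the
sustained activation seen in thrombosis-with-thrombocytopenia (TTS)
patients, and to quantify how rare that adverse event is.

It is written for analysts working with longitudinal bulk RNA-seq and
aptamer (SomaScan-style RFU) serum panels from small vaccine cohorts:
feature-by-sample matrices, sample metadata, GMT pathway collections,
and event/exposure surveillance counts.

## What it computes

* **Exact Poisson adverse-event rates.** For `k` events over `D` doses,
  the rate `1e6·k/D` per million with the exact (Garwood) two-sided CI,
  `[½χ²(α/2, 2k), ½χ²(1−α/2, 2k+2)]/D·1e6` — valid at zero events.
* **Preranked GSEA.** Weighted Kolmogorov–Smirnov enrichment score
  ES ∈ [−1, 1] over a signed ranked list, random same-size permutation
  null (default 1000 draws), meandiv normalisation
  NES = ES / mean|null ES of matching sign|, pooled-null FDR q,
  leading-edge extraction, abs-max probe collapsing, and cross-condition
  NES ratios.
* **Sample-level enrichment (SLEA).** Per pathway and sample,
  z = (mean log expression of members − mean of 1000 random same-size
  gene-set means) / their SD — the pathway × sample matrices behind
  per-sample heatmaps and median-score comparisons.
* **Outlier proteomics for tiny patient groups.** Within-sample z
  against the whole panel median, top-decile selection, strict ratio > 2
  versus a healthy-reference mean, and hypergeometric pathway overlap of
  the selected proteins.
* **Plate QC.** SomaScan-style calibration scale factors and the
  acceptance gate (plate scale factor in [0.4, 2.5]; ≥ 85% of QC ratios
  in [0.8, 1.2]).
* **Paired nonparametrics.** Exact Wilcoxon signed-rank (tie-exact up to
  n = 25), Benjamini–Hochberg adjustment, basemean filtering,
  below-detection imputation, log2 fold-ratio summaries.
* **Synthetic studies.** A seeded generator producing count matrices,
  serum panels, sample tables, gene sets and calibrator plates with the
  longitudinal dose-arm structure the analyses assume, so every stage is
  testable end to end with no external data.

See `docs/methods.md` for models, defaults and design decisions.

## Worked example

`examples/` contains one short script per capability. For instance,
exact adverse-event rates (`python examples/adverse_event_rates.py`):

```
       label    doses  events  rate_per_million  ci_low_per_million  ci_high_per_million
   prime_tts 17015922      60              3.53                2.69                 4.54
prime_deaths 17015922       9              0.53                0.24                 1.00
   boost_tts  1528813       0              0.00                0.00                 2.41
```

Each row turns an event count over administered doses into a rate per
million with an exact 95% CI; the zero-event boost row still bounds the
true rate below ~2.4 per million.

Pathway recovery on a simulated study
(`python examples/enrichment_workflow.py`):

```
            set_name       nes  p_nominal    fdr_q
COAGULATION_PLATELET  2.607216   0.001988 0.000000
INTERFERON_SIGNALING  2.678130   0.001934 0.000000
 INNATE_INFLAMMATION  2.644035   0.001996 0.000000
        RNA_NULL_022  1.521896   0.066798 0.206713
        RNA_NULL_010 -1.541346   0.049900 0.512239
```

The three pathways injected at +1 log2 one day post-vaccination lead the
table at FDR q < 0.10; unperturbed sets stay non-significant.

A thin CLI mirrors the stages for shell use:

```sh
vaxsig simulate --seed 3 --out fixtures/
vaxsig rank --matrix fixtures/counts.tsv --samples fixtures/samples.tsv \
    --contrast ad26_1e11:D2-vs-ad26_1e11:D1 --paired --out stats.tsv --rnk stats.rnk
vaxsig gsea --rnk stats.rnk --gmt fixtures/sets.gmt --seed 1 --out gsea.tsv
```

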