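"""End-to-end compositions of the analysis stages.

Three study-shaped analyses, each a plain function over in-memory
containers so they can run on simulated or user-supplied data alike:

* :func:`run_dose_response` — per arm and post-vaccination day, rank
  features against baseline, run preranked enrichment, build the
  per-sample pathway z matrix, and summarise activation kinetics
  (peak at D2, resolution by D8, dose ordering).
* :func:`run_prime_boost` — paired post-prime (D2) vs post-boost (D58)
  contrast, per-pathway NES ratios, paired Wilcoxon on per-subject
  pathway scores.
* :func:`run_tts` — outlier-protein selection for patient samples against
  a healthy reference panel, then pathway overlap enrichment.

Reports are dataclasses of DataFrames plus a manifest dict recording
every parameter and seed, so a fixed-seed run is reproducible file for
file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    ValidationError,
)
from .diffstats import Contrast, feature_stats, filter_low_expression, wilcoxon_signed_rank
from .gsea import RankedList, nes_ratio, preranked_gsea
from .slea import SLEAMatrix, median_slea, slea_matrix
from .tts import overlap_enrichment, select_outliers, union_selection

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters shared by the composed analyses.

    Defaults follow standard desktop enrichment practice: 1000
    permutations, set sizes 10-5000, weighted statistic, 1000 random
    gene sets for the per-sample z, FDR threshold 0.10.
    """

    n_perm: int = 1000
    min_size: int = 10
    max_size: int = 5000
    weight: float = 1.0
    n_random: int = 1000
    fdr_threshold: float = 0.10
    alpha: float = 0.05
    basemean_min: float = 10.0
    tts_percentile: float = 0.90
    tts_ratio_min: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def manifest(self, **extra) -> dict:
        entry = {k: getattr(self, k) for k in self.__dataclass_fields__}
        entry.update(extra)
        entry["config_hash"] = hashlib.sha256(
            json.dumps(entry, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return entry


@dataclass
class DoseResponseReport:
    gsea: dict[tuple[str, str], pd.DataFrame]  # (arm, timepoint) -> results
    slea: dict[str, SLEAMatrix]  # arm -> pathway x sample z
    median_scores: pd.DataFrame  # set_name, arm, timepoint, median_z
    kinetics: pd.DataFrame  # per activated set: D2 vs D8 and dose ordering
    manifest: dict = field(default_factory=dict)


def run_dose_response(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    collection: GeneSetCollection,
    config: PipelineConfig,
    arms: tuple[str, str] = ("ad26_5e10", "ad26_1e11"),
    post_timepoints: tuple[str, ...] = ("D2", "D8"),
    truth_sets: list[str] | None = None,
) -> DoseResponseReport:
    """Activation kinetics across dose arms.

    For each arm and post-vaccination day: paired contrast against D1,
    preranked enrichment, pathway-per-sample z matrix, per-day median z.
    ``kinetics`` compares, for each set in ``truth_sets`` (or every set
    significant at the FDR threshold), D2 against D8 medians and the
    high- against the low-dose arm at D2, with paired Wilcoxon p-values.
    """
    t0 = time.time()
    samples.check_covers(matrix)
    rng = np.random.default_rng(config.seed)
    gsea_results: dict[tuple[str, str], pd.DataFrame] = {}
    slea_by_arm: dict[str, SLEAMatrix] = {}
    median_rows = []
    for arm in arms:
        for tp in post_timepoints:
            contrast = Contrast(arm, tp, arm, "D1")
            table = feature_stats(matrix, samples, contrast, paired=True)
            table = filter_low_expression(table, config.basemean_min)
            ranked = RankedList.from_table(table)
            res = preranked_gsea(
                ranked, collection, n_perm=config.n_perm, min_size=config.min_size,
                max_size=config.max_size, weight=config.weight,
                seed=int(rng.integers(2**31)),
            )
            gsea_results[(arm, tp)] = res
            logger.info(
                "dose_response: arm=%s tp=%s ranked=%d sets=%d elapsed=%.1fs",
                arm, tp, len(ranked), len(res), time.time() - t0,
            )
        arm_samples = [
            s for tp in ("D1", *post_timepoints) for s in samples.select(group=arm, timepoint=tp)
            if s in set(matrix.sample_ids)
        ]
        sub = matrix.subset_samples(arm_samples)
        slea_by_arm[arm] = slea_matrix(
            sub, collection, n_random=config.n_random, seed=int(rng.integers(2**31))
        )
        for tp in ("D1", *post_timepoints):
            ids = [s for s in samples.select(group=arm, timepoint=tp) if s in arm_samples]
            if not ids:
                raise ValidationError(f"missing timepoint {tp} for arm {arm}")
            med = median_slea(slea_by_arm[arm], ids)
            for set_name, z in med.items():
                median_rows.append(
                    {"set_name": set_name, "arm": arm, "timepoint": tp, "median_z": z}
                )
    medians = pd.DataFrame(median_rows)

    if truth_sets is None:
        high_d2 = gsea_results[(arms[1], "D2")]
        truth_sets = high_d2.loc[high_d2["fdr_q"] < config.fdr_threshold, "set_name"].tolist()
    kin_rows = []
    piv = medians.set_index(["set_name", "arm", "timepoint"])["median_z"]
    low, high = arms
    for name in truth_sets:
        row = {
            "set_name": name,
            "median_z_d2_high": piv.get((name, high, "D2"), np.nan),
            "median_z_d8_high": piv.get((name, high, "D8"), np.nan),
            "median_z_d2_low": piv.get((name, low, "D2"), np.nan),
        }
        row["d2_exceeds_d8"] = bool(row["median_z_d2_high"] > row["median_z_d8_high"])
        row["high_exceeds_low"] = bool(row["median_z_d2_high"] > row["median_z_d2_low"])
        # paired Wilcoxon across subjects on per-sample z, D2 vs D8, high dose
        z_high = slea_by_arm[high].scores
        d2_ids = [s for s in samples.select(group=high, timepoint="D2") if s in z_high.columns]
        d8_ids = [s for s in samples.select(group=high, timepoint="D8") if s in z_high.columns]
        if name in z_high.index and len(d2_ids) == len(d8_ids) and len(d2_ids) >= 2:
            try:
                _, p = wilcoxon_signed_rank(
                    z_high.loc[name, d2_ids].to_numpy(), z_high.loc[name, d8_ids].to_numpy()
                )
            except ValueError:
                p = np.nan
            row["wilcoxon_p_d2_vs_d8"] = p
        else:
            row["wilcoxon_p_d2_vs_d8"] = np.nan
        kin_rows.append(row)
    kinetics = pd.DataFrame(kin_rows)
    manifest = config.manifest(stage="dose_response", arms=list(arms), elapsed_s=time.time() - t0)
    return DoseResponseReport(gsea_results, slea_by_arm, medians, kinetics, manifest)


@dataclass
class PrimeBoostReport:
    gsea_d2: pd.DataFrame
    gsea_d58: pd.DataFrame
    nes_ratios: pd.DataFrame  # pathway, NES_D2, NES_D58, ratio
    slea: SLEAMatrix
    pathway_wilcoxon: pd.DataFrame  # per set: paired p of D2 vs D58 z
    manifest: dict = field(default_factory=dict)


def run_prime_boost(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    collection: GeneSetCollection,
    config: PipelineConfig,
    arm: str = "ad26_1e11",
) -> PrimeBoostReport:
    """Post-prime (D2) vs post-boost (D58) comparison within one arm.

    Both days are ranked against baseline with paired contrasts, the
    per-pathway NES ratio D2/D58 is computed for sets significant at D2,
    and per-subject pathway z-scores are compared D2 vs D58 with the
    matched Wilcoxon signed-rank test.
    """
    t0 = time.time()
    samples.check_covers(matrix)
    rng = np.random.default_rng(config.seed)
    d2_ids = [s for s in samples.select(group=arm, timepoint="D2") if s in set(matrix.sample_ids)]
    d58_ids = [s for s in samples.select(group=arm, timepoint="D58") if s in set(matrix.sample_ids)]
    if not d2_ids or not d58_ids:
        raise ValidationError(f"arm {arm} lacks paired D2/D58 samples")
    df = samples.frame.set_index("sample_id")
    subj_d2 = {df.loc[s, "subject_id"] for s in d2_ids}
    subj_d58 = {df.loc[s, "subject_id"] for s in d58_ids}
    if subj_d2 != subj_d58:
        raise ValidationError(
            f"broken D2/D58 pairing for subjects: {sorted(subj_d2 ^ subj_d58)}"
        )

    results = {}
    for tp in ("D2", "D58"):
        table = feature_stats(matrix, samples, Contrast(arm, tp, arm, "D1"), paired=True)
        table = filter_low_expression(table, config.basemean_min)
        ranked = RankedList.from_table(table)
        results[tp] = preranked_gsea(
            ranked, collection, n_perm=config.n_perm, min_size=config.min_size,
            max_size=config.max_size, weight=config.weight,
            seed=int(rng.integers(2**31)),
        )
    sig_d2 = results["D2"][results["D2"]["fdr_q"] < config.fdr_threshold]
    ratios = nes_ratio(results["D2"], results["D58"])
    ratios = ratios[ratios["set_name"].isin(sig_d2["set_name"])].reset_index(drop=True)
    ratios = ratios.rename(columns={"nes_a": "nes_d2", "nes_b": "nes_d58"})

    both = matrix.subset_samples(d2_ids + d58_ids)
    slea = slea_matrix(both, collection, n_random=config.n_random,
                       seed=int(rng.integers(2**31)))
    subj_order = sorted(subj_d2)
    d2_by_subj = {df.loc[s, "subject_id"]: s for s in d2_ids}
    d58_by_subj = {df.loc[s, "subject_id"]: s for s in d58_ids}
    wil_rows = []
    for name in slea.scores.index:
        x = slea.scores.loc[name, [d2_by_subj[s] for s in subj_order]].to_numpy()
        y = slea.scores.loc[name, [d58_by_subj[s] for s in subj_order]].to_numpy()
        try:
            w, p = wilcoxon_signed_rank(x, y)
        except ValueError as exc:  # all-zero differences or single subject
            logger.warning("prime_boost: Wilcoxon undefined for %s: %s", name, exc)
            w, p = np.nan, np.nan
        wil_rows.append({"set_name": name, "w_plus": w, "p_value": p,
                         "median_z_d2": float(np.median(x)), "median_z_d58": float(np.median(y))})
    wil = pd.DataFrame(wil_rows)
    manifest = config.manifest(stage="prime_boost", arm=arm, elapsed_s=time.time() - t0)
    return PrimeBoostReport(results["D2"], results["D58"], ratios, slea, wil, manifest)


@dataclass
class TTSReport:
    selections: list  # per-timepoint OutlierSelection
    union: list[str]
    enrichment: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_tts(
    tts_matrix: ExpressionMatrix,
    reference_matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    config: PipelineConfig,
    timepoints: dict[str, str] | None = None,
) -> TTSReport:
    """Patient-sample outlier selection plus pathway overlap enrichment.

    Enrichment runs on the union of per-timepoint selections against the
    full protein universe; an empty selection yields an empty enrichment
    table rather than an error.
    """
    t0 = time.time()
    selections = select_outliers(
        tts_matrix, reference_matrix, timepoints=timepoints,
        q=config.tts_percentile, ratio_min=config.tts_ratio_min,
    )
    union = union_selection(selections)
    if union:
        enr = overlap_enrichment(union, collection, set(tts_matrix.feature_ids))
    else:
        logger.warning("run_tts: no protein selected; skipping enrichment")
        enr = pd.DataFrame(
            columns=["set_name", "set_size", "overlap", "p_value", "p_adjusted"]
        )
    manifest = config.manifest(
        stage="tts", n_selected=len(union),
        n_tts_samples=tts_matrix.n_samples, elapsed_s=time.time() - t0,
    )
    return TTSReport(selections, union, enr, manifest)
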