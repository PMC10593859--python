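"""Outlier-proteomics selection for tiny patient groups.

With only a couple of thrombosis-with-thrombocytopenia (TTS) patients, a
group-wise differential test has no power, so selection works within each
patient sample instead:

1. within-sample z: for each analyte, how far its log2 RFU lies from the
   sample median of the whole SOMAmer panel, in panel-SD units;
2. keep analytes in the top decile of that z (percentile rank >= 0.90,
   ties at the boundary included);
3. keep, of those, analytes whose linear-scale RFU exceeds twice the mean
   of a healthy reference panel (strict ratio > 2).

Selected proteins are then tested for overlap with annotated pathway sets
(coagulation, platelet, interferon, ...) by the upper-tail hypergeometric
test with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSetCollection, ValidationError
from .diffstats import bh_adjust


@dataclass
class OutlierSelection:
    """Per-timepoint selection with the evidence behind each protein."""

    timepoint: str
    sample_id: str
    table: pd.DataFrame  # feature_id, z_within_sample, percentile_rank, ratio_to_baseline
    percentile: float
    ratio_min: float

    @property
    def selected(self) -> list[str]:
        return self.table["feature_id"].tolist()


def sample_zscore(rfu_vector: np.ndarray, scale: str = "sd") -> np.ndarray:
    """Within-sample z of each analyte against the whole panel.

    Computed on log2 RFU: ``z_i = (x_i - median(x)) / s`` where ``s`` is
    the standard deviation about the median (``scale="sd"``) or the
    normal-consistent MAD (``scale="mad"``). The log scale makes the z
    invariant to a global rescaling of the sample's RFU.
    """
    rfu = np.asarray(rfu_vector, dtype=float)
    if rfu.size < 3:
        raise ValidationError("need at least 3 analytes for a within-sample z")
    if (rfu <= 0).any():
        raise ValidationError("RFU values must be strictly positive")
    x = np.log2(rfu)
    med = np.median(x)
    if scale == "sd":
        s = np.sqrt(((x - med) ** 2).sum() / (x.size - 1))
    elif scale == "mad":
        s = stats.median_abs_deviation(x, scale="normal")
    else:
        raise ValueError(f"unknown scale {scale!r}; use 'sd' or 'mad'")
    if s <= 0:
        raise ValidationError("zero panel dispersion; z undefined")
    return (x - med) / s


def percentile_ranks(z_vector: np.ndarray) -> np.ndarray:
    """Fraction of analytes with strictly smaller z, per analyte."""
    z = np.asarray(z_vector, dtype=float)
    order = np.argsort(z, kind="mergesort")
    sorted_z = z[order]
    # count of strictly smaller values via left-searchsorted on sorted copy
    smaller = np.searchsorted(sorted_z, z, side="left")
    return smaller / z.size


def select_top_percentile(z_vector: np.ndarray, q: float = 0.90) -> np.ndarray:
    """Boolean mask of analytes whose percentile rank is >= q.

    With all-distinct z this is the top ``(1-q)`` fraction; ties at the
    boundary are all included.
    """
    return percentile_ranks(z_vector) >= q


def baseline_ratio(
    tts_values: np.ndarray, reference_matrix: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature ratio of one TTS sample to the healthy-reference mean.

    The baseline is the arithmetic mean of linear-scale reference RFU per
    protein. Returns ``(ratio, valid)``; features with a non-positive
    baseline mean are invalid and carry NaN.
    """
    tts = np.asarray(tts_values, dtype=float)
    if reference_matrix.n_samples < 1:
        raise ValidationError("reference matrix has no samples")
    if tts.size != reference_matrix.n_features:
        raise ValidationError("TTS vector and reference features differ in length")
    baseline = reference_matrix.values.mean(axis=1)
    valid = baseline > 0
    ratio = np.full(tts.size, np.nan)
    ratio[valid] = tts[valid] / baseline[valid]
    return ratio, valid


def select_outliers(
    tts_matrix: ExpressionMatrix,
    reference_matrix: ExpressionMatrix,
    timepoints: dict[str, str] | None = None,
    q: float = 0.90,
    ratio_min: float = 2.0,
    scale: str = "sd",
) -> list[OutlierSelection]:
    """Full selection chain, one :class:`OutlierSelection` per TTS sample.

    ``timepoints`` maps sample_id -> timepoint label (defaults to the
    sample_id itself). The two matrices must share the feature universe
    in the same order.
    """
    if tts_matrix.feature_ids != reference_matrix.feature_ids:
        raise ValidationError("TTS and reference matrices must share features in order")
    out = []
    for j, sample_id in enumerate(tts_matrix.sample_ids):
        rfu = tts_matrix.values[:, j]
        z = sample_zscore(rfu, scale=scale)
        pr = percentile_ranks(z)
        top = pr >= q
        ratio, valid = baseline_ratio(rfu, reference_matrix)
        keep = top & valid & (ratio > ratio_min)
        idx = np.nonzero(keep)[0]
        idx = idx[np.argsort(-z[idx], kind="mergesort")]
        table = pd.DataFrame(
            {
                "feature_id": [tts_matrix.feature_ids[i] for i in idx],
                "z_within_sample": z[idx],
                "percentile_rank": pr[idx],
                "ratio_to_baseline": ratio[idx],
            }
        )
        tp = (timepoints or {}).get(sample_id, sample_id)
        out.append(
            OutlierSelection(
                timepoint=tp, sample_id=sample_id, table=table,
                percentile=q, ratio_min=ratio_min,
            )
        )
    return out


def union_selection(selections: list[OutlierSelection]) -> list[str]:
    """Union of per-timepoint selections, ordered by best (highest) z."""
    best: dict[str, float] = {}
    for sel in selections:
        for fid, z in zip(sel.table["feature_id"], sel.table["z_within_sample"]):
            if fid not in best or z > best[fid]:
                best[fid] = z
    return sorted(best, key=lambda f: (-best[f], f))


def overlap_enrichment(
    selected: list[str] | set[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap of a selection with each set.

    With universe size N, selection size n and a set of size K (after
    intersection with the universe), the p-value is
    ``P(overlap >= observed)`` under random draws of n from N. BH
    adjustment runs across the collection's sets.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    sel = set(selected) & universe
    stray = set(selected) - universe
    if stray:
        raise ValidationError(f"selected features outside the universe: {sorted(stray)}")
    n_univ = len(universe)
    n_sel = len(sel)
    rows = []
    for name in collection.names():
        members = collection[name] & universe
        k_set = len(members)
        overlap = len(sel & members)
        # survival function at overlap-1 gives P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, k_set, n_sel))
        rows.append(
            {
                "set_name": name,
                "set_size": k_set,
                "overlap": overlap,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p_value"].to_numpy())
        result = result.sort_values(
            ["p_value", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    return result
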