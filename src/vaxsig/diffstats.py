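"""Per-feature differential statistics and the small rules around them.

The ranking statistic feeding preranked enrichment is a Welch (unpaired)
or paired t statistic computed on log2-transformed values: counts are
library-size normalised to counts-per-million and taken as ``log2(cpm+1)``,
RFU and pg/mL intensities as ``log2(x)``. This is a deliberately simple
signed ranking metric — downstream enrichment is rank-based, so moderated
or shrunken variants would change individual p-values but not the analyses
built on the ranking.

Also here: Benjamini–Hochberg adjustment, an exact Wilcoxon signed-rank
test (ties handled exactly via the rank-sum distribution), low-expression
filtering on basemean, fold-ratio summaries, and replacement of
below-detection cytokine values by the per-analyte column minimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SampleTable, ValidationError

logger = logging.getLogger(__name__)

#: Columns of a feature statistics table, in output order.
STAT_COLUMNS = (
    "feature_id",
    "statistic",
    "p_value",
    "p_adjusted",
    "log2_fold_change",
    "base_mean",
)


@dataclass(frozen=True)
class Contrast:
    """Two cell definitions (group, timepoint) to compare, a minus b."""

    group_a: str
    timepoint_a: str
    group_b: str
    timepoint_b: str

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse ``"group:timepoint-vs-group:timepoint"``."""
        try:
            a, b = text.split("-vs-")
            ga, ta = a.split(":")
            gb, tb = b.split(":")
        except ValueError:
            raise ValueError(
                f"contrast {text!r} is not of the form group:tp-vs-group:tp"
            ) from None
        return cls(ga, ta, gb, tb)


def log_expression(matrix: ExpressionMatrix) -> np.ndarray:
    """Log2 expression on the scale used for testing and enrichment.

    Counts: log2(CPM + 1) after per-sample library-size normalisation.
    RFU / pg-per-mL intensities: plain log2.
    """
    if matrix.assay_kind == "rnaseq_counts":
        return np.log2(normalized_counts(matrix) + 1.0)
    vals = matrix.values
    if (vals <= 0).any():
        raise ValidationError("non-positive intensity cannot be log-transformed")
    return np.log2(vals)


def normalized_counts(matrix: ExpressionMatrix) -> np.ndarray:
    """Counts-per-million library-size normalisation (counts only)."""
    if matrix.assay_kind != "rnaseq_counts":
        return matrix.values.copy()
    libsize = matrix.values.sum(axis=0)
    if (libsize <= 0).any():
        raise ValidationError("sample with zero library size")
    return matrix.values / libsize * 1e6


def feature_stats(
    matrix: ExpressionMatrix,
    sample_table: SampleTable,
    contrast: Contrast,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-feature t statistics for one two-cell contrast.

    Unpaired contrasts use the Welch t on log expression; paired contrasts
    match samples by ``subject_id`` across the two cells and use the paired
    t on within-subject differences. ``base_mean`` is the mean normalised
    value over all samples in the matrix (the scale the basemean < 10
    filter applies to). Ties in the statistic are broken by feature ID so
    the resulting ordering is total and reproducible.

    Returns a DataFrame with :data:`STAT_COLUMNS`, sorted by statistic
    descending.
    """
    sample_table.check_covers(matrix)
    ids_a = _cell_samples(matrix, sample_table, contrast.group_a, contrast.timepoint_a)
    ids_b = _cell_samples(matrix, sample_table, contrast.group_b, contrast.timepoint_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(
            f"each contrast cell needs >=2 samples; got {len(ids_a)} and {len(ids_b)}"
        )
    logx = log_expression(matrix)
    sidx = matrix.sample_index()
    a = logx[:, [sidx[s] for s in ids_a]]
    b = logx[:, [sidx[s] for s in ids_b]]

    if paired:
        a, b = _align_pairs(sample_table, ids_a, ids_b, logx, sidx)
        diffs = a - b
        n = diffs.shape[1]
        mean_d = diffs.mean(axis=1)
        sd_d = diffs.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd_d > 0, mean_d / (sd_d / math.sqrt(n)), 0.0)
        df = np.full(matrix.n_features, n - 1, dtype=float)
    else:
        na, nb = a.shape[1], b.shape[1]
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2), 0.0)
            df = np.where(
                se2 > 0,
                se2**2
                / ((va / na) ** 2 / max(na - 1, 1) + (vb / nb) ** 2 / max(nb - 1, 1)),
                1.0,
            )
    p = np.where(t == 0.0, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    norm = normalized_counts(matrix)
    base_mean = norm.mean(axis=1)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "statistic": t,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
            "log2_fold_change": log2fc,
            "base_mean": base_mean,
        }
    )
    table = table.sort_values(
        ["statistic", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def filter_low_expression(table: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Drop features with ``base_mean`` strictly below ``threshold``.

    Features exactly at the threshold are kept (the rule removes < 10).
    """
    if "base_mean" not in table.columns:
        raise ValidationError("table has no base_mean column")
    kept = table[table["base_mean"] >= threshold].reset_index(drop=True)
    n_removed = len(table) - len(kept)
    if n_removed:
        logger.info("filter_low_expression: removed %d of %d features", n_removed, len(table))
    if kept.empty:
        logger.warning("filter_low_expression: no feature passed basemean >= %s", threshold)
    return kept


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Matched two-tailed Wilcoxon signed-rank test.

    Pass paired vectors ``x, y`` (differences ``x - y`` are tested) or a
    single vector of differences. Zero differences are dropped before
    ranking. For n <= 25 the p-value is exact — computed from the full
    null distribution of the positive-rank sum over all 2^n sign
    assignments (ties handled via midranks, so the exact p matches
    enumeration even with tied magnitudes). Larger n uses the normal
    approximation with tie and continuity corrections.

    Returns ``(W_plus, p_two_sided)``.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: no information")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance of the rank sum
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return w_plus, float(min(p, 1.0))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the positive rank sum.

    Doubling the midranks makes them integers, so the distribution of the
    doubled rank sum over all equally-likely sign assignments is computed
    by dynamic programming in O(n * total).
    """
    doubled = np.rint(ranks * 2).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_low, p_high))


def log2_ratio(means_a: pd.Series, means_b: pd.Series) -> pd.DataFrame:
    """Per-feature log2(a/b) of group means on the linear scale.

    Features with non-positive mean in either input are flagged (column
    ``flagged``) and excluded from the ratio (NaN). Inputs must share at
    least one feature; the output covers the intersection in the order of
    ``means_a``.
    """
    common = [f for f in means_a.index if f in set(means_b.index)]
    if not common:
        raise ValidationError("inputs share no features")
    a = means_a.loc[common].astype(float)
    b = means_b.loc[common].astype(float)
    flagged = (a <= 0) | (b <= 0)
    ratio = pd.Series(np.nan, index=a.index, dtype=float)
    ok = ~flagged
    ratio[ok] = np.log2(a[ok] / b[ok])
    return pd.DataFrame(
        {"log2_ratio": ratio, "flagged": flagged.astype(bool)}
    ).rename_axis("feature_id")


def group_means(
    matrix: ExpressionMatrix, sample_ids: list[str], linear: bool = True
) -> pd.Series:
    """Per-feature mean over ``sample_ids`` (linear normalised scale)."""
    sub = matrix.subset_samples(sample_ids)
    vals = normalized_counts(sub) if linear else log_expression(sub)
    return pd.Series(vals.mean(axis=1), index=sub.feature_ids, name="mean")


def impute_below_detection(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace below-detection cells by the minimum observed value of the
    same analyte (row) across samples.

    An analyte with every value below detection has no observed minimum
    and is an error.
    """
    if matrix.below_detection is None or not matrix.below_detection.any():
        return ExpressionMatrix(
            feature_ids=list(matrix.feature_ids),
            sample_ids=list(matrix.sample_ids),
            values=matrix.values.copy(),
            assay_kind=matrix.assay_kind,
        )
    values = matrix.values.copy()
    mask = matrix.below_detection
    all_masked = mask.all(axis=1)
    if all_masked.any():
        bad = [matrix.feature_ids[i] for i in np.nonzero(all_masked)[0]]
        raise ValidationError(f"analytes with all values below detection: {bad}")
    masked_vals = np.where(mask, np.inf, values)
    row_min = masked_vals.min(axis=1)
    rows, cols = np.nonzero(mask)
    values[rows, cols] = row_min[rows]
    return ExpressionMatrix(
        feature_ids=list(matrix.feature_ids),
        sample_ids=list(matrix.sample_ids),
        values=values,
        assay_kind=matrix.assay_kind,
    )


def _cell_samples(
    matrix: ExpressionMatrix, table: SampleTable, group: str, timepoint: str
) -> list[str]:
    present = set(matrix.sample_ids)
    ids = [s for s in table.select(group=group, timepoint=timepoint) if s in present]
    if not ids:
        raise ValidationError(f"no samples for cell ({group}, {timepoint}) in matrix")
    return ids


def _align_pairs(
    table: SampleTable,
    ids_a: list[str],
    ids_b: list[str],
    logx: np.ndarray,
    sidx: dict[str, int],
) -> tuple[np.ndarray, np.ndarray]:
    df = table.frame.set_index("sample_id")
    subj_a = {df.loc[s, "subject_id"]: s for s in ids_a}
    subj_b = {df.loc[s, "subject_id"]: s for s in ids_b}
    shared = [subj for subj in subj_a if subj in subj_b]
    unmatched = sorted(set(subj_a) ^ set(subj_b))
    if unmatched:
        raise ValidationError(f"paired contrast with unmatched subjects: {unmatched}")
    if len(shared) < 2:
        raise ValidationError("paired contrast needs >=2 matched subjects")
    cols_a = [sidx[subj_a[s]] for s in shared]
    cols_b = [sidx[subj_b[s]] for s in shared]
    return logx[:, cols_a], logx[:, cols_b]
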