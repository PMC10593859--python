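"""Sample-level enrichment analysis (SLEA).

For one pathway and one sample, the observed score is the mean log
expression of the pathway's members in that sample. It is compared with
the means of ``n_random`` random feature sets of the same size drawn from
all features of the matrix, and expressed as a z-score:

    z = (observed - mean(null)) / sd(null)

The same random draws are reused for every sample within one call, so
differences between samples in one pathway row reflect the data, not
null-sampling noise. A pathway x sample matrix of these z-scores is the
quantity plotted in per-sample pathway heatmaps; per-set medians over a
sample subset feed paired comparisons (e.g. post-prime vs post-boost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection, ValidationError
from .diffstats import log_expression

logger = logging.getLogger(__name__)

_DEGENERATE_SD = 1e-12


@dataclass
class SLEAMatrix:
    """Pathway x sample z-score grid plus the null parameters used."""

    scores: pd.DataFrame  # set_names x sample_ids
    n_random: int
    seed: int | None
    flagged: dict[str, str]

    def to_tsv(self, path) -> None:
        self.scores.rename_axis("set_name").to_csv(path, sep="\t")


def slea_zscore(
    matrix: ExpressionMatrix,
    gene_set: frozenset[str] | set[str],
    n_random: int = 1000,
    seed: int | np.random.Generator = 0,
    log_values: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Per-sample SLEA z-scores for one set.

    Returns ``(z, degenerate)``; when the null standard deviation is
    numerically zero (e.g. a constant matrix) all z are set to 0 and the
    degenerate flag is raised instead of emitting NaN.

    ``log_values`` may pass a precomputed log-expression grid to avoid
    re-transforming the matrix for every set of a collection.
    """
    rng = np.random.default_rng(seed)
    logx = log_expression(matrix) if log_values is None else log_values
    members = frozenset(gene_set)
    fidx = matrix.feature_index()
    rows = sorted(fidx[f] for f in members if f in fidx)
    k = len(rows)
    n = matrix.n_features
    if k < 2:
        raise ValidationError(f"set intersects matrix in {k} < 2 features")
    if k >= n:
        raise ValidationError("set covers every feature; null is undefined")
    observed = logx[rows, :].mean(axis=0)
    # one draw matrix shared by all samples of this call
    keys = rng.random((n_random, n))
    draw = np.argpartition(keys, k, axis=1)[:, :k]
    null_means = logx[draw, :].mean(axis=1)  # (n_random, n_samples)
    mu = null_means.mean(axis=0)
    sd = null_means.std(axis=0, ddof=1)
    degenerate = bool((sd < _DEGENERATE_SD).any())
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd < _DEGENERATE_SD, 0.0, (observed - mu) / sd)
    return z, degenerate


def slea_matrix(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    n_random: int = 1000,
    seed: int = 0,
) -> SLEAMatrix:
    """One SLEA z row per set of the collection, in collection order.

    Per-set failures (too-small intersection, degenerate null) become
    flagged all-zero rows rather than aborting the whole matrix.
    """
    logx = log_expression(matrix)
    rng = np.random.default_rng(seed)
    rows: dict[str, np.ndarray] = {}
    flagged: dict[str, str] = {}
    for name in collection.names():
        try:
            z, degenerate = slea_zscore(
                matrix, collection[name], n_random=n_random, seed=rng,
                log_values=logx,
            )
        except ValidationError as exc:
            logger.warning("slea_matrix: set %s flagged: %s", name, exc)
            rows[name] = np.zeros(matrix.n_samples)
            flagged[name] = str(exc)
            continue
        rows[name] = z
        if degenerate:
            flagged[name] = "degenerate null (sd ~ 0); z set to 0"
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.sample_ids)
    scores = scores.loc[collection.names()]
    return SLEAMatrix(scores=scores, n_random=n_random,
                      seed=seed if isinstance(seed, int) else None, flagged=flagged)


def median_slea(slea: SLEAMatrix, sample_subset: list[str]) -> pd.Series:
    """Per-set median z over a sample subset (e.g. one arm at one day)."""
    if not sample_subset:
        raise ValidationError("empty sample subset")
    missing = [s for s in sample_subset if s not in slea.scores.columns]
    if missing:
        raise ValidationError(f"samples not in SLEA matrix: {missing}")
    return slea.scores.loc[:, sample_subset].median(axis=1)
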