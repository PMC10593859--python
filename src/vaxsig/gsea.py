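"""Preranked gene-set enrichment analysis (weighted Kolmogorov–Smirnov).

Given a feature list ranked by a signed statistic, the enrichment score of
a set is the signed extremum of a running sum that increments by
``|stat|^weight / sum_hits |stat|^weight`` at each set member ("hit") and
decrements by ``1 / (N - N_hits)`` at each non-member. Significance comes
from a permutation null of random same-size feature draws from the ranked
universe (the preranked null — phenotype permutation is unavailable
without per-sample labels). Normalisation is "meandiv": NES is the ES
divided by the mean magnitude of same-sign null scores; the FDR q-value
uses the pooled positive/negative normalised-null procedure.

Defaults mirror standard desktop practice: 1000 permutations, set sizes
filtered to [10, 5000] after intersection with the ranked universe,
weight 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, ProbeMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Feature IDs ordered by descending signed statistic.

    Ties in the statistic are broken lexicographically by feature ID, so
    the ordering is total and identical across runs.
    """

    feature_ids: list[str]
    statistics: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.statistics = np.asarray(self.statistics, dtype=float)
        if len(self.feature_ids) != self.statistics.size:
            raise ValidationError("feature/statistic length mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate features in ranked list")
        order = sorted(
            range(len(self.feature_ids)),
            key=lambda i: (-self.statistics[i], self.feature_ids[i]),
        )
        self.feature_ids = [self.feature_ids[i] for i in order]
        self.statistics = self.statistics[list(order)]

    def __len__(self) -> int:
        return len(self.feature_ids)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "RankedList":
        """Build from a feature-statistics table (feature_id, statistic)."""
        return cls(table["feature_id"].tolist(), table["statistic"].to_numpy())


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: frozenset[str]
    set_size_used: int
    flags: list[str] = field(default_factory=list)


def collapse_probes(ranked: RankedList, probe_map: ProbeMap) -> RankedList:
    """Collapse probe-level statistics to genes, keeping per gene the probe
    with the maximal absolute statistic (abs-max collapsing).

    A tie in |statistic| between two probes of one gene keeps the
    lexicographically smaller probe's value; the decision is logged.
    """
    unmapped = [p for p in ranked.feature_ids if p not in probe_map]
    if unmapped:
        raise ValidationError(f"probes missing from probe map: {unmapped}")
    best: dict[str, tuple[float, str]] = {}
    for probe, stat in zip(ranked.feature_ids, ranked.statistics):
        gene = probe_map[probe]
        key = (abs(stat), )
        if gene not in best:
            best[gene] = (stat, probe)
            continue
        cur_stat, cur_probe = best[gene]
        if abs(stat) > abs(cur_stat):
            best[gene] = (stat, probe)
        elif abs(stat) == abs(cur_stat) and probe < cur_probe:
            logger.info(
                "collapse_probes: tie on |stat| for gene %s; keeping probe %s over %s",
                gene, probe, cur_probe,
            )
            best[gene] = (stat, probe)
    genes = sorted(best)
    return RankedList(genes, np.array([best[g][0] for g in genes]))


def enrichment_score(
    ranked: RankedList, gene_set: frozenset[str] | set[str], weight: float = 1.0
) -> tuple[float, np.ndarray, frozenset[str]]:
    """Weighted running-sum enrichment score of one set.

    Returns ``(ES, running_sum, leading_edge)`` where ``running_sum`` has
    one entry per ranked feature (value after that feature is processed)
    and the leading edge contains the hit members at or before the
    extremum (at or after it, for negative ES).
    """
    members = frozenset(gene_set)
    hit_mask = np.fromiter(
        (f in members for f in ranked.feature_ids), dtype=bool, count=len(ranked)
    )
    n = len(ranked)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValidationError("gene set has no member in the ranked list")
    if n_hits == n:
        raise ValidationError("gene set covers the whole ranked list (no misses)")
    weights = np.abs(ranked.statistics) ** weight
    hit_w = np.where(hit_mask, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit statistics are exactly zero; fall back to equal weights
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # signed extremum; when the two magnitudes tie exactly, the positive
    # deviation is reported
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        le_mask = hit_mask & (np.arange(n) <= i_max)
    else:
        le_mask = hit_mask & (np.arange(n) >= i_min)
    leading = frozenset(
        f for f, m in zip(ranked.feature_ids, le_mask) if m
    )
    return float(es), running, leading


def _es_from_positions(
    positions: np.ndarray, abs_weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorised ES for many same-size hit-position draws.

    ``positions`` is (n_draws, k) of sorted 0-based ranks; ``abs_weights``
    are |stat|^weight per rank. Candidate extrema occur only immediately
    after a hit (running maximum) or immediately before one (minimum).
    """
    k = positions.shape[1]
    w = abs_weights[positions]
    denom = w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        denom = w.sum(axis=1, keepdims=True)
    cum_w = np.cumsum(w, axis=1) / denom
    miss = 1.0 / (n - k)
    j = np.arange(k)
    misses_before = positions - j  # non-members strictly before hit j
    after = cum_w - (misses_before) * miss
    before = np.concatenate(
        [np.zeros((positions.shape[0], 1)), cum_w[:, :-1]], axis=1
    ) - misses_before * miss
    es_max = after.max(axis=1)
    es_min = np.minimum(before.min(axis=1), 0.0)
    return np.where(es_max >= -es_min, es_max, es_min)


def preranked_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 10,
    max_size: int = 5000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection, with permutation p and FDR q.

    For each set passing the size filter (after intersection with the
    ranked universe) the null is ``n_perm`` ES values of random same-size
    draws from the universe. NES divides ES by the mean |null ES| of
    matching sign; nominal p is the fraction of same-sign null ES at least
    as extreme, using the (r+1)/(n+1) estimator; FDR q pools normalised
    null and observed scores by sign, then enforces monotonicity in |NES|.

    Returns a DataFrame with columns set_name, set_size_used, es, nes,
    p_nominal, fdr_q, leading_edge (comma-joined, ranked order), flags.
    """
    rng = np.random.default_rng(seed)
    universe = set(ranked.feature_ids)
    usable = collection.filter_sizes(universe, min_size, max_size)
    if len(usable) == 0:
        logger.warning("preranked_gsea: no set passed the size filter")
        return pd.DataFrame(
            columns=[
                "set_name", "set_size_used", "es", "nes",
                "p_nominal", "fdr_q", "leading_edge", "flags",
            ]
        )
    n = len(ranked)
    abs_w = np.abs(ranked.statistics) ** weight
    rank_of = {f: i for i, f in enumerate(ranked.feature_ids)}
    order = np.array(ranked.feature_ids)

    rows = []
    null_by_set: dict[str, np.ndarray] = {}
    for name in usable.names():
        members = usable[name]
        k = len(members)
        es, _, leading = enrichment_score(ranked, members, weight=weight)
        # uniform same-size draws without replacement, one row per permutation
        keys = rng.random((n_perm, n))
        positions = np.argpartition(keys, k, axis=1)[:, :k]
        positions.sort(axis=1)
        null_es = _es_from_positions(positions, abs_w, n)
        null_by_set[name] = null_es
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        r = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p_nom = (r + 1) / (n_same + 1)
        mean_same = np.abs(null_es[same_sign]).mean() if n_same else np.nan
        flags = []
        if n_same == 0 or not np.isfinite(mean_same) or mean_same == 0:
            nes = np.nan
            flags.append("nes_undefined")
        else:
            nes = es / mean_same
        le_sorted = sorted(leading, key=lambda f: rank_of[f])
        rows.append(
            {
                "set_name": name,
                "set_size_used": k,
                "es": es,
                "nes": nes,
                "p_nominal": p_nom,
                "fdr_q": np.nan,
                "leading_edge": ",".join(le_sorted),
                "flags": ";".join(flags),
            }
        )
    result = pd.DataFrame(rows)
    result["fdr_q"] = _pooled_fdr(result, null_by_set)
    return result


def _pooled_fdr(result: pd.DataFrame, null_by_set: dict[str, np.ndarray]) -> np.ndarray:
    """GSEA pooled-null FDR: normalise every null ES by its set's same-sign
    null mean, pool across sets within each sign class, and compare tail
    fractions of null vs observed NES. Monotone in |NES| by cumulative max
    of the raw ratio within each sign class, clipped to [0, 1]."""
    pooled_pos: list[np.ndarray] = []
    pooled_neg: list[np.ndarray] = []
    for name, null_es in null_by_set.items():
        pos = null_es[null_es >= 0]
        neg = null_es[null_es < 0]
        if pos.size and pos.mean() > 0:
            pooled_pos.append(pos / pos.mean())
        if neg.size and np.abs(neg).mean() > 0:
            pooled_neg.append(neg / np.abs(neg).mean())
    pool_pos = np.concatenate(pooled_pos) if pooled_pos else np.array([])
    pool_neg = np.concatenate(pooled_neg) if pooled_neg else np.array([])

    nes = result["nes"].to_numpy()
    q = np.full(len(result), np.nan)
    obs_pos = nes[np.isfinite(nes) & (nes >= 0)]
    obs_neg = nes[np.isfinite(nes) & (nes < 0)]
    for i, v in enumerate(nes):
        if not np.isfinite(v):
            continue
        if v >= 0:
            if pool_pos.size == 0 or obs_pos.size == 0:
                q[i] = 1.0
                continue
            null_frac = (pool_pos >= v).mean()
            obs_frac = max((obs_pos >= v).mean(), 1.0 / obs_pos.size)
        else:
            if pool_neg.size == 0 or obs_neg.size == 0:
                q[i] = 1.0
                continue
            null_frac = (pool_neg <= v).mean()
            obs_frac = max((obs_neg <= v).mean(), 1.0 / obs_neg.size)
        q[i] = null_frac / obs_frac
    # step-up: q monotone non-increasing in |NES| within each sign class,
    # taking for each set the smallest raw ratio among sets no more extreme
    for sign_mask in (np.isfinite(nes) & (nes >= 0), np.isfinite(nes) & (nes < 0)):
        idx = np.nonzero(sign_mask)[0]
        if idx.size == 0:
            continue
        order = idx[np.argsort(np.abs(nes[idx]), kind="mergesort")]
        running = np.inf
        for i in order:
            running = min(running, q[i])
            q[i] = running
    return np.clip(q, 0.0, 1.0)


def nes_ratio(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Per-set NES ratio a/b (e.g. post-prime D2 over post-boost D58).

    Sets whose NES signs disagree, or whose denominator is numerically
    zero or undefined, are flagged and excluded from the ratio rather than
    producing misleading numbers.
    """
    a = results_a.set_index("set_name")
    b = results_b.set_index("set_name")
    shared = [s for s in a.index if s in b.index]
    if not shared:
        raise ValidationError("no shared set names between the two result tables")
    rows = []
    for name in shared:
        nes_a = float(a.loc[name, "nes"])
        nes_b = float(b.loc[name, "nes"])
        flag = ""
        ratio = np.nan
        if not (np.isfinite(nes_a) and np.isfinite(nes_b)):
            flag = "nes_undefined"
        elif abs(nes_b) < 1e-9:
            flag = "denominator_zero"
        elif nes_a * nes_b < 0:
            flag = "opposite_sign"
        else:
            ratio = nes_a / nes_b
        rows.append(
            {"set_name": name, "nes_a": nes_a, "nes_b": nes_b, "ratio": ratio, "flag": flag}
        )
    return pd.DataFrame(rows)


def write_rnk(ranked: RankedList, path) -> None:
    """Two-column feature/statistic file consumed by desktop GSEA tools."""
    with open(path, "w") as fh:
        for f, s in zip(ranked.feature_ids, ranked.statistics):
            fh.write(f"{f}\t{float(s)!r}\n")


def read_rnk(path) -> RankedList:
    feats: list[str] = []
    stats_: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f, s = line.split("\t")
            feats.append(f)
            stats_.append(float(s))
    return RankedList(feats, np.array(stats_))
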