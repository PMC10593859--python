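"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives a quantity by direct enumeration or numerical
inversion, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, stats


def brute_force_es(
    ordered_stats: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Enrichment score by an explicit loop over the ranked list."""
    n = len(ordered_stats)
    n_hits = int(hit_mask.sum())
    assert 0 < n_hits < n
    denom = sum(abs(ordered_stats[i]) ** weight for i in range(n) if hit_mask[i])
    if denom == 0:
        denom = float(n_hits)
        hit_step = [1.0 if hit_mask[i] else 0.0 for i in range(n)]
    else:
        hit_step = [
            abs(ordered_stats[i]) ** weight if hit_mask[i] else 0.0 for i in range(n)
        ]
    running = 0.0
    peak = -math.inf
    trough = math.inf
    for i in range(n):
        if hit_mask[i]:
            running += hit_step[i] / denom
        else:
            running -= 1.0 / (n - n_hits)
        peak = max(peak, running)
        trough = min(trough, running)
    # equal-magnitude extrema report the positive one (documented tie-break)
    return peak if peak >= -trough else trough


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Quadratic-time Benjamini-Hochberg step-up."""
    m = len(p)
    adjusted = np.empty(m)
    for i in range(m):
        rank_i = sum(1 for q in p if q <= p[i])
        candidates = []
        for j in range(m):
            if p[j] >= p[i]:
                rank_j = sum(1 for q in p if q <= p[j])
                candidates.append(p[j] * m / rank_j)
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def enumerate_wilcoxon_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = diffs[diffs != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    total = len(w_all)
    p_low = (w_all <= w_obs + 1e-9).sum() / total
    p_high = (w_all >= w_obs - 1e-9).sum() / total
    return float(w_obs), min(1.0, 2.0 * min(p_low, p_high))


def enumerate_hypergeom_p(universe: set, selected: set, members: set) -> float:
    """P(overlap >= observed) by enumerating all same-size selections."""
    items = sorted(universe)
    observed = len(selected & members)
    count = total = 0
    for combo in itertools.combinations(items, len(selected)):
        total += 1
        if len(set(combo) & members) >= observed:
            count += 1
    return count / total


def poisson_ci_bisection(events: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact Poisson CI on the count scale by inverting the CDF numerically."""
    if events == 0:
        lower = 0.0
    else:
        lower = optimize.brentq(
            lambda lam: stats.poisson.sf(events - 1, lam) - alpha / 2,
            1e-12, 10 * events + 50,
        )
    upper = optimize.brentq(
        lambda lam: stats.poisson.cdf(events, lam) - alpha / 2,
        1e-12, 10 * events + 100,
    )
    return lower, upper


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Direct evaluation of the Welch t statistic."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    return (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
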