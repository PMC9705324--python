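"""Independent brute-force oracles used only by the tests.

Everything here is written naively (pure-Python loops, exhaustive
enumeration) and never imports the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def running_es_naive(stats, member_mask, exponent=1.0):
    """Prefix-enumeration running enrichment score.

    Walks the ranked list once, accumulating hit increments |s|^p / sum and
    miss decrements 1/(N-k); returns (es, profile, peak) with a 1-based peak
    at the first position of maximum absolute deviation.
    """
    stats = [float(s) for s in stats]
    member_mask = [bool(m) for m in member_mask]
    n = len(stats)
    k = sum(member_mask)
    total = sum(abs(s) ** exponent for s, m in zip(stats, member_mask) if m)
    weights = [abs(s) ** exponent for s in stats]
    if total == 0:
        weights = [1.0] * n
        total = float(k)
    miss = 1.0 / (n - k) if n > k else 0.0
    running, profile = 0.0, []
    for s, m, w in zip(stats, member_mask, weights):
        running += (w / total) if m else -miss
        profile.append(running)
    peak, best = 0, abs(profile[0])
    for i, value in enumerate(profile):
        if abs(value) > best:
            peak, best = i, abs(value)
    return profile[peak], profile, peak + 1


def leading_edge_naive(genes, member_mask, es, peak):
    """Members before (positive ES) or after (negative ES) the 1-based peak."""
    if es == 0:
        return ()
    out = []
    for position, (gene, member) in enumerate(zip(genes, member_mask), start=1):
        if member and ((es > 0 and position <= peak) or (es < 0 and position >= peak)):
            out.append(gene)
    return tuple(out)


def _u_statistic(x, y):
    return float(sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y))


def mannwhitney_enum(x, y):
    """Exhaustive two-sided Mann-Whitney: (U of x, doubled one-sided p)."""
    x, y = list(map(float, x)), list(map(float, y))
    pool = x + y
    n = len(x)
    observed = _u_statistic(x, y)
    null = []
    for combo in itertools.combinations(range(len(pool)), n):
        rest = [i for i in range(len(pool)) if i not in set(combo)]
        null.append(_u_statistic([pool[i] for i in combo], [pool[i] for i in rest]))
    null = np.asarray(null)
    p_greater = float((null >= observed).mean())
    p_less = float((null <= observed).mean())
    return observed, min(1.0, 2.0 * min(p_greater, p_less))


def signed_rank_enum(deltas):
    """Exhaustive two-sided signed-rank over all sign assignments.

    Zero differences are dropped before ranking; ties in |delta| take
    midranks. Returns (W+ of the observed signs, doubled one-sided p).
    """
    d = np.asarray([float(v) for v in deltas if v != 0])
    ranks = rankdata(np.abs(d))
    observed = float(ranks[d > 0].sum())
    null = []
    for signs in itertools.product((1.0, -1.0), repeat=len(d)):
        signs = np.asarray(signs)
        null.append(float(ranks[signs > 0].sum()))
    null = np.asarray(null)
    p_greater = float((null >= observed).mean())
    p_less = float((null <= observed).mean())
    return observed, min(1.0, 2.0 * min(p_greater, p_less))


def kruskal_by_formula(groups):
    """Tie-corrected Kruskal-Wallis H computed from the textbook rank formula."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = rankdata(pooled)
    n_total = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n_total + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    return h / correction
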