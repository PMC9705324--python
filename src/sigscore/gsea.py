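"""Weighted Kolmogorov-Smirnov gene-set enrichment with permutation inference.

The running enrichment score walks the ranked gene list top to bottom: hitting
a set member increments the running sum by ``|stat|^exponent`` normalized by
the sum of weights over all hits, missing decrements it by ``1/(N - n_hits)``.
The enrichment score (ES) is the running sum at its maximum absolute
deviation; the leading edge contains the set members at or before that peak
(at or after it for negative ES).

Significance uses repeated permutation (default 1000 permutations, add-one
estimator so p >= 1/(n_perm + 1)):

* ``gene_label`` scheme — set membership is reassigned to random rank
  positions (the fast, preranked-style null);
* ``phenotype`` scheme — sample group labels are shuffled and the ranking
  recomputed (requires the expression matrix).

NES divides the observed ES by the mean |ES| of the same-sign permutations.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import EnrichmentResult, ExpressionMatrix, GeneSet, GeneSetCollection, RankedList
from .exceptions import EmptyIntersectionError, GroupingError

logger = logging.getLogger(__name__)

__all__ = [
    "rank_genes",
    "running_enrichment",
    "leading_edge",
    "permutation_test",
    "batch_gsea",
]

Metric = Literal["signal_to_noise", "t_statistic", "precomputed"]
Scheme = Literal["gene_label", "phenotype"]

#: Relative SD floor used by the signal-to-noise and t metrics: the group SD is
#: raised to at least 0.2 * |group mean| (0.2 absolute when the mean is zero),
#: which keeps near-constant genes from dominating the ranking.
SD_FLOOR_FRACTION = 0.2


def _group_moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    floor = SD_FLOOR_FRACTION * np.abs(mean)
    floor[floor == 0] = SD_FLOOR_FRACTION
    return mean, np.maximum(sd, floor)


def rank_genes(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    metric: Metric = "signal_to_noise",
    *,
    case: str = "case",
    control: str = "control",
    stats: pd.Series | None = None,
) -> RankedList:
    """Rank all genes by a case-vs-control statistic, best first.

    ``signal_to_noise`` is ``(mean_case - mean_control) / (sd_case +
    sd_control)`` with the SD floor above; ``t_statistic`` is the Welch t with
    the same floor; ``precomputed`` ranks a caller-supplied per-gene statistic
    (``stats``). Ties are broken by ascending gene id.
    """
    if metric == "precomputed":
        if stats is None:
            raise GroupingError("precomputed metric requires a stats Series")
        values = stats.reindex(matrix.genes) if matrix is not None else stats
        genes = np.asarray(values.index, dtype=object)
        stat = values.to_numpy(dtype=float)
    else:
        groups = annotations.loc[annotations.index.intersection(matrix.samples), "group"]
        case_ids = groups.index[groups == case]
        ctrl_ids = groups.index[groups == control]
        if len(case_ids) == 0 or len(ctrl_ids) == 0:
            raise GroupingError(
                f"need both groups {case!r} and {control!r}; "
                f"got {len(case_ids)} cases and {len(ctrl_ids)} controls"
            )
        if len(case_ids) < 2 or len(ctrl_ids) < 2:
            raise GroupingError("variance-based metrics need >= 2 samples per group")
        x1 = matrix.data[case_ids].to_numpy(dtype=float)
        x0 = matrix.data[ctrl_ids].to_numpy(dtype=float)
        m1, s1 = _group_moments(x1)
        m0, s0 = _group_moments(x0)
        if metric == "signal_to_noise":
            stat = (m1 - m0) / (s1 + s0)
        elif metric == "t_statistic":
            stat = (m1 - m0) / np.sqrt(s1**2 / x1.shape[1] + s0**2 / x0.shape[1])
        else:
            raise GroupingError(f"unknown metric {metric!r}")
        genes = np.asarray(matrix.genes, dtype=object)

    order = np.lexsort((genes, -stat))
    return RankedList(genes[order], stat[order], metric=metric)


def _intersect(ranked: RankedList, gene_set: GeneSet) -> np.ndarray:
    members = set(gene_set.genes)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    if not hits.any():
        raise EmptyIntersectionError(
            f"gene set {gene_set.name!r} shares no genes with the ranked list"
        )
    return hits


def _weights(stats: np.ndarray, hits: np.ndarray, exponent: float) -> tuple[np.ndarray, float]:
    w = np.abs(stats) ** exponent
    total = w[hits].sum()
    if total == 0.0:  # all hit statistics are exactly zero: fall back to equal weights
        logger.warning("all hit weights are zero; falling back to unweighted increments")
        w = np.ones_like(w)
        total = float(hits.sum())
    return w, float(total)


def running_enrichment(
    ranked: RankedList, gene_set: GeneSet, exponent: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Running enrichment score for one gene set.

    Returns ``(es, profile, peak)`` where ``profile`` is the running sum at
    every rank position and ``peak`` is the 1-based position of its maximum
    absolute deviation (first such position on exact ties). ``|es| <= 1``.
    """
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0, got {exponent}")
    hits = _intersect(ranked, gene_set)
    n, k = len(ranked), int(hits.sum())
    w, total = _weights(ranked.stats, hits, exponent)
    miss = 1.0 / (n - k) if n > k else 0.0
    steps = np.where(hits, w / total, -miss)
    profile = np.cumsum(steps)
    peak = int(np.argmax(np.abs(profile)))
    return float(profile[peak]), profile, peak + 1


def leading_edge(
    ranked: RankedList, gene_set: GeneSet, es: float, peak: int
) -> tuple[str, ...]:
    """Set members driving the enrichment peak, in rank order.

    For positive ES these are the members at 1-based positions ``<= peak``;
    for negative ES the members at positions ``>= peak``. An ES of exactly
    zero yields an empty leading edge (logged).
    """
    if es == 0.0:
        logger.warning("ES is exactly 0 for set %r; leading edge is empty", gene_set.name)
        return ()
    hits = _intersect(ranked, gene_set)
    positions = np.flatnonzero(hits) + 1  # 1-based
    selected = positions <= peak if es > 0 else positions >= peak
    return tuple(ranked.genes[positions[selected] - 1])


def _null_es_gene_label(
    stats: np.ndarray, k: int, exponent: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized ES for ``n_perm`` random size-``k`` memberships.

    Only the running sum immediately after each hit (candidate maxima) and
    immediately before each hit (candidate minima) need to be evaluated: the
    running sum decreases between hits and returns to 0 at the end of the
    list, so the extreme deviations always occur at those positions. On an
    exact |max| == |min| tie the positive deviation is reported.
    """
    n = len(stats)
    w_all = np.abs(stats) ** exponent
    pos = np.argsort(rng.random((n_perm, n)), axis=1, kind="stable")[:, :k]
    pos.sort(axis=1)
    w = w_all[pos]
    totals = w.sum(axis=1, keepdims=True)
    zero_rows = totals[:, 0] == 0.0
    if zero_rows.any():
        w[zero_rows] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1)
    miss = 1.0 / (n - k) if n > k else 0.0
    misses_before = (pos - np.arange(k)) * miss
    after = cumw / totals - misses_before
    before = (cumw - w) / totals - misses_before
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def permutation_test(
    data: RankedList | ExpressionMatrix,
    gene_set: GeneSet,
    n_perm: int = 1000,
    scheme: Scheme = "gene_label",
    seed: int = 0,
    *,
    annotations: pd.DataFrame | None = None,
    metric: Metric = "signal_to_noise",
    exponent: float = 1.0,
) -> EnrichmentResult:
    """ES, NES, permutation p-value and leading edge for one gene set.

    ``p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm)`` — the two-sided
    add-one estimator (so p >= 1/(n_perm + 1), and an observed ES beyond
    every permutation attains exactly 1/(n_perm + 1)); ``NES = ES /
    mean(|ES_perm|)`` over same-sign permutations, NaN if none exist.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if scheme not in ("gene_label", "phenotype"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    if isinstance(data, RankedList):
        if scheme == "phenotype":
            raise GroupingError("phenotype permutation needs an expression matrix, not a ranked list")
        ranked = data
    else:
        if annotations is None:
            raise GroupingError("an expression matrix requires sample annotations")
        ranked = rank_genes(data, annotations, metric)

    es, profile, peak = running_enrichment(ranked, gene_set, exponent)
    k = int(_intersect(ranked, gene_set).sum())
    rng = np.random.default_rng(seed)

    if scheme == "gene_label":
        null_es = _null_es_gene_label(ranked.stats, k, exponent, n_perm, rng)
    else:
        groups = annotations["group"].loc[annotations.index.intersection(data.samples)]
        null_es = np.empty(n_perm)
        shuffled = annotations.loc[groups.index].copy()
        for i in range(n_perm):
            shuffled["group"] = rng.permutation(groups.to_numpy())
            perm_ranked = rank_genes(data, shuffled, metric)
            null_es[i] = running_enrichment(perm_ranked, gene_set, exponent)[0]

    if es == 0.0:
        pvalue, nes = 1.0, 0.0
    else:
        # two-sided magnitude comparison: |ES_obs| and |ES_perm| are iid under
        # the null, so this add-one estimator is calibrated for any null shape
        same_sign = null_es > 0 if es > 0 else null_es < 0
        pvalue = (1 + int((np.abs(null_es) >= abs(es)).sum())) / (1 + n_perm)
        if same_sign.any():
            nes = es / float(np.abs(null_es[same_sign]).mean())
        else:
            logger.warning("no same-sign permutation ES for %r; NES undefined", gene_set.name)
            nes = float("nan")

    return EnrichmentResult(
        set_name=gene_set.name,
        size=k,
        es=es,
        peak=peak,
        leading_edge=leading_edge(ranked, gene_set, es, peak),
        profile=profile,
        nes=nes,
        pvalue=pvalue,
        scheme=scheme,
        n_perm=n_perm,
        seed=seed,
    )


def batch_gsea(
    data: RankedList | ExpressionMatrix,
    collection: GeneSetCollection | Sequence[GeneSet],
    n_perm: int = 1000,
    scheme: Scheme = "gene_label",
    seed: int = 0,
    *,
    annotations: pd.DataFrame | None = None,
    metric: Metric = "signal_to_noise",
    exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Run the permutation test over a collection, with BH adjustment.

    Sets are filtered to ``min_size <= |set ∩ ranked genes| <= max_size``
    before testing; per-set permutation streams are spawned deterministically
    from ``seed``. Returns one row per retained set with columns
    ``set, size, es, nes, pvalue, qvalue, peak, leading_edge``; the raw
    permutation p is reported alongside the BH q, never replaced by it.
    """
    sets = list(collection)
    if not sets:
        raise EmptyIntersectionError("empty gene-set collection")

    if isinstance(data, RankedList):
        ranked = data
    else:
        if annotations is None:
            raise GroupingError("an expression matrix requires sample annotations")
        ranked = rank_genes(data, annotations, metric)
    present = set(ranked.genes.tolist())

    retained, reasons = [], []
    for gs in sets:
        overlap = len(present.intersection(gs.genes))
        if overlap < min_size:
            reasons.append(f"{gs.name}: {overlap} genes after intersection (< {min_size})")
        elif overlap > max_size:
            reasons.append(f"{gs.name}: {overlap} genes after intersection (> {max_size})")
        else:
            retained.append(gs)
    if not retained:
        raise EmptyIntersectionError(
            "all gene sets filtered out:\n  " + "\n  ".join(reasons)
        )
    for reason in reasons:
        logger.info("filtered gene set: %s", reason)

    child_seeds = np.random.SeedSequence(seed).generate_state(len(retained))
    rows = []
    for gs, child in zip(retained, child_seeds):
        res = permutation_test(
            data if scheme == "phenotype" else ranked,
            gs,
            n_perm=n_perm,
            scheme=scheme,
            seed=int(child % (2**31)),
            annotations=annotations,
            metric=metric,
            exponent=exponent,
        )
        rows.append(
            {
                "set": res.set_name,
                "size": res.size,
                "es": res.es,
                "nes": res.nes,
                "pvalue": res.pvalue,
                "peak": res.peak,
                "leading_edge": res.leading_edge,
            }
        )
    table = pd.DataFrame(rows)
    table.insert(5, "qvalue", multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1])
    return table
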