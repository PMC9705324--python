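"""Control-referenced signature scores and related normalizations.

Three scores live here, all referenced to a control population:

* the composite signature score — per sample, the sum over signature genes of
  the number of control SDs the sample lies from the control mean (so the
  control-group mean score is 0 by construction and a case shifted by one
  control SD on each of k genes scores ~k);
* percent-of-control normalization — each sample's linear-scale value for a
  gene expressed as a percentage of the within-study control mean, which makes
  studies with arbitrary multiplicative scale poolable;
* the single-cell module score — per cell, the mean normalized expression of
  a gene set minus the mean over expression-matched control genes drawn from
  average-expression bins.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .containers import (
    EnrichmentResult,
    ExpressionMatrix,
    GeneSet,
    SignatureScores,
)
from .exceptions import EmptyIntersectionError, GroupingError
from .gsea import Metric, Scheme, permutation_test

logger = logging.getLogger(__name__)

__all__ = [
    "gene_zscores",
    "signature_score",
    "end_to_end_score",
    "cross_study_percent",
    "normalize_cells",
    "sc_module_score",
]


def gene_zscores(
    matrix: ExpressionMatrix,
    control_ids: Sequence[str],
    genes: Sequence[str],
) -> tuple[pd.DataFrame, tuple[tuple[str, str], ...]]:
    """Standardize genes against the control group.

    ``z(g, s) = (x(g, s) - mean_controls(g)) / sd_controls(g)`` with the n-1
    SD. Genes absent from the matrix or with zero control SD are excluded and
    reported in the second return value as (gene, reason) pairs, not raised.
    """
    control_ids = [s for s in control_ids if s in matrix.samples]
    if len(control_ids) < 2:
        raise GroupingError(f"need >= 2 control samples, got {len(control_ids)}")

    excluded: list[tuple[str, str]] = []
    retained: list[str] = []
    for gene in genes:
        if gene not in matrix.genes:
            excluded.append((gene, "absent from matrix"))
        else:
            retained.append(gene)

    if retained:
        sub = matrix.data.loc[retained]
        mean = sub[control_ids].mean(axis=1)
        sd = sub[control_ids].std(axis=1, ddof=1)
        zero_sd = sd == 0
        for gene in sub.index[zero_sd]:
            excluded.append((gene, "zero control SD"))
        sub = sub.loc[~zero_sd]
        z = sub.sub(mean[~zero_sd], axis=0).div(sd[~zero_sd], axis=0)
    else:
        z = pd.DataFrame(columns=matrix.samples)

    if z.empty:
        raise EmptyIntersectionError(
            f"no scorable genes: all {len(list(genes))} excluded "
            f"({'; '.join(f'{g}: {r}' for g, r in excluded[:5])})"
        )
    for gene, reason in excluded:
        logger.info("excluded gene %s from z-scoring: %s", gene, reason)
    return z, tuple(excluded)


def signature_score(
    matrix: ExpressionMatrix,
    control_ids: Sequence[str],
    signature_genes: Sequence[str],
) -> SignatureScores:
    """Composite score: per-sample sum of control-referenced z-scores.

    Scores every sample in the matrix (controls included; their mean score is
    0 up to floating error). Missing or zero-SD genes are dropped and the
    number of genes actually summed recorded per sample.
    """
    z, excluded = gene_zscores(matrix, control_ids, signature_genes)
    table = pd.DataFrame(
        {"score": z.sum(axis=0), "n_genes_used": z.shape[0]},
        index=pd.Index(matrix.samples, name="sample_id"),
    )
    return SignatureScores(table=table, genes_used=tuple(z.index), excluded=excluded)


def end_to_end_score(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    scheme: Scheme = "gene_label",
    metric: Metric = "signal_to_noise",
    exponent: float = 1.0,
    case: str = "case",
    control: str = "control",
) -> tuple[EnrichmentResult, SignatureScores]:
    """GSEA on case-vs-control, then score all samples on the leading edge.

    Runs the permutation test for ``gene_set`` using the samples annotated as
    case or control, extracts the leading-edge genes, and computes the
    composite signature score for every column of the matrix (samples outside
    the two groups — e.g. later timepoints — are passed through and scored
    against the same controls). A non-positive ES is allowed with a warning:
    the leading edge then comes from the negative side of the profile.
    """
    groups = annotations.loc[annotations.index.intersection(matrix.samples), "group"]
    used = groups[groups.isin([case, control])]
    baseline = ExpressionMatrix(matrix.data[used.index], scale=matrix.scale)
    result = permutation_test(
        baseline,
        gene_set,
        n_perm=n_perm,
        scheme=scheme,
        seed=seed,
        annotations=annotations.loc[used.index],
        metric=metric,
        exponent=exponent,
    )
    if result.es <= 0:
        logger.warning(
            "ES for %r is non-positive (%.4f); leading edge taken from the negative side",
            gene_set.name,
            result.es,
        )
    if not result.leading_edge:
        raise EmptyIntersectionError(f"empty leading edge for set {gene_set.name!r}")
    control_ids = used.index[used == control]
    scores = signature_score(matrix, list(control_ids), list(result.leading_edge))
    return result, scores


def cross_study_percent(
    studies: Sequence[tuple[str, ExpressionMatrix, pd.DataFrame]],
    gene: str,
    *,
    control: str = "control",
) -> pd.DataFrame:
    """Percent-of-control normalization pooled across studies.

    For each study, every sample's linear-scale value of ``gene`` is expressed
    as ``100 * x / mean(controls in the same study)``, then studies are
    concatenated — the within-study control mean is exactly 100 by
    construction, so studies with arbitrary multiplicative scale pool. A study
    is dropped (and logged in the frame's ``attrs["dropped_studies"]``) when
    the gene is missing, no controls exist, or the control mean is <= 0.
    """
    frames = []
    dropped: list[tuple[str, str]] = []
    for study_id, matrix, annotations in studies:
        if gene not in matrix.genes:
            dropped.append((study_id, f"gene {gene!r} absent"))
            continue
        groups = annotations.loc[annotations.index.intersection(matrix.samples), "group"]
        ctrl_ids = groups.index[groups == control]
        if len(ctrl_ids) == 0:
            dropped.append((study_id, "no control samples"))
            continue
        linear = matrix.to_linear().loc[gene]
        ctrl_mean = float(linear[ctrl_ids].mean())
        if ctrl_mean <= 0:
            dropped.append((study_id, f"non-positive control mean ({ctrl_mean:g})"))
            continue
        frames.append(
            pd.DataFrame(
                {
                    "study_id": study_id,
                    "sample_id": groups.index,
                    "group": groups.to_numpy(),
                    "gene": gene,
                    "percent_of_control": 100.0 * linear[groups.index].to_numpy() / ctrl_mean,
                }
            )
        )
    for study_id, reason in dropped:
        logger.warning("dropped study %s from percent-of-control pooling: %s", study_id, reason)
    if not frames:
        raise GroupingError(f"no study usable for gene {gene!r}: {dropped}")
    table = pd.concat(frames, ignore_index=True)
    table.attrs["dropped_studies"] = dropped
    return table


def normalize_cells(adata: AnnData, target_sum: float = 1e4) -> np.ndarray:
    """Per-cell depth normalization to ``target_sum`` followed by log1p.

    Returns a dense cells x genes float array; cells with zero total count are
    left at zero.
    """
    counts = adata.X
    if sparse.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * target_sum)


def sc_module_score(
    adata: AnnData,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl_per_bin: int = 100,
    seed: int = 0,
    *,
    target_sum: float = 1e4,
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Module score with expression-matched binned control genes.

    Counts are depth-normalized and log1p-transformed, genes are assigned to
    ``n_bins`` equal-frequency bins of average normalized expression across
    cells, and for each set gene ``n_ctrl_per_bin`` control genes are sampled
    without replacement from its bin (set genes excluded; if a bin holds fewer
    candidates all are taken, logged). The score per cell is the mean over set
    genes minus the average of the per-set-gene matched control means —
    keeping one control draw per set gene preserves the expression matching
    even when bins are small — so a random gene set scores ~0 in every cell
    population.

    Returns a frame indexed by cell id with columns ``cluster`` (NaN when the
    annotation is absent) and ``score``.
    """
    genes = np.asarray(adata.var_names, dtype=object)
    members = [g for g in gene_set.genes if g in set(genes.tolist())]
    if not members:
        raise EmptyIntersectionError(
            f"gene set {gene_set.name!r} shares no genes with the dataset"
        )
    if len(members) < len(gene_set):
        logger.info(
            "%d/%d set genes present in the dataset", len(members), len(gene_set)
        )

    data = normalize_cells(adata, target_sum)
    avg = data.mean(axis=0)
    # equal-frequency bins over average expression; ties broken by gene order
    order = np.argsort(avg, kind="stable")
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(len(genes))
    bins = np.minimum(ranks * n_bins // len(genes), n_bins - 1)

    gene_index = {g: i for i, g in enumerate(genes)}
    member_idx = np.array([gene_index[g] for g in members])
    member_set = set(member_idx.tolist())

    # one matched control draw per set gene (possibly overlapping across set
    # genes) so expression matching holds even when a bin is nearly exhausted
    rng = np.random.default_rng(seed)
    bin_candidates = {
        b: np.array([i for i in np.flatnonzero(bins == b) if i not in member_set])
        for b in sorted(set(bins[member_idx].tolist()))
    }
    exhausted = 0
    control_reference = np.zeros(data.shape[0])
    for idx in member_idx:
        candidates = bin_candidates[bins[idx]]
        if len(candidates) == 0:
            raise EmptyIntersectionError(
                f"no control candidates share an expression bin with gene {genes[idx]!r}"
            )
        if len(candidates) <= n_ctrl_per_bin:
            exhausted += len(candidates) < n_ctrl_per_bin
            chosen = candidates
        else:
            chosen = rng.choice(candidates, size=n_ctrl_per_bin, replace=False)
        control_reference += data[:, chosen].mean(axis=1)
    control_reference /= len(member_idx)
    if exhausted:
        logger.info(
            "%d/%d set genes had fewer than %d bin candidates; used all available",
            exhausted,
            len(member_idx),
            n_ctrl_per_bin,
        )

    score = data[:, member_idx].mean(axis=1) - control_reference
    cluster = (
        adata.obs[cluster_key]
        if cluster_key in adata.obs.columns
        else pd.Series(np.nan, index=adata.obs_names)
    )
    return pd.DataFrame(
        {"cluster": np.asarray(cluster), "score": score},
        index=pd.Index(adata.obs_names, name="cell_id"),
    )
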