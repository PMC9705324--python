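"""Nonparametric group comparisons and response stratification.

All tests are two-sided. Small-sample rank tests (both groups of size <= 8
for Mann-Whitney, <= 13 pairs for the signed-rank) use full permutation
enumeration so p-values are exact even under ties; larger samples use the
tie-corrected normal approximation. Single-cell differential expression is a
per-gene Wilcoxon rank-sum on depth-normalized log1p values with Bonferroni
correction over the genes actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats as sps

from .containers import RESPONSE_GRADES, SignatureScores
from .exceptions import GroupingError, StratificationError
from .scoring import normalize_cells

logger = logging.getLogger(__name__)

__all__ = [
    "compare_two_groups",
    "differential_expression",
    "paired_change",
    "stratify_by_response",
    "PairedChange",
    "StratifiedChange",
]

#: Exact enumeration for the two-sample test needs C(n+m, n) resamples;
#: C(16, 8) = 12870 covers groups up to 8 + 8.
_EXACT_TWO_SAMPLE_RESAMPLES = 13000
#: Exact sign-flip enumeration covers up to 2^13 = 8192 pairs' assignments.
_EXACT_PAIRED_N = 13


def compare_two_groups(values, labels) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between the two label groups.

    Returns ``(U, p)`` where U counts pairs in which the *first* group (first
    label in order of appearance) exceeds the second. Exact permutation
    enumeration when both groups have <= 8 observations, tie-corrected normal
    approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise GroupingError(f"need exactly two groups, got {list(uniq)}")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) == 0 or len(y) == 0:
        raise GroupingError("one group is empty")
    return mannwhitney(x, y)


def mannwhitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of ``x`` vs ``y`` (see compare_two_groups)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 2:
        # scipy's permutation path needs >= 2 per group; the classical exact
        # U distribution covers the singleton case
        method = "exact"
    elif max(len(x), len(y)) <= 8:
        method = sps.PermutationMethod(n_resamples=_EXACT_TWO_SAMPLE_RESAMPLES)
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PairedChange:
    """Per-patient pre/post score change with a signed-rank test.

    ``table`` has one row per retained patient (baseline score, day-3 score,
    delta, grade); ``all_zero`` flags the degenerate case where every delta is
    exactly zero (p reported as 1).
    """

    table: pd.DataFrame
    statistic: float
    pvalue: float
    n_dropped: int = 0
    all_zero: bool = False


def paired_change(scores: SignatureScores | pd.DataFrame, response: pd.DataFrame) -> PairedChange:
    """Day-3 minus baseline score per patient, with Wilcoxon signed-rank p.

    Patients whose baseline or day-3 sample is missing from the score table
    are dropped (logged). Zero differences are discarded before ranking
    (standard signed-rank convention); if every difference is zero the test is
    degenerate and p = 1 is reported with ``all_zero=True``.
    """
    score_table = scores.table if isinstance(scores, SignatureScores) else scores
    score = score_table["score"]

    rows, dropped = [], 0
    for rec in response.itertuples(index=False):
        if rec.baseline_sample not in score.index or rec.day3_sample not in score.index:
            dropped += 1
            logger.warning("patient %s dropped: sample missing from score table", rec.patient_id)
            continue
        pre = float(score[rec.baseline_sample])
        post = float(score[rec.day3_sample])
        rows.append((rec.patient_id, pre, post, post - pre, rec.grade))
    if not rows:
        raise GroupingError("no patient has both samples scored")
    table = pd.DataFrame(
        rows, columns=["patient_id", "baseline_score", "day3_score", "delta", "grade"]
    ).set_index("patient_id")
    table["grade"] = pd.Categorical(table["grade"], categories=RESPONSE_GRADES, ordered=True)

    deltas = table["delta"].to_numpy()
    nonzero = deltas[deltas != 0]
    if len(nonzero) == 0:
        logger.warning("all paired differences are zero; signed-rank test degenerate")
        return PairedChange(table, statistic=0.0, pvalue=1.0, n_dropped=dropped, all_zero=True)
    if len(deltas) != len(nonzero):
        logger.info("dropped %d zero differences before ranking", len(deltas) - len(nonzero))
    if len(nonzero) <= _EXACT_PAIRED_N:
        method = sps.PermutationMethod(n_resamples=2**_EXACT_PAIRED_N)
    else:
        method = "approx"
    res = sps.wilcoxon(nonzero, alternative="two-sided", method=method)
    return PairedChange(table, float(res.statistic), float(res.pvalue), n_dropped=dropped)


@dataclass
class StratifiedChange:
    """Score change stratified by ordinal response grade.

    ``summary`` holds n / median / quartiles per grade in fixed grade order;
    ``monotone_trend`` is True when per-grade medians are non-increasing from
    NR to ACR100 (the direction expected when better responders lose more of
    the signature).
    """

    summary: pd.DataFrame
    statistic: float
    pvalue: float
    monotone_trend: bool


def stratify_by_response(deltas: pd.DataFrame | PairedChange, min_per_grade: int = 2) -> StratifiedChange:
    """Kruskal-Wallis comparison of per-patient deltas across response grades.

    ``deltas`` needs columns ``delta`` and ``grade`` (a :class:`PairedChange`
    is accepted directly). Grades absent from the data are omitted; at least
    two grades with ``min_per_grade`` patients each are required. The omnibus
    statistic is the tie-corrected Kruskal-Wallis H over all represented
    grades.
    """
    table = deltas.table if isinstance(deltas, PairedChange) else deltas
    groups = {
        grade: table.loc[table["grade"] == grade, "delta"].to_numpy()
        for grade in RESPONSE_GRADES
        if (table["grade"] == grade).any()
    }
    usable = [g for g, v in groups.items() if len(v) >= min_per_grade]
    if len(usable) < 2:
        raise StratificationError(
            f"need >= 2 grades with >= {min_per_grade} patients; got {usable}"
        )

    summary = pd.DataFrame(
        {
            "n": [len(groups[g]) for g in groups],
            "median_delta": [float(np.median(groups[g])) for g in groups],
            "q1": [float(np.percentile(groups[g], 25)) for g in groups],
            "q3": [float(np.percentile(groups[g], 75)) for g in groups],
        },
        index=pd.Index(list(groups), name="grade"),
    )
    stat, pvalue = sps.kruskal(*groups.values())
    medians = summary["median_delta"].to_numpy()
    monotone = bool(np.all(np.diff(medians) <= 0))
    return StratifiedChange(summary, float(stat), float(pvalue), monotone)


def differential_expression(
    cells: AnnData,
    group_a: str,
    group_b: str,
    *,
    labels: str | pd.Series = "cluster",
    min_fraction: float = 0.1,
    pseudocount: float = 1.0,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression between two cell groups.

    Counts are depth-normalized and log1p-transformed; genes detected in fewer
    than ``min_fraction`` of cells in both groups are skipped (their number
    logged and recorded in ``attrs["n_filtered"]``). The fold change is
    ``log2(mean_a + pseudocount) - log2(mean_b + pseudocount)`` on the
    normalized scale, and Bonferroni uses m = genes actually tested.
    """
    label_series = cells.obs[labels] if isinstance(labels, str) else labels
    mask_a = np.asarray(label_series == group_a)
    mask_b = np.asarray(label_series == group_b)
    for name, mask in ((group_a, mask_a), (group_b, mask_b)):
        if mask.sum() < 3:
            raise GroupingError(f"group {name!r} has {int(mask.sum())} cells (< 3)")

    data = normalize_cells(cells, target_sum)
    a, b = data[mask_a], data[mask_b]
    frac_a = (a > 0).mean(axis=0)
    frac_b = (b > 0).mean(axis=0)
    tested = (frac_a >= min_fraction) | (frac_b >= min_fraction)
    n_filtered = int((~tested).sum())
    if n_filtered:
        logger.info("skipping %d genes below the %.0f%% detection filter", n_filtered, 100 * min_fraction)

    a, b = a[:, tested], b[:, tested]
    if max(a.shape[0], b.shape[0]) <= 8:
        pvals = np.array([mannwhitney(a[:, j], b[:, j])[1] for j in range(a.shape[1])])
    else:
        pvals = sps.mannwhitneyu(a, b, alternative="two-sided", axis=0).pvalue
    m = int(tested.sum())
    log2fc = np.log2(a.mean(axis=0) + pseudocount) - np.log2(b.mean(axis=0) + pseudocount)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "p_adj": np.minimum(1.0, pvals * m),
            "pct_a": frac_a[tested],
            "pct_b": frac_b[tested],
        },
        index=pd.Index(np.asarray(cells.var_names, dtype=object)[tested], name="gene"),
    )
    table.attrs["n_filtered"] = n_filtered
    table.attrs["groups"] = (group_a, group_b)
    return table
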