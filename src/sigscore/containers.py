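"""Core in-memory containers shared across the package.

Bulk expression lives in an :class:`ExpressionMatrix` (genes x samples pandas
DataFrame plus a declared value scale); gene sets follow GMT semantics; GSEA
output is collected in :class:`EnrichmentResult`. Single-cell data uses
:class:`anndata.AnnData` directly (cells x genes, cluster labels in
``obs["cluster"]``) and is not wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataFormatError

#: Ordinal clinical response vocabulary, worst to best (ACR improvement grades).
RESPONSE_GRADES: tuple[str, ...] = ("NR", "ACR30", "ACR50", "ACR70", "ACR90", "ACR100")

#: Recognised expression value scales.
SCALES: tuple[str, ...] = ("log2", "linear")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared value scale.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with one column per sample. Gene ids and
        sample ids must be unique; values must be numeric.
    scale:
        ``"log2"`` for log-scale summaries (microarray/RNA-seq style) or
        ``"linear"`` for natural-scale intensities.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigurationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample ids: {dupes[:5]}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise DataFormatError("expression matrix contains non-numeric columns")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_linear(self) -> pd.DataFrame:
        """Return values on the linear scale (exponentiates log2 input)."""
        if self.scale == "linear":
            return self.data
        return np.exp2(self.data)


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with GMT semantics (name, description, members)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataFormatError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DataFormatError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class GeneSetCollection:
    """Ordered collection of uniquely named :class:`GeneSet` objects."""

    def __init__(self, sets: Sequence[GeneSet]):
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            raise DataFormatError("duplicate gene-set names in collection")
        self._sets: list[GeneSet] = list(sets)
        self._by_name = {s.name: s for s in self._sets}

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._sets]


@dataclass
class RankedList:
    """Genes ordered by a ranking statistic, best (largest) first.

    Ties in the statistic are broken by ascending gene id so that the ordering
    is reproducible across platforms; :func:`sigscore.gsea.rank_genes` applies
    that rule on construction.
    """

    genes: np.ndarray
    stats: np.ndarray
    metric: str = "precomputed"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.stats = np.asarray(self.stats, dtype=float)
        if self.genes.shape != self.stats.shape or self.genes.ndim != 1:
            raise DataFormatError("genes and stats must be 1-D arrays of equal length")
        if len(set(self.genes.tolist())) != len(self.genes):
            raise DataFormatError("ranked list contains duplicate gene ids")
        if np.any(np.diff(self.stats) > 0):
            raise DataFormatError("ranking statistics must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """GSEA output for one gene set.

    ``peak`` is the 1-based rank position at which the running sum attains its
    maximum absolute deviation; ``profile`` holds the running sum at every rank
    position. ``nes`` is NaN when no same-sign permutation ES exists.
    """

    set_name: str
    size: int
    es: float
    peak: int
    leading_edge: tuple[str, ...]
    profile: np.ndarray
    nes: float = float("nan")
    pvalue: float = float("nan")
    qvalue: float = float("nan")
    scheme: str | None = None
    n_perm: int = 0
    seed: int | None = None


@dataclass
class SignatureScores:
    """Per-sample composite control-referenced signature scores.

    ``table`` is indexed by sample id with columns ``score`` (sum of per-gene
    z-scores, dimensionless) and ``n_genes_used``; ``excluded`` lists
    (gene, reason) pairs for signature genes that could not be scored.
    """

    table: pd.DataFrame
    genes_used: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...] = ()

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]


def make_response_table(records: Sequence[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Build a response table from (patient, baseline sample, day-3 sample, grade).

    The grade column is an ordered categorical over :data:`RESPONSE_GRADES`.
    """
    table = pd.DataFrame(
        records, columns=["patient_id", "baseline_sample", "day3_sample", "grade"]
    )
    bad = set(table["grade"]) - set(RESPONSE_GRADES)
    if bad:
        raise DataFormatError(f"unknown response grades: {sorted(bad)}")
    table["grade"] = pd.Categorical(table["grade"], categories=RESPONSE_GRADES, ordered=True)
    return table


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic dataset.

    Records exactly what was planted so downstream recovery tests never have to
    re-derive it: the signature gene ids, the per-sample group labels, per-gene
    log-scale case shifts, the per-grade attenuation fractions (response
    cohorts) and the activated cluster label (single-cell datasets).
    """

    signature_genes: tuple[str, ...]
    group_labels: pd.Series | None = None
    gene_shifts: pd.Series | None = None
    grade_attenuation: dict[str, float] | None = None
    activated_cluster: str | None = None
    extra: dict = field(default_factory=dict)
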