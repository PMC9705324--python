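"""Synthetic cohorts with planted ground truth.

Every generator here emits data plus a :class:`~sigscore.containers.GroundTruth`
record of exactly what was planted, so each downstream stage (enrichment,
scoring, stratification, module scoring) can be validated against a known
answer without any external download.

Models
------
* Bulk cohorts: per-gene baselines drawn uniformly on the log2 scale with
  additive Gaussian noise; signature genes in cases are shifted upward by
  ``effect_size * noise_sd`` log2 units. The scoring math downstream only
  assumes a location/scale model, so this is the minimal faithful emulation of
  normalized microarray / RNA-seq summary data.
* Paired response cohorts: each patient carries a persistent per-gene random
  effect shared by the baseline and day-3 draws (test-retest correlation of
  repeat blood samples), and the planted day-3 shift equals the baseline shift
  times ``1 - attenuation[grade]``.
* Multi-study collections: per-study multiplicative scale on the linear scale,
  plus designated target genes with a fixed case-vs-control fold change within
  every study (the situation percent-of-control normalization exists for).
* Single-cell datasets: gamma-Poisson (negative binomial) counts with per-cell
  library-size factors; signature genes in one activated cluster have their
  means multiplied by ``activation_fold``.

Determinism: each generator consumes a single ``numpy`` Generator seeded from
``config.seed``, with per-study sub-seeds spawned deterministically, so an
identical config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .containers import (
    RESPONSE_GRADES,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GroundTruth,
    make_response_table,
)
from .exceptions import ConfigurationError

__all__ = [
    "SyntheticCohortConfig",
    "ResponseCohortConfig",
    "MultiStudyConfig",
    "SyntheticSingleCellConfig",
    "generate_bulk_cohort",
    "generate_response_cohort",
    "generate_gene_set_collection",
    "generate_multi_study",
    "generate_single_cell_dataset",
]


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Case/control bulk cohort with one planted up-regulated gene set.

    Defaults mirror a canakinumab-trial-sized cohort: 22 healthy controls and
    82 patients at baseline, a 30-gene signature shifted by one control SD.

    Parameters
    ----------
    effect_size:
        Case shift of signature genes in units of the control SD (log2 scale).
    noise_sd:
        Per-gene residual SD on the log2 scale.
    baseline_mean_range:
        Interval for per-gene baseline means (log2 scale).
    """

    n_controls: int = 22
    n_cases: int = 82
    n_genes: int = 1000
    n_signature_genes: int = 30
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_cases", "n_genes", "n_signature_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_signature_genes > self.n_genes:
            raise ConfigurationError(
                f"n_signature_genes={self.n_signature_genes} exceeds n_genes={self.n_genes}"
            )
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        lo, hi = self.baseline_mean_range
        if hi < lo:
            raise ConfigurationError("baseline_mean_range upper bound below lower bound")


def _default_grade_counts() -> dict[str, int]:
    # Fig-5d-sized trial arm: 62 patients across six ACR grades.
    return {"NR": 10, "ACR30": 6, "ACR50": 11, "ACR70": 16, "ACR90": 8, "ACR100": 11}


def _default_attenuation() -> dict[str, float]:
    return {"NR": 0.0, "ACR30": 0.2, "ACR50": 0.4, "ACR70": 0.6, "ACR90": 0.8, "ACR100": 1.0}


@dataclass(frozen=True)
class ResponseCohortConfig(SyntheticCohortConfig):
    """Paired baseline/day-3 cohort with grade-dependent attenuation.

    ``attenuation_fractions`` gives, per response grade, the fraction of the
    planted baseline effect removed at day 3; it must be non-decreasing from
    NR to ACR100. ``test_retest_correlation`` is the fraction of per-gene
    noise variance shared between a patient's two timepoints (persistent
    patient effect); the marginal per-sample distribution is unaffected.
    ``n_cases`` is derived from ``grade_counts``.
    """

    grade_counts: Mapping[str, int] = field(default_factory=_default_grade_counts)
    attenuation_fractions: Mapping[str, float] = field(default_factory=_default_attenuation)
    test_retest_correlation: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_cases", sum(self.grade_counts.values()))
        super().__post_init__()
        unknown = set(self.grade_counts) - set(RESPONSE_GRADES)
        if unknown:
            raise ConfigurationError(f"unknown response grades: {sorted(unknown)}")
        if any(v < 0 for v in self.grade_counts.values()):
            raise ConfigurationError("grade counts must be non-negative")
        missing = {
            g for g, n in self.grade_counts.items() if n > 0
        } - set(self.attenuation_fractions)
        if missing:
            raise ConfigurationError(f"no attenuation fraction for grades: {sorted(missing)}")
        fracs = [self.attenuation_fractions[g] for g in RESPONSE_GRADES if g in self.grade_counts]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("attenuation fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ConfigurationError(
                "attenuation fractions must be non-decreasing from NR to ACR100"
            )
        if not 0.0 <= self.test_retest_correlation < 1.0:
            raise ConfigurationError("test_retest_correlation must lie in [0, 1)")


@dataclass(frozen=True)
class MultiStudyConfig:
    """Several case/control studies differing by a multiplicative scale.

    ``target_gene_effects`` maps extra gene ids (appended to every study's
    panel) to a case-vs-control fold change applied within each study —
    e.g. ``{"TSC1": 0.7, "TSC2": 0.7}`` plants a down-regulated pair.
    Emitted matrices are on the linear scale, each multiplied by its study's
    scale factor.
    """

    n_studies: int = 6
    scale_factors: tuple[float, ...] = (1.0, 2.5, 0.5, 10.0, 5.0, 1.5)
    study_ids: tuple[str, ...] | None = None
    cohort: SyntheticCohortConfig = field(
        default_factory=lambda: SyntheticCohortConfig(n_controls=20, n_cases=25, n_genes=200)
    )
    target_gene_effects: Mapping[str, float] = field(
        default_factory=lambda: {"TSC1": 0.7, "TSC2": 0.7}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies <= 0:
            raise ConfigurationError("n_studies must be positive")
        if len(self.scale_factors) != self.n_studies:
            raise ConfigurationError("scale_factors length must equal n_studies")
        if any(s <= 0 for s in self.scale_factors):
            raise ConfigurationError("scale factors must be > 0")
        ids = self.study_ids or tuple(f"STUDY{i + 1}" for i in range(self.n_studies))
        if len(ids) != self.n_studies:
            raise ConfigurationError("study_ids length must equal n_studies")
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate study ids")
        object.__setattr__(self, "study_ids", ids)
        if any(f <= 0 for f in self.target_gene_effects.values()):
            raise ConfigurationError("target gene fold changes must be > 0")


@dataclass(frozen=True)
class SyntheticSingleCellConfig:
    """Clustered droplet-style count data with one activated cluster.

    Counts are gamma-Poisson: per-gene base means drawn log-uniformly from
    ``base_expression``, multiplied by a per-cell library factor drawn from
    ``library_size_range``; ``dispersion`` is the NB overdispersion (variance
    = mu + dispersion * mu^2; 0 gives pure Poisson). Signature genes in the
    ``activated_cluster`` have their means multiplied by ``activation_fold``.
    """

    n_clusters: int = 4
    n_cells_per_cluster: int | tuple[int, ...] = 250
    n_genes: int = 2000
    n_signature_genes: int = 30
    base_expression: tuple[float, float] = (0.05, 2.0)
    dispersion: float = 0.3
    activated_cluster: int = 0
    activation_fold: float = 4.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters <= 0 or self.n_genes <= 0 or self.n_signature_genes <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_signature_genes > self.n_genes:
            raise ConfigurationError("n_signature_genes exceeds n_genes")
        if self.activation_fold < 1.0:
            raise ConfigurationError(
                f"activation_fold must be >= 1, got {self.activation_fold}"
            )
        if not 0 <= self.activated_cluster < self.n_clusters:
            raise ConfigurationError("activated_cluster index out of range")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        lo, hi = self.base_expression
        if lo <= 0 or hi < lo:
            raise ConfigurationError("base_expression interval must be positive and ordered")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("library_size_range must be positive and ordered")

    @property
    def cells_per_cluster(self) -> tuple[int, ...]:
        if isinstance(self.n_cells_per_cluster, int):
            return (self.n_cells_per_cluster,) * self.n_clusters
        if len(self.n_cells_per_cluster) != self.n_clusters:
            raise ConfigurationError("n_cells_per_cluster length must equal n_clusters")
        return tuple(self.n_cells_per_cluster)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_bulk_cohort(
    config: SyntheticCohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a two-group bulk cohort with a planted up-regulated signature.

    Returns the log2-scale expression matrix (genes x samples), sample
    annotations (``group`` in {control, case}) and the planted truth. With
    ``effect_size == 0`` every gene/group combination is exchangeable.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    controls = [f"CTRL{i + 1:03d}" for i in range(config.n_controls)]
    cases = [f"CASE{i + 1:03d}" for i in range(config.n_cases)]
    samples = controls + cases

    baselines = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    values = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(samples))
    )
    sig_idx = np.sort(rng.choice(config.n_genes, config.n_signature_genes, replace=False))
    shift = config.effect_size * config.noise_sd
    values[np.ix_(sig_idx, np.arange(config.n_controls, len(samples)))] += shift

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale="log2")
    annotations = pd.DataFrame(
        {"group": ["control"] * len(controls) + ["case"] * len(cases)},
        index=pd.Index(samples, name="sample_id"),
    )
    shifts = pd.Series(0.0, index=matrix.genes, name="log2_shift")
    shifts.iloc[sig_idx] = shift
    truth = GroundTruth(
        signature_genes=tuple(np.asarray(genes, dtype=object)[sig_idx]),
        group_labels=annotations["group"],
        gene_shifts=shifts,
    )
    return matrix, annotations, truth


def generate_response_cohort(
    config: ResponseCohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate controls plus paired baseline/day-3 patients.

    The day-3 signature shift for a patient with grade *g* equals the baseline
    shift times ``1 - attenuation_fractions[g]``. Returns the expression
    matrix, a response table (patient, baseline sample, day-3 sample, grade)
    and the planted truth; per-sample annotations are stored in
    ``truth.extra["annotations"]``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baselines = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    sig_idx = np.sort(rng.choice(config.n_genes, config.n_signature_genes, replace=False))
    sig_mask = np.zeros(config.n_genes, dtype=bool)
    sig_mask[sig_idx] = True
    shift = config.effect_size * config.noise_sd

    rho = config.test_retest_correlation
    sd_patient = np.sqrt(rho) * config.noise_sd
    sd_resid = np.sqrt(1.0 - rho) * config.noise_sd

    columns: dict[str, np.ndarray] = {}
    ann_rows: list[tuple[str, str, str, str, str]] = []
    for i in range(config.n_controls):
        sid = f"CTRL{i + 1:03d}"
        columns[sid] = baselines + rng.normal(0.0, config.noise_sd, config.n_genes)
        ann_rows.append((sid, "control", sid, "baseline", ""))

    records = []
    patient_no = 0
    for grade in RESPONSE_GRADES:
        n = config.grade_counts.get(grade, 0)
        if n == 0:
            continue
        att = config.attenuation_fractions[grade]
        for _ in range(n):
            patient_no += 1
            pid = f"P{patient_no:03d}"
            persistent = rng.normal(0.0, sd_patient, config.n_genes)
            for timepoint, frac in (("baseline", 1.0), ("day3", 1.0 - att)):
                sid = f"{pid}_{'T0' if timepoint == 'baseline' else 'T3'}"
                x = baselines + persistent + rng.normal(0.0, sd_resid, config.n_genes)
                x[sig_mask] += shift * frac
                columns[sid] = x
                ann_rows.append((sid, "case", pid, timepoint, grade))
            records.append((pid, f"{pid}_T0", f"{pid}_T3", grade))

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes), scale="log2")
    annotations = pd.DataFrame(
        ann_rows, columns=["sample_id", "group", "patient_id", "timepoint", "response_grade"]
    ).set_index("sample_id")
    response = make_response_table(records)
    shifts = pd.Series(0.0, index=matrix.genes, name="log2_shift")
    shifts.iloc[sig_idx] = shift
    truth = GroundTruth(
        signature_genes=tuple(np.asarray(genes, dtype=object)[sig_idx]),
        group_labels=annotations["group"],
        gene_shifts=shifts,
        grade_attenuation={
            g: float(f) for g, f in config.attenuation_fractions.items() if g in RESPONSE_GRADES
        },
        extra={"annotations": annotations},
    )
    return matrix, response, truth


def generate_gene_set_collection(
    n_sets: int,
    set_size_range: tuple[int, int],
    signature_gene_ids: Sequence[str],
    universe: Sequence[str],
    seed: int = 0,
) -> GeneSetCollection:
    """One planted signature set plus ``n_sets - 1`` decoy sets.

    Decoys are drawn uniformly without replacement from non-signature genes of
    the universe, so they are disjoint from the planted signature by
    construction.
    """
    if n_sets <= 0:
        raise ConfigurationError("n_sets must be positive")
    universe = list(universe)
    signature = list(signature_gene_ids)
    missing = set(signature) - set(universe)
    if missing:
        raise ConfigurationError(f"signature genes not in universe: {sorted(missing)[:5]}")
    lo, hi = set_size_range
    if lo <= 0 or hi < lo:
        raise ConfigurationError("set_size_range must be positive and ordered")
    decoy_pool = np.asarray(sorted(set(universe) - set(signature)), dtype=object)
    if hi > len(decoy_pool):
        raise ConfigurationError(
            f"decoy set size up to {hi} exceeds {len(decoy_pool)} available non-signature genes"
        )
    rng = np.random.default_rng(seed)
    sets = [GeneSet("PLANTED_SIGNATURE", tuple(signature), "planted signature set")]
    for i in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(decoy_pool, size=size, replace=False)
        sets.append(GeneSet(f"DECOY_{i + 1:03d}", tuple(members), "random decoy set"))
    return GeneSetCollection(sets)


def generate_multi_study(
    config: MultiStudyConfig,
) -> list[tuple[str, ExpressionMatrix, pd.DataFrame]]:
    """Simulate several studies with study-specific multiplicative scale.

    Each study is an independent bulk cohort (per-study sub-seed spawned from
    ``config.seed``) with the configured target genes appended; target genes
    carry their fold change in cases within every study. Matrices are emitted
    on the linear scale, multiplied by the study's scale factor.

    Returns a list of ``(study_id, matrix, annotations)`` tuples; annotations
    carry a ``study_id`` column.
    """
    out = []
    child_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_studies)
    target_genes = list(config.target_gene_effects)
    for study_id, scale, child in zip(config.study_ids, config.scale_factors, child_seeds):
        sub = replace(config.cohort, seed=int(child % (2**31)))
        matrix, annotations, _ = generate_bulk_cohort(sub)
        rng = np.random.default_rng(int(child % (2**31)) + 1)
        data = matrix.data.copy()
        n_case = int((annotations["group"] == "case").sum())
        case_cols = annotations.index[annotations["group"] == "case"]
        for gene in target_genes:
            base = rng.uniform(*sub.baseline_mean_range)
            row = base + rng.normal(0.0, sub.noise_sd, data.shape[1])
            data.loc[gene] = row
            data.loc[gene, case_cols] += np.log2(config.target_gene_effects[gene])
        linear = np.exp2(data) * scale
        annotations = annotations.copy()
        annotations["study_id"] = study_id
        annotations.index = pd.Index(
            [f"{study_id}_{s}" for s in annotations.index], name="sample_id"
        )
        linear.columns = annotations.index
        out.append((study_id, ExpressionMatrix(linear, scale="linear"), annotations))
    return out


def generate_single_cell_dataset(
    config: SyntheticSingleCellConfig,
) -> tuple[AnnData, pd.DataFrame, GroundTruth]:
    """Simulate clustered sparse counts with one signature-activated cluster.

    Returns an :class:`AnnData` (cells x genes, CSR integer counts, cluster
    labels in ``obs["cluster"]``), a cell annotation frame and the planted
    truth. Cluster labels are ``C0 ... C{k-1}``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    lo, hi = config.base_expression
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    sig_idx = np.sort(rng.choice(config.n_genes, config.n_signature_genes, replace=False))

    blocks = []
    labels: list[str] = []
    for j, n_cells in enumerate(config.cells_per_cluster):
        lib = rng.uniform(*config.library_size_range, size=n_cells)
        mu = np.outer(lib, base)
        if j == config.activated_cluster:
            mu[:, sig_idx] *= config.activation_fold
        if config.dispersion > 0:
            lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
        else:
            lam = mu
        blocks.append(rng.poisson(lam))
        labels.extend([f"C{j}"] * n_cells)

    counts = sparse.csr_matrix(np.vstack(blocks).astype(np.int64))
    barcodes = [f"CELL{i + 1:05d}" for i in range(counts.shape[0])]
    obs = pd.DataFrame({"cluster": labels}, index=pd.Index(barcodes, name="cell_id"))
    adata = AnnData(X=counts, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    truth = GroundTruth(
        signature_genes=tuple(np.asarray(genes, dtype=object)[sig_idx]),
        group_labels=obs["cluster"],
        activated_cluster=f"C{config.activated_cluster}",
        extra={"base_expression": pd.Series(base, index=genes)},
    )
    return adata, obs, truth
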