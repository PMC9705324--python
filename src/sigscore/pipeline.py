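"""End-to-end driver: enrichment -> leading edge -> scores -> stratification.

Every intermediate is persisted as flat text (TSV/JSON) in the output
directory, and the final report contains only numbers that can be recomputed
from those persisted files — :func:`verify_run` asserts exactly that.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, GeneSetCollection
from .exceptions import ConfigurationError, SigscoreError
from .gsea import batch_gsea, rank_genes
from .io import read_annotations, read_expression, read_gmt
from .scoring import signature_score
from .stats import paired_change, stratify_by_response

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "verify_run"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; round-trips losslessly via YAML."""

    expression: str
    annotations: str
    gene_sets: str
    outdir: str
    set_name: str | None = None
    response: str | None = None
    scale: str = "log2"
    metric: str = "signal_to_noise"
    n_perm: int = 1000
    scheme: str = "gene_label"
    exponent: float = 1.0
    min_size: int = 5
    max_size: int = 500
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        missing = {"expression", "annotations", "gene_sets", "outdir"} - set(raw)
        if missing:
            raise ConfigurationError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)


def _score_summaries(scores: pd.DataFrame, annotations: pd.DataFrame) -> dict:
    merged = scores.join(annotations, how="left")
    out: dict[str, dict] = {}
    for group, sub in merged.groupby("group", sort=True):
        out[str(group)] = {
            "n": int(len(sub)),
            "mean": float(sub["score"].mean()),
            "median": float(sub["score"].median()),
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config`` and persist every stage.

    Stages: read inputs; rank genes case-vs-control; permutation GSEA over the
    collection; pick the target set (``set_name`` or the smallest p); extract
    its leading edge; score every sample against the controls; and, when a
    response table is supplied, compute per-patient deltas and the
    grade-stratified Kruskal-Wallis comparison. Returns the run report (also
    written to ``report.json``). Fully deterministic given the seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    stage = "read inputs"
    try:
        matrix = read_expression(config.expression, scale=config.scale)
        annotations = read_annotations(config.annotations)
        collection = read_gmt(config.gene_sets)

        stage = "rank genes"
        baseline_ids = annotations.index[annotations["group"].isin(["control", "case"])]
        baseline = ExpressionMatrix(
            matrix.data[matrix.samples.intersection(baseline_ids)], scale=matrix.scale
        )
        ranked = rank_genes(baseline, annotations, config.metric)
        pd.DataFrame({"gene": ranked.genes, "stat": ranked.stats}).to_csv(
            outdir / "ranked.tsv", sep="\t", index=False
        )

        stage = "gene set enrichment"
        enrichment = batch_gsea(
            baseline if config.scheme == "phenotype" else ranked,
            collection,
            n_perm=config.n_perm,
            scheme=config.scheme,
            seed=config.seed,
            annotations=annotations,
            metric=config.metric,
            exponent=config.exponent,
            min_size=config.min_size,
            max_size=config.max_size,
        )
        flat = enrichment.copy()
        flat["leading_edge"] = flat["leading_edge"].map(";".join)
        flat.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        stage = "leading edge"
        if config.set_name is not None:
            if config.set_name not in set(enrichment["set"]):
                raise ConfigurationError(f"set {config.set_name!r} not in retained collection")
            row = enrichment.loc[enrichment["set"] == config.set_name].iloc[0]
        else:
            row = enrichment.sort_values(["pvalue", "set"]).iloc[0]
        edge = list(row["leading_edge"])
        (outdir / "leading_edge.txt").write_text("\n".join(edge) + "\n")

        stage = "signature scoring"
        control_ids = annotations.index[annotations["group"] == "control"]
        scores = signature_score(matrix, list(control_ids), edge)
        scores.table.to_csv(outdir / "scores.tsv", sep="\t")

        stage = "response stratification"
        stratification = None
        deltas = None
        if config.response is not None:
            response = pd.read_csv(config.response, dtype={"grade": str})
            from .containers import make_response_table

            response = make_response_table(
                list(
                    response[["patient_id", "baseline_sample", "day3_sample", "grade"]]
                    .itertuples(index=False, name=None)
                )
            )
            deltas = paired_change(scores, response)
            deltas.table.to_csv(outdir / "deltas.tsv", sep="\t")
            stratification = stratify_by_response(deltas)
            payload = {
                "kruskal_wallis_statistic": stratification.statistic,
                "kruskal_wallis_p": stratification.pvalue,
                "monotone_trend": stratification.monotone_trend,
                "signed_rank_statistic": deltas.statistic,
                "signed_rank_p": deltas.pvalue,
                "per_grade": stratification.summary.reset_index().to_dict(orient="records"),
            }
            (outdir / "stratification.json").write_text(json.dumps(payload, indent=2) + "\n")
    except SigscoreError as err:
        raise SigscoreError(f"pipeline stage {stage!r} failed: {err}") from err

    report = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "counts": {
            "genes": int(matrix.shape[0]),
            "samples": int(matrix.shape[1]),
            "gene_sets_tested": int(len(enrichment)),
            "leading_edge_size": len(edge),
        },
        "enrichment": flat.drop(columns=["leading_edge"]).to_dict(orient="records"),
        "target_set": {
            "name": str(row["set"]),
            "es": float(row["es"]),
            "nes": float(row["nes"]),
            "pvalue": float(row["pvalue"]),
            "leading_edge": edge,
        },
        "score_summaries": _score_summaries(scores.table, annotations),
    }
    if stratification is not None:
        report["stratification"] = {
            "kruskal_wallis_statistic": stratification.statistic,
            "kruskal_wallis_p": stratification.pvalue,
            "monotone_trend": stratification.monotone_trend,
            "per_grade_median_delta": {
                str(g): float(m)
                for g, m in stratification.summary["median_delta"].items()
            },
        }
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def verify_run(outdir: str | Path, atol: float = 1e-9) -> list[str]:
    """Check that every report number is recomputable from the stage files.

    Recomputes the report's summary block from the persisted TSVs and returns
    a list of mismatch descriptions (empty when the run verifies).
    """
    outdir = Path(outdir)
    report = json.loads((outdir / "report.json").read_text())
    mismatches: list[str] = []

    enrichment = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    target = report["target_set"]
    row = enrichment.loc[enrichment["set"] == target["name"]]
    if row.empty:
        mismatches.append(f"target set {target['name']!r} absent from enrichment.tsv")
    else:
        for key in ("es", "nes", "pvalue"):
            if not np.isclose(row.iloc[0][key], target[key], atol=atol, equal_nan=True):
                mismatches.append(
                    f"target {key}: report {target[key]} vs enrichment.tsv {row.iloc[0][key]}"
                )
        edge_file = (outdir / "leading_edge.txt").read_text().split()
        if edge_file != target["leading_edge"]:
            mismatches.append("leading_edge.txt does not match report leading edge")

    scores = pd.read_csv(outdir / "scores.tsv", sep="\t", index_col=0)
    annotations = read_annotations(report["parameters"]["annotations"])
    recomputed = _score_summaries(scores, annotations)
    for group, summary in report["score_summaries"].items():
        for key in ("mean", "median"):
            got = recomputed.get(group, {}).get(key)
            if got is None or not np.isclose(got, summary[key], atol=atol):
                mismatches.append(f"score summary {group}/{key}: report {summary[key]} vs {got}")

    if "stratification" in report:
        deltas = pd.read_csv(outdir / "deltas.tsv", sep="\t", index_col=0)
        for grade, median in report["stratification"]["per_grade_median_delta"].items():
            got = float(deltas.loc[deltas["grade"] == grade, "delta"].median())
            if not np.isclose(got, median, atol=atol):
                mismatches.append(f"median delta for {grade}: report {median} vs {got}")
    return mismatches
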