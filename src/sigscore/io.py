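"""Readers and writers for the flat-text formats the pipeline exchanges.

Formats: expression TSV (first column gene id, header row of sample ids),
annotations CSV, GMT gene-set collections, and the MatrixMarket single-cell
bundle (matrix.mtx + genes.tsv + barcodes.tsv + clusters.csv, genes x cells
as emitted by droplet pipelines). Everything round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.io import mmread, mmwrite

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection
from .exceptions import DataFormatError

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "read_cell_bundle",
    "write_cell_bundle",
]


def read_expression(path: str | Path, scale: str = "log2", sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples table; rejects duplicates and non-numeric cells."""
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)[1:]
    seen_twice = {s for s in header if header.count(s) > 1}
    if seen_twice:
        raise DataFormatError(f"{path.name}: duplicate sample id(s) {sorted(seen_twice)[:5]}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataFormatError(f"{path.name}: duplicate gene id(s) {dupes[:5]}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DataFormatError(f"{path.name}: duplicate sample id(s) {dupes[:5]}")
    data = raw.apply(pd.to_numeric, errors="coerce")
    bad = data.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        gene, sample = data.index[rows[0]], data.columns[cols[0]]
        raise DataFormatError(
            f"{path.name}: non-numeric value {raw.iat[rows[0], cols[0]]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    if data.isna().to_numpy().any():
        raise DataFormatError(f"{path.name}: missing values in expression table")
    data.index.name = "gene_id"
    return ExpressionMatrix(data, scale=scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    data = matrix.data.copy()
    data.index.name = "gene_id"
    data.to_csv(path, sep=sep)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation CSV indexed by ``sample_id``."""
    table = pd.read_csv(path, dtype=str).fillna("")
    if "sample_id" not in table.columns:
        raise DataFormatError(f"{Path(path).name}: missing required column 'sample_id'")
    if table["sample_id"].duplicated().any():
        raise DataFormatError(f"{Path(path).name}: duplicate sample ids")
    return table.set_index("sample_id")


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> member...).

    Lines with fewer than three fields are rejected with their line number;
    duplicated members within a line are dropped with a warning.
    """
    import warnings

    sets = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{Path(path).name}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"{Path(path).name}:{lineno}: duplicated members in set {name!r} deduplicated"
                )
            if not unique:
                raise DataFormatError(f"{Path(path).name}:{lineno}: set {name!r} is empty")
            sets.append(GeneSet(name, tuple(unique), description))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in collection:
            handle.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_cell_bundle(directory: str | Path) -> AnnData:
    """Read a MatrixMarket bundle into an AnnData (cells x genes).

    Expects ``matrix.mtx`` (genes x cells), ``genes.tsv``, ``barcodes.tsv``
    and optionally ``clusters.csv`` (barcode, cluster). Dimension mismatches
    between the matrix and sidecars are rejected with expected/actual sizes.
    """
    directory = Path(directory)
    matrix = sparse.csr_matrix(mmread(directory / "matrix.mtx").T)
    genes = (directory / "genes.tsv").read_text().splitlines()
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    n_cells, n_genes = matrix.shape
    if len(genes) != n_genes:
        raise DataFormatError(
            f"genes.tsv lists {len(genes)} genes but matrix.mtx has {n_genes} gene rows"
        )
    if len(barcodes) != n_cells:
        raise DataFormatError(
            f"barcodes.tsv lists {len(barcodes)} cells but matrix.mtx has {n_cells} cell columns"
        )
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    clusters_path = directory / "clusters.csv"
    if clusters_path.exists():
        clusters = pd.read_csv(clusters_path, dtype=str).set_index("cell_id")["cluster"]
        missing = set(barcodes) - set(clusters.index)
        if missing:
            raise DataFormatError(f"clusters.csv missing {len(missing)} barcodes")
        obs["cluster"] = clusters.reindex(barcodes).to_numpy()
    return AnnData(X=matrix, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))


def write_cell_bundle(adata: AnnData, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix = adata.X
    if not sparse.issparse(matrix):
        matrix = sparse.csr_matrix(matrix)
    mmwrite(directory / "matrix.mtx", sparse.coo_matrix(matrix.T.astype(np.int64)))
    (directory / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    if "cluster" in adata.obs.columns:
        pd.DataFrame(
            {"cell_id": adata.obs_names, "cluster": adata.obs["cluster"].to_numpy()}
        ).to_csv(directory / "clusters.csv", index=False)
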