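"""Readers and writers for the package's on-disk formats.

Count matrices travel either as a MatrixMarket file with gene/cell sidecar
TSVs (directory layout: ``matrix.mtx``, ``genes.tsv``, ``cells.tsv``) or as
a single dense TSV whose header row names the samples and whose first
column holds gene identifiers.  All tables are plain TSV; manifests and
parameter bundles are JSON.  Every writer's output is re-readable by the
matching reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, ValidationError
from .tissue_identity import SimilarityMatrix, TissuePanel, TissueSignature

GENE_ANNOTATION_REQUIRED = ("gene_id", "symbol", "length_bp", "biotype", "is_mitochondrial")

MTX_NAME, GENES_NAME, CELLS_NAME = "matrix.mtx", "genes.tsv", "cells.tsv"
DENSE_NAME = "counts.tsv"


def _parse_bool(series: pd.Series) -> pd.Series:
    """Robust boolean parse: TSV round-trips may deliver 'True'/'False' strings."""
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False}
    parsed = series.map(lambda v: mapping.get(str(v).strip().lower()))
    if parsed.isna().any():
        bad = series[parsed.isna()].iloc[0]
        raise ValidationError(f"cannot parse boolean value {bad!r}")
    return parsed.astype(bool)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def write_counts(counts: CountMatrix, path: str | Path, fmt: str = "mtx") -> Path:
    """Write a count matrix.

    ``fmt='mtx'``: ``path`` is a directory receiving matrix.mtx plus
    genes.tsv / cells.tsv sidecars (annotation and metadata columns ride
    along).  ``fmt='tsv'``: same directory layout with a dense counts.tsv.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    genes = counts.gene_annotation.copy() if counts.gene_annotation is not None else pd.DataFrame(index=counts.gene_ids)
    genes.index.name = "gene_id"
    genes.to_csv(path / GENES_NAME, sep="\t")
    cells = counts.cell_metadata.copy() if counts.cell_metadata is not None else pd.DataFrame(index=counts.sample_ids)
    cells.index.name = "cell_id"
    cells.to_csv(path / CELLS_NAME, sep="\t")
    if fmt == "mtx":
        spio.mmwrite(str(path / MTX_NAME), sparse.coo_matrix(counts.values.to_numpy()))
    elif fmt == "tsv":
        dense = counts.values.copy()
        dense.index.name = "gene_id"
        dense.to_csv(path / DENSE_NAME, sep="\t")
    else:
        raise ValidationError(f"unknown count format {fmt!r}")
    return path


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix written by :func:`write_counts`, or a bare dense TSV.

    A directory is expected to hold matrix.mtx or counts.tsv with the two
    sidecars; a file path is parsed as a dense TSV (header = samples,
    first column = gene IDs) without annotation or metadata.
    """
    path = Path(path)
    if path.is_file():
        values = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(values)
    genes = pd.read_csv(path / GENES_NAME, sep="\t", index_col=0)
    cells = pd.read_csv(path / CELLS_NAME, sep="\t", index_col=0)
    mtx_path, dense_path = path / MTX_NAME, path / DENSE_NAME
    if mtx_path.exists():
        mat = np.asarray(spio.mmread(str(mtx_path)).todense())
        if mat.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match sidecars ({len(genes)} genes, {len(cells)} cells)"
            )
        values = pd.DataFrame(mat, index=genes.index, columns=cells.index)
    elif dense_path.exists():
        values = pd.read_csv(dense_path, sep="\t", index_col=0)
        if not values.index.equals(genes.index) or not values.columns.equals(cells.index):
            raise ValidationError("dense matrix identifiers do not match sidecars")
    else:
        raise ValidationError(f"no matrix.mtx or counts.tsv under {path}")
    annotation = genes if genes.shape[1] else None
    metadata = cells if cells.shape[1] else None
    if annotation is not None and "is_mitochondrial" in annotation.columns:
        annotation["is_mitochondrial"] = _parse_bool(annotation["is_mitochondrial"])
    return CountMatrix(values, gene_annotation=annotation, cell_metadata=metadata)


def load_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Load a gene annotation TSV (gene_id, symbol, length_bp, biotype, is_mitochondrial)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in GENE_ANNOTATION_REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"gene annotation is missing required columns: {missing}")
    table = table.set_index("gene_id")
    try:
        lengths = pd.to_numeric(table["length_bp"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"malformed length_bp value: {exc}") from exc
    if len(table) and (np.any(~np.isfinite(lengths)) or np.any(lengths <= 0) or np.any(lengths % 1 != 0)):
        raise ValidationError("length_bp must be positive integers")
    table["length_bp"] = lengths.astype(int) if len(table) else lengths
    if len(table):
        table["is_mitochondrial"] = _parse_bool(table["is_mitochondrial"])
    return table


# ---------------------------------------------------------------------------
# panels, signatures, tables
# ---------------------------------------------------------------------------


def write_panel(panel: TissuePanel, values_path: str | Path, tissues_path: str | Path) -> None:
    values = panel.values.copy()
    values.index.name = "gene_id"
    values.to_csv(values_path, sep="\t")
    tissues = panel.tissue_of_sample.rename("tissue").to_frame()
    tissues.index.name = "sample"
    tissues.to_csv(tissues_path, sep="\t")


def read_panel(values_path: str | Path, tissues_path: str | Path) -> TissuePanel:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    tissues = pd.read_csv(tissues_path, sep="\t", index_col=0)["tissue"]
    return TissuePanel(values=values, tissue_of_sample=tissues)


def write_signature(signature: TissueSignature, path: str | Path) -> None:
    table = signature.assignment.copy()
    table.index.name = "gene_id"
    table.to_csv(path, sep="\t")


def read_signature(path: str | Path, top_n: int | None = None) -> TissueSignature:
    table = pd.read_csv(path, sep="\t", index_col=0)
    inferred = int(table.groupby("tissue").size().max()) if len(table) else 0
    return TissueSignature(assignment=table, top_n=top_n or inferred)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    table = sim.values.copy()
    table["best_tissue"] = sim.best_tissue
    table["margin"] = sim.margin
    table.index.name = "query"
    table.to_csv(path, sep="\t")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_de_table(path: str | Path, source: str = "external") -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "log2_fold_change" not in table.columns:
        raise ValidationError("DE table must have a log2_fold_change column")
    table.attrs["source"] = source
    return table


def read_signature_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return symbols


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
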