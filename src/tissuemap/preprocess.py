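"""Cell/gene quality-control filters and expression normalizations.

Implements the preprocessing conventions of full-length (Fluidigm C1-style)
single-cell RNA-seq: per-cell QC on alignment-level metrics, CPM and
length-aware TPM normalization, pseudo-bulk aggregation by summing counts
within a cluster before normalizing, and the two gene filters used for
clustering (expression-based) and for DE / tissue classification
(count-based).

Boundary conventions follow the wording each rule is stated with: the QC
rules are strict inequalities ("greater than 20%", "less than 500
thousand"), so a cell sitting exactly on a threshold passes; the count
filter is inclusive ("10 or more counts in at least 10 cells").  The
expression filter log2(CPM) > 2 is applied as CPM > 4 on the linear scale,
which needs no pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CELL_METADATA_COLUMNS,
    CountMatrix,
    DegenerateInputError,
    EmptyResultError,
    ExpressionMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

MILLION = 1_000_000.0

#: QC rule labels, in the order the rules are evaluated.
QC_RULES = ("mito", "alignments", "genes", "mrna")


@dataclass(frozen=True)
class QCThresholds:
    """Cell QC thresholds.

    Defaults are the deep-coverage full-length single-cell conventions:
    remove cells with more than 20% mitochondrial reads, fewer than
    500 000 total alignments, fewer than 500 detected genes, or less than
    20% mRNA bases.  All four comparisons are strict, so boundary values
    pass.
    """

    max_mito: float = 0.20
    min_alignments: int = 500_000
    min_genes: int = 500
    min_mrna: float = 0.20


@dataclass
class CellQCMetrics:
    """Per-cell QC metrics plus pass/fail status.

    ``table`` has one row per cell with the four metric columns, a boolean
    ``pass_qc`` and a ``failed_rules`` column (comma-joined rule labels,
    empty string when passing).
    """

    table: pd.DataFrame
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def passing(self) -> pd.Index:
        return self.table.index[self.table["pass_qc"]]

    @property
    def failing(self) -> pd.Index:
        return self.table.index[~self.table["pass_qc"]]


def compute_cell_qc(counts: CountMatrix, thresholds: QCThresholds | None = None) -> CellQCMetrics:
    """Evaluate the four cell QC rules on the per-cell metadata.

    A cell fails iff ``mito_fraction > max_mito``, or
    ``total_alignments < min_alignments``, or ``detected_genes < min_genes``,
    or ``mrna_base_fraction < min_mrna`` (all strict).  The metrics are
    alignment-level quantities carried in ``counts.cell_metadata``; they are
    not recomputed from the count matrix.
    """
    thresholds = thresholds or QCThresholds()
    meta = counts.cell_metadata
    if meta is None:
        raise ValidationError("cell metadata is required for QC")
    for col in CELL_METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"cell metadata column {col!r} is required for QC")

    fails = pd.DataFrame(
        {
            "mito": meta["mito_fraction"] > thresholds.max_mito,
            "alignments": meta["total_alignments"] < thresholds.min_alignments,
            "genes": meta["detected_genes"] < thresholds.min_genes,
            "mrna": meta["mrna_base_fraction"] < thresholds.min_mrna,
        }
    )
    failed_rules = fails.apply(lambda row: ",".join(r for r in QC_RULES if row[r]), axis=1)
    table = meta[list(CELL_METADATA_COLUMNS)].copy()
    table["pass_qc"] = ~fails.any(axis=1)
    table["failed_rules"] = failed_rules
    n_fail = int((~table["pass_qc"]).sum())
    logger.info("cell QC: %d/%d cells pass (%d removed)", len(table) - n_fail, len(table), n_fail)
    return CellQCMetrics(table=table, thresholds=thresholds)


def filter_cells(counts: CountMatrix, qc: CellQCMetrics) -> CountMatrix:
    """Keep the QC-passing columns of ``counts`` (order preserved)."""
    if not counts.sample_ids.equals(qc.table.index):
        raise ValidationError("QC metrics were not computed on these cells")
    passing = [c for c in counts.sample_ids if qc.table.at[c, "pass_qc"]]
    if not passing:
        raise EmptyResultError("no cells pass QC")
    return counts.subset_cells(passing)


def _column_sums(counts: CountMatrix) -> np.ndarray:
    sums = counts.values.to_numpy().sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(f"sample {counts.sample_ids[zero[0]]!r} has an all-zero column")
    return sums.astype(float)


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: each column scaled to sum to 10^6."""
    sums = _column_sums(counts)
    values = counts.values.astype(float) / sums * MILLION
    return ExpressionMatrix(values=values, scale="CPM")


def tpm_from_counts(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million from counts and annotated gene lengths.

    Each count is divided by the gene length in kilobases to form a
    per-base rate; rates are renormalized per sample to sum to 10^6.
    """
    lengths = counts.require_annotation("length_bp").to_numpy(dtype=float)
    _column_sums(counts)  # reject all-zero columns up front
    rates = counts.values.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    rate_sums = rates.sum(axis=0)
    values = pd.DataFrame(
        rates / rate_sums * MILLION, index=counts.gene_ids, columns=counts.sample_ids
    )
    return ExpressionMatrix(values=values, scale="TPM")


def _cluster_labels(clusters) -> pd.Series:
    """Accept a ClusterAssignment, mapping or Series of cell -> cluster."""
    labels = getattr(clusters, "labels", clusters)
    if not isinstance(labels, pd.Series):
        labels = pd.Series(dict(labels))
    return labels


def pseudobulk_counts(counts: CountMatrix, clusters) -> CountMatrix:
    """Sum counts across the member cells of each cluster.

    Cluster columns are named ``C<label>`` for integer labels and kept in
    sorted label order.
    """
    labels = _cluster_labels(clusters)
    missing = counts.sample_ids.difference(labels.index)
    if len(missing):
        raise ValidationError(f"cells without a cluster assignment: {missing[:3].tolist()}")
    labels = labels.loc[counts.sample_ids]
    summed = {}
    for lab in sorted(labels.unique()):
        members = labels.index[labels == lab]
        if len(members) == 0:
            raise EmptyResultError(f"cluster {lab!r} has no member cells")
        name = f"C{lab}" if not isinstance(lab, str) else lab
        summed[name] = counts.values[members].sum(axis=1)
    values = pd.DataFrame(summed, index=counts.gene_ids)
    return CountMatrix(values, gene_annotation=counts.gene_annotation)


def pseudobulk_tpm(counts: CountMatrix, clusters) -> ExpressionMatrix:
    """TPM of cluster pseudo-bulk profiles.

    Counts are summed across the cells of each cluster *first* and the
    summed matrix is TPM-normalized — never the mean of per-cell TPMs.
    """
    return tpm_from_counts(pseudobulk_counts(counts, clusters))


def filter_genes_expression(
    counts: CountMatrix, min_log2_cpm: float = 2.0, min_cells: int = 10
) -> pd.Index:
    """Genes with log2(CPM) above ``min_log2_cpm`` in at least ``min_cells`` cells.

    The comparison is applied on the linear CPM scale (CPM > 2**min_log2_cpm,
    strict), so zero counts need no pseudocount.  Returns kept genes in
    input order.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValidationError("empty count matrix")
    expr = cpm(counts).values.to_numpy()
    n_exceed = (expr > 2.0**min_log2_cpm).sum(axis=1)
    return counts.gene_ids[n_exceed >= min_cells]


def filter_genes_count(counts: CountMatrix, min_count: int = 10, min_cells: int = 10) -> pd.Index:
    """Genes with at least ``min_count`` counts in ``min_cells`` or more cells (inclusive)."""
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValidationError("empty count matrix")
    n_hit = (counts.values.to_numpy() >= min_count).sum(axis=1)
    return counts.gene_ids[n_hit >= min_cells]


def filter_genes_biotype(counts: CountMatrix, biotype: str = "protein_coding") -> pd.Index:
    """Genes whose annotated biotype equals ``biotype`` (input order)."""
    biotypes = counts.require_annotation("biotype")
    return counts.gene_ids[(biotypes == biotype).to_numpy()]


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) of a linear-scale matrix."""
    if expr.is_log:
        raise ValidationError(f"matrix is already on a log scale ({expr.scale})")
    arr = expr.values.to_numpy()
    if np.any(arr < 0):
        raise ValidationError("negative values cannot be log-transformed")
    values = pd.DataFrame(
        np.log2(arr + pseudocount), index=expr.values.index, columns=expr.values.columns
    )
    return ExpressionMatrix(
        values=values,
        scale=f"log2{expr.scale}",
        pseudocount=pseudocount,
        column_roles=expr.column_roles,
    )
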