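"""Core containers shared by every pipeline stage.

One orientation rule holds package-wide: matrices are genes x samples
(rows are genes; columns are cells, cluster pseudo-bulk profiles, bulk
samples or tissue replicates).  Annotation tables are aligned to the
matrix at construction time so downstream code may index positionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural contract (shape, sign, identifiers)."""


class DegenerateInputError(ValueError):
    """The input is structurally valid but carries no usable signal."""


class EmptyResultError(ValueError):
    """An operation produced an empty result where downstream stages need data."""


#: Columns required of a gene annotation table.
GENE_ANNOTATION_COLUMNS = ("symbol", "length_bp", "biotype", "is_mitochondrial")

#: Per-cell metadata fields consumed by quality control.
CELL_METADATA_COLUMNS = (
    "total_alignments",
    "mito_fraction",
    "detected_genes",
    "mrna_base_fraction",
)

#: Expression scales understood by the normalization layer.
VALID_SCALES = ("CPM", "log2CPM", "TPM", "log2TPM")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} identifiers: {dups}")


def _align(table: pd.DataFrame, index: pd.Index, what: str) -> pd.DataFrame:
    missing = index.difference(table.index)
    if len(missing):
        raise ValidationError(
            f"{what} table is missing {len(missing)} entries, e.g. {missing[:3].tolist()}"
        )
    return table.loc[index]


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
        Entries must be non-negative and integral (integer-valued floats
        are cast to ``int64``).
    gene_annotation
        Optional per-gene table (``symbol``, ``length_bp``, ``biotype``,
        ``is_mitochondrial``), indexed by gene identifier.  May cover a
        superset of the genes; it is subset and re-ordered to match.
    cell_metadata
        Optional per-sample table (QC metrics, genotype, provenance),
        indexed by sample identifier.
    """

    values: pd.DataFrame
    gene_annotation: pd.DataFrame | None = None
    cell_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "sample")
        arr = v.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("counts must be numeric")
            neg = np.argwhere(arr < 0)
            if neg.size:
                g, s = neg[0]
                raise ValidationError(
                    f"negative count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
                )
        if not np.issubdtype(arr.dtype, np.integer):
            frac = np.argwhere(np.mod(arr, 1) != 0)
            if frac.size:
                g, s = frac[0]
                raise ValidationError(
                    f"non-integer count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
                )
            self.values = v.astype(np.int64)
        if self.gene_annotation is not None:
            self.gene_annotation = _align(self.gene_annotation, v.index, "gene annotation")
            if "length_bp" in self.gene_annotation.columns:
                lengths = self.gene_annotation["length_bp"].to_numpy()
                if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
                    raise ValidationError("gene lengths must be positive")
        if self.cell_metadata is not None:
            self.cell_metadata = _align(self.cell_metadata, v.columns, "cell metadata")

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    # -- subsetting ----------------------------------------------------------

    def subset_genes(self, genes) -> "CountMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.gene_ids)
        if len(missing):
            raise ValidationError(f"unknown genes requested: {missing[:3].tolist()}")
        return CountMatrix(
            self.values.loc[genes],
            None if self.gene_annotation is None else self.gene_annotation.loc[genes],
            self.cell_metadata,
        )

    def subset_cells(self, cells) -> "CountMatrix":
        cells = pd.Index(cells)
        missing = cells.difference(self.sample_ids)
        if len(missing):
            raise ValidationError(f"unknown samples requested: {missing[:3].tolist()}")
        return CountMatrix(
            self.values[cells],
            self.gene_annotation,
            None if self.cell_metadata is None else self.cell_metadata.loc[cells],
        )

    def require_annotation(self, column: str) -> pd.Series:
        """Return an annotation column, raising a named error when absent."""
        if self.gene_annotation is None or column not in self.gene_annotation.columns:
            raise ValidationError(f"gene annotation column {column!r} is required")
        return self.gene_annotation[column]

    def require_metadata(self, column: str) -> pd.Series:
        if self.cell_metadata is None or column not in self.cell_metadata.columns:
            raise ValidationError(f"cell metadata column {column!r} is required")
        return self.cell_metadata[column]


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued expression on a declared scale.

    ``scale`` is one of ``CPM``, ``log2CPM``, ``TPM``, ``log2TPM``; the
    log scales record the pseudocount used.  ``column_roles`` optionally
    carries per-column provenance ("cluster", "bulk", "tissue") for
    matrices assembled from several sources.
    """

    values: pd.DataFrame
    scale: str
    pseudocount: float | None = None
    column_roles: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.is_log and self.pseudocount is None:
            raise ValidationError("log-scale matrices must record their pseudocount")
        if self.column_roles is not None:
            self.column_roles = _align(
                self.column_roles.to_frame("role"), self.values.columns, "column role"
            )["role"]

    @property
    def is_log(self) -> bool:
        return self.scale.startswith("log2")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index
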