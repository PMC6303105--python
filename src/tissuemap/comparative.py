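"""Cross-platform comparisons: fold-change correlation and signature PCA.

Two analyses sit here.  First, a deliberately simple differential
expression summary (CPM-pseudocount log2 fold change with a rank-sum
test) that produces the fold-change table used for the single-cell vs.
bulk Pearson correlation; the correlation step applies the bulk
mean-count filter and accepts any externally produced table with the
required columns.  Second, projection of expression profiles onto the
first two principal components of a named gene signature (e.g. the human
invasive-mucinous-adenocarcinoma signature), after cross-species symbol
matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .clustering import EmbeddingCoords
from .containers import (
    CountMatrix,
    EmptyResultError,
    ExpressionMatrix,
    ValidationError,
)
from .preprocess import cpm, filter_genes_count

logger = logging.getLogger(__name__)

DE_TABLE_COLUMNS = (
    "log2_fold_change",
    "mean_count_group_a",
    "mean_count_group_b",
    "p_value",
    "adjusted_p",
)


@dataclass
class SignatureList:
    """A flat list of gene symbols defining a published signature."""

    symbols: tuple[str, ...]
    species: str = "human"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("signature symbols must be unique")


def de_lfc(
    counts: CountMatrix,
    group_a,
    group_b,
    min_count: int = 10,
    min_cells: int = 10,
    source: str = "single_cell",
) -> pd.DataFrame:
    """Fold-change table between two sample groups.

    Genes are first filtered to those with at least ``min_count`` counts
    in ``min_cells`` or more of the compared samples.  The fold change is
    ``log2((mean CPM_a + 1) / (mean CPM_b + 1))``; p-values come from a
    two-sided rank-sum test on per-sample CPM, Benjamini-Hochberg
    adjusted.  The returned frame carries ``source`` in ``attrs``.
    """
    group_a, group_b = pd.Index(group_a), pd.Index(group_b)
    overlap = group_a.intersection(group_b)
    if len(overlap):
        raise ValidationError(f"groups overlap: {overlap[:3].tolist()}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    sub = counts.subset_cells(group_a.append(group_b))
    min_cells_eff = min(min_cells, sub.n_cells)
    kept = filter_genes_count(sub, min_count=min_count, min_cells=min_cells_eff)
    if kept.empty:
        raise EmptyResultError("no genes pass the count filter")
    sub = sub.subset_genes(kept)

    expr = cpm(sub).values
    A = expr[group_a].to_numpy()
    B = expr[group_b].to_numpy()
    lfc = np.log2((A.mean(axis=1) + 1.0) / (B.mean(axis=1) + 1.0))
    res = mannwhitneyu(A, B, axis=1, alternative="two-sided")
    adj = multipletests(res.pvalue, method="fdr_bh")[1]
    raw = counts.values
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "mean_count_group_a": raw.loc[kept, group_a].mean(axis=1),
            "mean_count_group_b": raw.loc[kept, group_b].mean(axis=1),
            "p_value": res.pvalue,
            "adjusted_p": adj,
        },
        index=kept,
    )
    table.attrs["source"] = source
    return table


def lfc_correlation(
    sc: pd.DataFrame,
    bulk: pd.DataFrame,
    min_bulk_mean: float = 1000.0,
    bulk_mean_mode: str = "group_mean",
) -> dict:
    """Pearson correlation of single-cell vs. bulk log2 fold changes.

    Gene sets are intersected; genes whose bulk average count is below
    ``min_bulk_mean`` (strict) are removed.  ``bulk_mean_mode`` selects
    how the bulk average is formed: ``group_mean`` (unweighted mean of
    the two group means, the default) or ``overall`` is provided for
    tables that carry a precomputed ``mean_count`` column.
    """
    for tbl, name in ((sc, "sc"), (bulk, "bulk")):
        if "log2_fold_change" not in tbl.columns:
            raise ValidationError(f"{name} table lacks a log2_fold_change column")
    shared = sc.index.intersection(bulk.index)
    if bulk_mean_mode == "group_mean":
        bulk_avg = (bulk["mean_count_group_a"] + bulk["mean_count_group_b"]) / 2.0
    elif bulk_mean_mode == "overall":
        bulk_avg = bulk["mean_count"]
    else:
        raise ValidationError(f"unknown bulk_mean_mode {bulk_mean_mode!r}")
    keep = [g for g in shared if bulk_avg[g] >= min_bulk_mean]
    if len(keep) < 3:
        raise EmptyResultError(
            f"only {len(keep)} genes survive the bulk mean-count filter; need >= 3"
        )
    pairs = pd.DataFrame(
        {
            "sc_lfc": sc.loc[keep, "log2_fold_change"],
            "bulk_lfc": bulk.loc[keep, "log2_fold_change"],
            "bulk_mean_count": bulk_avg.loc[keep],
        }
    )
    r, p = pearsonr(pairs["sc_lfc"], pairs["bulk_lfc"])
    logger.info("LFC correlation: r=%.3f over %d genes", r, len(keep))
    return {
        "r": float(r),
        "p_value": float(p),
        "n_genes": len(keep),
        "table": pairs,
        "sc_source": sc.attrs.get("source", "unknown"),
        "bulk_source": bulk.attrs.get("source", "unknown"),
    }


def project_on_signature(
    expr: ExpressionMatrix,
    signature: SignatureList,
    symbol_map: pd.Series | dict,
    pseudocount: float = 1.0,
) -> EmbeddingCoords:
    """PCA of samples restricted to a gene signature (first two components).

    ``symbol_map`` maps the matrix's gene identifiers to symbols; matching
    against the signature is case-insensitive (human vs. mouse symbol
    casing).  Input must be linear TPM; values are log2(x + pseudocount)
    before the column-centered PCA.
    """
    if expr.is_log:
        raise ValidationError("projection expects a linear TPM matrix")
    symbol_map = pd.Series(symbol_map)
    wanted = {s.upper() for s in signature.symbols}
    mapped = symbol_map.reindex(expr.gene_ids).dropna()
    hits = mapped.index[[str(s).upper() in wanted for s in mapped]]
    if len(hits) < 2:
        found = {str(symbol_map.get(g, "")).upper() for g in hits}
        missing = sorted(wanted - found)
        raise EmptyResultError(
            f"only {len(hits)} signature genes present (need >= 2 for a 2-component PCA); "
            f"unmatched symbols e.g. {missing[:5]}"
        )
    X = np.log2(expr.values.loc[hits].to_numpy().T + pseudocount)  # samples x genes
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(coords, index=expr.sample_ids, columns=["x", "y"])
    params = {
        "n_signature_genes": int(len(hits)),
        "explained_variance": tuple(float(v) for v in pca.explained_variance_ratio_),
        "pseudocount": pseudocount,
    }
    return EmbeddingCoords(coords=frame, method="pca", params=params)
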