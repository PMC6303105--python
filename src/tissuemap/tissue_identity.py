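"""Tissue-enriched signatures and cluster-to-tissue classification.

This is the bespoke heart of the pipeline: given a reference panel of
normal-tissue expression and cluster pseudo-bulk TPM profiles, build
per-tissue signatures by mean-centered average log2 expression, restrict
all profiles to the signature gene union, and compare every cluster to
every tissue three ways — cosine similarity (the quantitative call),
hierarchical clustering on principal components (HCPC), and a seeded
t-SNE of the combined matrix.

Signature rule: for each gene, average its log2 expression within each
tissue, subtract the across-tissue mean, and assign the gene to the tissue
where the centered value is maximal, with that value as its enrichment
score.  Genes whose centered profile ties at the maximum (including
all-constant genes) carry no tissue information and are excluded.  Each
tissue's assigned genes are ranked by score and the top ``top_n`` kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .clustering import ClusterAssignment, EmbeddingCoords, embed_tsne
from .containers import (
    CountMatrix,
    DegenerateInputError,
    EmptyResultError,
    ExpressionMatrix,
    ValidationError,
)
from .preprocess import (
    filter_genes_biotype,
    filter_genes_count,
    log_transform,
    pseudobulk_tpm,
    tpm_from_counts,
)

logger = logging.getLogger(__name__)

MILLION = 1_000_000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TissuePanel:
    """Reference tissue expression: genes x (tissue replicate) columns."""

    values: pd.DataFrame
    tissue_of_sample: pd.Series

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.tissue_of_sample.index)
        if len(missing):
            raise ValidationError(f"samples without a tissue label: {missing[:3].tolist()}")
        self.tissue_of_sample = self.tissue_of_sample.loc[self.values.columns]
        if self.tissue_of_sample.nunique() < 2:
            raise ValidationError("a tissue panel needs at least two tissues")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.tissue_of_sample.unique())

    def tissue_mean(self) -> pd.DataFrame:
        """Average replicate columns within each tissue (linear scale)."""
        return self.values.T.groupby(self.tissue_of_sample).mean().T


@dataclass
class TissueSignature:
    """Per-tissue ranked gene lists with mean-centered enrichment scores.

    ``assignment`` is a table (gene index; tissue, score, rank) holding
    only the genes that made a top-``top_n`` list; lists are pairwise
    disjoint by construction.
    """

    assignment: pd.DataFrame
    top_n: int

    def genes_for(self, tissue: str) -> list[str]:
        sub = self.assignment[self.assignment["tissue"] == tissue]
        return sub.sort_values("rank").index.tolist()

    @property
    def tissues(self) -> list[str]:
        return sorted(self.assignment["tissue"].unique())

    @property
    def gene_union(self) -> pd.Index:
        return self.assignment.index


@dataclass
class SimilarityMatrix:
    """Query x tissue cosine similarities with per-query argmax and margin."""

    values: pd.DataFrame
    best_tissue: pd.Series
    margin: pd.Series


@dataclass
class HCPCResult:
    """Hierarchical clustering on principal components."""

    component_scores: pd.DataFrame
    linkage: np.ndarray
    partition: pd.Series
    explained_variance: np.ndarray
    n_clusters: int


@dataclass
class TissueClassification:
    """Bundle of the three classification views over one combined matrix."""

    similarity: SimilarityMatrix
    hcpc: HCPCResult
    embedding: EmbeddingCoords
    signature: TissueSignature
    combined: ExpressionMatrix
    genes_used: pd.Index


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def tissue_enriched_genes(
    panel_log2: ExpressionMatrix,
    tissue_map: pd.Series | dict,
    top_n: int = 70,
) -> TissueSignature:
    """Build per-tissue signatures from a log2-scale panel.

    Replicate columns of the same tissue are averaged first; the centered
    score of a gene sums to zero across tissues by construction.
    """
    if not panel_log2.is_log:
        raise ValidationError("signature construction expects a log2-scale panel")
    tissue_map = pd.Series(tissue_map)
    missing = panel_log2.sample_ids.difference(tissue_map.index)
    if len(missing):
        raise ValidationError(f"samples without a tissue label: {missing[:3].tolist()}")
    tissue_map = tissue_map.loc[panel_log2.sample_ids]
    if tissue_map.nunique() < 2:
        raise DegenerateInputError("mean-centering is identically zero for a single tissue")
    if top_n <= 0:
        raise ValidationError("top_n must be positive")

    means = panel_log2.values.T.groupby(tissue_map).mean().T  # gene x tissue
    centered = means.sub(means.mean(axis=1), axis=0)
    arr = centered.to_numpy()
    max_val = arr.max(axis=1)
    ties = (arr == max_val[:, None]).sum(axis=1) > 1
    best = centered.columns.to_numpy()[np.argmax(arr, axis=1)]

    assigned = pd.DataFrame(
        {"tissue": best, "score": max_val}, index=centered.index
    ).loc[~ties]
    parts = []
    for tissue, sub in assigned.groupby("tissue"):
        # rank by descending enrichment score; gene id breaks exact ties
        order = np.lexsort((sub.index.to_numpy(), -sub["score"].to_numpy()))
        sub = sub.iloc[order].head(top_n).copy()
        sub["rank"] = np.arange(1, len(sub) + 1)
        parts.append(sub)
    if parts:
        assignment = pd.concat(parts)
    else:
        assignment = pd.DataFrame(columns=["tissue", "score", "rank"])
    return TissueSignature(assignment=assignment, top_n=top_n)


def combine_profiles(
    cluster_tpm: ExpressionMatrix,
    panel_tpm: ExpressionMatrix,
    signature: TissueSignature,
    bulk_tpm: ExpressionMatrix | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Intersect all profiles on the signature gene union and log-transform.

    Columns are cluster pseudo-bulks, then optional bulk samples, then
    tissue columns; ``column_roles`` records which is which.  Values are
    log2(TPM + pseudocount).
    """
    for m, name in ((cluster_tpm, "cluster"), (panel_tpm, "panel")):
        if m.is_log:
            raise ValidationError(f"{name} profiles must be on the linear TPM scale")
    sources = [("cluster", cluster_tpm)]
    if bulk_tpm is not None:
        if bulk_tpm.is_log:
            raise ValidationError("bulk profiles must be on the linear TPM scale")
        sources.append(("bulk", bulk_tpm))
    sources.append(("tissue", panel_tpm))

    sig_genes = set(signature.gene_union)
    keep = [g for g in cluster_tpm.gene_ids if g in sig_genes]
    for _, m in sources[1:]:
        present = set(m.gene_ids)
        keep = [g for g in keep if g in present]
    if not keep:
        raise EmptyResultError("no signature genes shared by all profiles")

    blocks, roles = [], {}
    for role, m in sources:
        blocks.append(m.values.loc[keep])
        for col in m.sample_ids:
            roles[col] = role
    values = pd.concat(blocks, axis=1)
    linear = ExpressionMatrix(values=values, scale="TPM", column_roles=pd.Series(roles))
    return log_transform(linear, pseudocount=pseudocount)


def cosine_similarity(
    combined: ExpressionMatrix,
    query_cols,
    reference_cols,
) -> SimilarityMatrix:
    """Cosine similarity of every query column against every reference column."""
    query_cols, reference_cols = pd.Index(query_cols), pd.Index(reference_cols)
    overlap = query_cols.intersection(reference_cols)
    if len(overlap):
        raise ValidationError(f"query and reference columns overlap: {overlap[:3].tolist()}")
    for cols in (query_cols, reference_cols):
        missing = cols.difference(combined.sample_ids)
        if len(missing):
            raise ValidationError(f"unknown columns: {missing[:3].tolist()}")
    Q = combined.values[query_cols].to_numpy().T
    R = combined.values[reference_cols].to_numpy().T
    for cols, block in ((query_cols, Q), (reference_cols, R)):
        norms = np.linalg.norm(block, axis=1)
        dead = np.flatnonzero(norms == 0)
        if dead.size:
            raise ValidationError(f"column {cols[dead[0]]!r} has zero norm")
    values = pd.DataFrame(_sk_cosine(Q, R), index=query_cols, columns=reference_cols)
    best = values.idxmax(axis=1)
    if values.shape[1] >= 2:
        sorted_vals = np.sort(values.to_numpy(), axis=1)
        margin = pd.Series(sorted_vals[:, -1] - sorted_vals[:, -2], index=query_cols)
    else:
        margin = pd.Series(np.nan, index=query_cols)
    return SimilarityMatrix(values=values, best_tissue=best, margin=margin)


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def hcpc(
    combined: ExpressionMatrix,
    n_components: int = 5,
    scale: bool = False,
    max_k: int = 10,
) -> HCPCResult:
    """Hierarchical clustering on principal components of the columns.

    Columns are the observations.  Features (genes) are centered — and
    variance-scaled only if ``scale`` — before PCA; Ward linkage is built
    on Euclidean distances between component scores, and the partition
    cuts the tree at the number of clusters maximizing the relative
    inertia-gain ratio (W(k-1) - W(k)) / (W(k) - W(k+1)).
    """
    X = combined.values.to_numpy().T  # samples x genes
    n = X.shape[0]
    if n < 3:
        raise ValidationError(f"HCPC needs at least 3 samples, got {n}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    d = max(1, min(n_components, rank))
    scores = U[:, :d] * S[:d]
    var = S**2
    explained = var[:d] / var.sum() if var.sum() > 0 else np.zeros(d)

    Z = linkage(scores, method="ward")
    kmax = min(max_k, n - 1)
    W = {k: _within_inertia(scores, fcluster(Z, t=k, criterion="maxclust")) for k in range(1, kmax + 2)}
    eps = 1e-12 * max(W[1], 1e-300)
    best_k, best_q = 2, -np.inf
    for k in range(2, kmax + 1):
        num, den = W[k - 1] - W[k], W[k] - W[k + 1]
        if den <= eps:
            q = np.inf if num > eps else -np.inf
        else:
            q = num / den
        if q > best_q:
            best_k, best_q = k, q
    raw = fcluster(Z, t=best_k, criterion="maxclust")
    order = {lab: i + 1 for i, lab in enumerate(pd.unique(raw))}
    partition = pd.Series([order[v] for v in raw], index=combined.sample_ids, name="hcpc_cluster")
    score_df = pd.DataFrame(
        scores, index=combined.sample_ids, columns=[f"PC{i + 1}" for i in range(d)]
    )
    return HCPCResult(
        component_scores=score_df,
        linkage=Z,
        partition=partition,
        explained_variance=explained,
        n_clusters=int(partition.max()),
    )


def classify_clusters(
    counts: CountMatrix,
    clusters: ClusterAssignment | pd.Series,
    panel: TissuePanel,
    bulk_counts: CountMatrix | None = None,
    top_n: int = 70,
    perplexity: float = 13.0,
    initial_dims: int = 5,
    n_components: int = 5,
    biotype: str = "protein_coding",
    min_count: int = 10,
    min_cells: int = 10,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> TissueClassification:
    """Full cluster-to-tissue classification.

    Genes are restricted to the annotated biotype with at least
    ``min_count`` counts in ``min_cells`` or more cells, intersected with
    the panel (and bulk, when given); cluster pseudo-bulk TPM is computed
    by summing member counts; tissue replicates are averaged; signatures
    built; and the combined signature-restricted matrix is scored by
    cosine similarity, HCPC and t-SNE with a single seed.

    The t-SNE perplexity is reduced when the combined matrix has too few
    columns for the requested value (3 * perplexity must stay below the
    column count).
    """
    genes_bio = set(filter_genes_biotype(counts, biotype))
    genes_cnt = set(filter_genes_count(counts, min_count=min_count, min_cells=min_cells))
    keep = [g for g in counts.gene_ids if g in genes_bio and g in genes_cnt]
    panel_genes = set(panel.values.index)
    keep = [g for g in keep if g in panel_genes]
    if bulk_counts is not None:
        bulk_genes = set(bulk_counts.gene_ids)
        keep = [g for g in keep if g in bulk_genes]
    if not keep:
        raise EmptyResultError("no genes survive the biotype/count/panel intersection")
    logger.info("classification gene set: %d of %d genes", len(keep), counts.n_genes)

    cluster_tpm = pseudobulk_tpm(counts.subset_genes(keep), clusters)
    panel_mean = panel.tissue_mean().loc[keep]
    panel_tpm = ExpressionMatrix(values=panel_mean, scale="TPM")
    panel_log2 = log_transform(panel_tpm, pseudocount=pseudocount)
    tissue_map = pd.Series({t: t for t in panel_mean.columns})
    signature = tissue_enriched_genes(panel_log2, tissue_map, top_n=top_n)

    bulk_tpm = None
    if bulk_counts is not None:
        bulk_tpm = tpm_from_counts(bulk_counts.subset_genes(keep))

    combined = combine_profiles(
        cluster_tpm, panel_tpm, signature, bulk_tpm=bulk_tpm, pseudocount=pseudocount
    )
    roles = combined.column_roles
    queries = roles.index[roles.isin(["cluster", "bulk"])]
    references = roles.index[roles == "tissue"]
    similarity = cosine_similarity(combined, queries, references)
    hcpc_result = hcpc(combined, n_components=n_components, scale=False)

    n_cols = combined.values.shape[1]
    eff_perplexity = min(perplexity, (n_cols - 1) / 3.0)
    if eff_perplexity < perplexity:
        logger.info(
            "perplexity reduced from %s to %.2f for %d columns", perplexity, eff_perplexity, n_cols
        )
    embedding = embed_tsne(
        combined, perplexity=eff_perplexity, initial_dims=initial_dims, seed=seed
    )
    return TissueClassification(
        similarity=similarity,
        hcpc=hcpc_result,
        embedding=embedding,
        signature=signature,
        combined=combined,
        genes_used=pd.Index(keep),
    )
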