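"""Consensus clustering of cells, marker detection, and 2-D embeddings.

The consensus scheme is a compact re-implementation of the SC3-style
procedure: for every combination of cell-cell distance (Euclidean, Pearson,
Spearman), matrix transform (PCA of the distance matrix, or the normalized
graph Laplacian) and a grid of retained dimensions (4-7% of the number of
cells), seeded k-means is run and the binary co-clustering indicator
recorded; the consensus matrix is the mean over runs and the final
partition cuts a complete-linkage dendrogram of the consensus at k.
No internal gene filtering is performed ("gene filtering turned off"):
every gene of the input matrix participates.

Markers are genes that separate one cluster from all remaining cells:
one-vs-rest AUROC plus a Wilcoxon rank-sum test, Holm-adjusted across
genes; a gene can be a marker of at most one cluster (its AUROC argmax).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from ._rng import stage_int_seed
from .containers import (
    CountMatrix,
    DegenerateInputError,
    EmptyResultError,
    ExpressionMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

DISTANCES = ("euclidean", "pearson", "spearman")
TRANSFORMS = ("pca", "laplacian")


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels (1..k) plus the consensus co-clustering matrix."""

    labels: pd.Series
    k: int
    consensus: pd.DataFrame
    params: dict = field(default_factory=dict)

    def members(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class EmbeddingCoords:
    """2-D embedding, one (x, y) pair per input sample."""

    coords: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)


def _correlation_distance(X: np.ndarray, method: str) -> np.ndarray:
    """1 - correlation between rows of X; degenerate rows get distance 1."""
    if method == "spearman":
        X = rankdata(X, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return 1.0 - corr


def _distance_matrix(X: np.ndarray, method: str) -> np.ndarray:
    if method == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    if method in ("pearson", "spearman"):
        return _correlation_distance(X, method)
    raise ValidationError(f"unknown distance {method!r}")


def _pca_scores(D: np.ndarray) -> np.ndarray:
    """PCA of the distance matrix itself (columns standardized), all components."""
    Z = D - D.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    return U * S


def _laplacian_scores(D: np.ndarray) -> np.ndarray:
    """Eigenvectors (ascending eigenvalue) of the normalized graph Laplacian."""
    scale = D.max()
    A = np.exp(-D / scale) if scale > 0 else np.ones_like(D)
    deg = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(len(D)) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh((L + L.T) / 2.0)
    return vecs


def _dimension_grid(n_cells: int, low: float, high: float) -> list[int]:
    lo = max(2, math.floor(low * n_cells))
    hi = min(n_cells - 1, math.ceil(high * n_cells))
    grid = list(range(lo, hi + 1))
    if not grid:
        grid = [min(max(2, round((low + high) / 2 * n_cells)), n_cells - 1)]
    return grid


def consensus_cluster(
    logexpr: ExpressionMatrix,
    k: int,
    seed: int = 0,
    distances: tuple[str, ...] = DISTANCES,
    transforms: tuple[str, ...] = TRANSFORMS,
    dim_fraction_range: tuple[float, float] = (0.04, 0.07),
) -> ClusterAssignment:
    """Consensus k-means clustering of the columns (cells) of ``logexpr``.

    Deterministic given ``seed``; evaluation of results should use the
    adjusted Rand index (labels are arbitrary up to permutation).
    """
    if not logexpr.is_log:
        raise ValidationError("consensus clustering expects a log-scale matrix")
    cells = logexpr.sample_ids
    n = len(cells)
    if not 2 <= k <= n:
        raise ValidationError(f"k={k} must be between 2 and the number of cells ({n})")
    for d in distances:
        if d not in DISTANCES:
            raise ValidationError(f"unknown distance {d!r}")
    for t in transforms:
        if t not in TRANSFORMS:
            raise ValidationError(f"unknown transform {t!r}")
    X = logexpr.values.to_numpy().T  # cells x genes
    if np.ptp(X) == 0:
        raise DegenerateInputError("constant expression matrix cannot be clustered")

    params = {
        "distances": tuple(distances),
        "transforms": tuple(transforms),
        "dim_fraction_range": tuple(dim_fraction_range),
        "seed": seed,
    }

    if k == n:  # forced partition: every cell its own cluster
        labels = pd.Series(np.arange(1, n + 1), index=cells, name="cluster")
        consensus = pd.DataFrame(np.eye(n), index=cells, columns=cells)
        return ClusterAssignment(labels=labels, k=k, consensus=consensus, params=params)

    grid = _dimension_grid(n, *dim_fraction_range)
    consensus = np.zeros((n, n))
    run = 0
    for dist_name in distances:
        D = _distance_matrix(X, dist_name)
        for transform in transforms:
            scores = _pca_scores(D) if transform == "pca" else _laplacian_scores(D)
            for d in grid:
                d_eff = min(d, scores.shape[1])
                km = KMeans(
                    n_clusters=k,
                    n_init=10,
                    random_state=stage_int_seed(seed, "consensus", run),
                )
                lab = km.fit_predict(scores[:, :d_eff])
                consensus += lab[:, None] == lab[None, :]
                run += 1
    consensus /= run

    condensed = squareform(1.0 - (consensus + consensus.T) / 2.0, checks=False)
    Z = linkage(condensed, method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # stable relabeling: clusters numbered by first appearance
    order = {lab: i + 1 for i, lab in enumerate(pd.unique(raw))}
    labels = pd.Series([order[v] for v in raw], index=cells, name="cluster")
    consensus_df = pd.DataFrame(consensus, index=cells, columns=cells)
    logger.info("consensus clustering: %d cells, k=%d, %d runs", n, k, run)
    return ClusterAssignment(labels=labels, k=int(labels.max()), consensus=consensus_df, params=params)


def find_markers(
    logexpr: ExpressionMatrix,
    clusters: ClusterAssignment,
    min_auroc: float = 0.85,
    max_p: float = 0.01,
) -> pd.DataFrame:
    """Per-gene one-vs-rest marker statistics.

    Returns a table indexed by gene with columns ``cluster`` (the AUROC
    argmax), ``auroc``, ``p_value`` (one-sided rank-sum), ``adjusted_p``
    (Holm, across genes) and ``is_marker``.  Size-1 clusters are skipped
    with a logged warning.
    """
    labels = clusters.labels.loc[logexpr.sample_ids]
    cluster_ids = sorted(labels.unique())
    usable = []
    for c in cluster_ids:
        if (labels == c).sum() < 2:
            logger.warning("cluster %s has a single cell; skipped in marker detection", c)
        else:
            usable.append(c)
    if len(usable) < 2:
        raise ValidationError("marker detection needs at least two clusters of size >= 2")

    V = logexpr.values.to_numpy()
    ranks = rankdata(V, axis=1)
    n = V.shape[1]
    aurocs = {}
    pvals = {}
    for c in usable:
        mask = (labels == c).to_numpy()
        n1 = int(mask.sum())
        n2 = n - n1
        aurocs[c] = (ranks[:, mask].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n2)
        res = mannwhitneyu(V[:, mask], V[:, ~mask], axis=1, alternative="greater")
        pvals[c] = res.pvalue
    auroc_mat = np.column_stack([aurocs[c] for c in usable])
    best_idx = np.argmax(auroc_mat, axis=1)
    best_cluster = np.array(usable)[best_idx]
    best_auroc = auroc_mat[np.arange(len(best_idx)), best_idx]
    best_p = np.column_stack([pvals[c] for c in usable])[np.arange(len(best_idx)), best_idx]
    adj_p = multipletests(best_p, method="holm")[1]

    table = pd.DataFrame(
        {
            "cluster": best_cluster,
            "auroc": best_auroc,
            "p_value": best_p,
            "adjusted_p": adj_p,
        },
        index=logexpr.gene_ids,
    )
    table["is_marker"] = (table["auroc"] >= min_auroc) & (table["adjusted_p"] <= max_p)
    return table


def embed_tsne(
    matrix: ExpressionMatrix,
    perplexity: float = 13.0,
    initial_dims: int = 5,
    seed: int = 0,
) -> EmbeddingCoords:
    """t-SNE of the columns of ``matrix``: PCA to ``initial_dims``, then 2-D t-SNE.

    Requires ``3 * perplexity < n_samples``.  Deterministic for a fixed
    seed and input on one platform.
    """
    X = matrix.values.to_numpy().T
    n = X.shape[0]
    if initial_dims < 2:
        raise ValidationError("initial_dims must be at least 2")
    if 3.0 * perplexity >= n:
        raise ValidationError(
            f"perplexity {perplexity} too large: need 3*perplexity < n_samples ({n})"
        )
    n_comp = min(initial_dims, n - 1, X.shape[1])
    reduced = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        learning_rate="auto",
        random_state=stage_int_seed(seed, "tsne"),
    ).fit_transform(reduced)
    frame = pd.DataFrame(coords, index=matrix.sample_ids, columns=["x", "y"])
    params = {"perplexity": perplexity, "initial_dims": initial_dims, "seed": seed}
    return EmbeddingCoords(coords=frame, method="tsne", params=params)


def merge_external_cells(
    a: CountMatrix,
    b: CountMatrix,
    labels: tuple[str, str] = ("primary", "external"),
) -> CountMatrix:
    """Column-concatenate two count matrices on their shared genes.

    Gene order follows ``a``; a per-cell ``provenance`` column records the
    source of every cell.
    """
    shared = a.gene_ids[a.gene_ids.isin(b.gene_ids)]
    if shared.empty:
        raise EmptyResultError("the two matrices share no genes")
    values = pd.concat([a.values.loc[shared], b.values.loc[shared]], axis=1)
    meta_parts = []
    for m, ids, lab in ((a, a.sample_ids, labels[0]), (b, b.sample_ids, labels[1])):
        meta = m.cell_metadata.copy() if m.cell_metadata is not None else pd.DataFrame(index=ids)
        meta["provenance"] = lab
        meta_parts.append(meta)
    metadata = pd.concat(meta_parts, axis=0)
    annotation = None if a.gene_annotation is None else a.gene_annotation.loc[shared]
    return CountMatrix(values, gene_annotation=annotation, cell_metadata=metadata)
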