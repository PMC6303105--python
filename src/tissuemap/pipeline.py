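"""End-to-end orchestration: QC -> normalize -> cluster -> classify -> compare.

``run_pipeline`` executes the stages in order on in-memory objects and
(optionally) writes every stage output plus a JSON run manifest.  The
manifest records the configuration, seed, input checksums, per-stage
row/column counts and output checksums — enough to replay a run
bit-identically on one platform — and deliberately contains no wallclock
information, so replays produce byte-identical manifests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from .clustering import ClusterAssignment, EmbeddingCoords, consensus_cluster, embed_tsne, find_markers
from .comparative import SignatureList, de_lfc, lfc_correlation, project_on_signature
from .config import PipelineConfig
from .containers import CountMatrix, ValidationError
from .preprocess import (
    CellQCMetrics,
    QCThresholds,
    compute_cell_qc,
    cpm,
    filter_cells,
    filter_genes_expression,
    log_transform,
    tpm_from_counts,
)
from .synthdata import StudyData, simulate_study
from .tissue_identity import TissueClassification, TissuePanel, classify_clusters

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineResult:
    manifest: dict
    qc: CellQCMetrics
    clusters: ClusterAssignment
    markers: pd.DataFrame
    classification: TissueClassification
    cell_embedding: EmbeddingCoords | None = None
    sc_de: pd.DataFrame | None = None
    bulk_de: pd.DataFrame | None = None
    correlation: dict | None = None
    projection: EmbeddingCoords | None = None


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})
    logger.info("stage %s: %s", name, counts)


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix,
    panel: TissuePanel,
    bulk_counts: CountMatrix | None = None,
    signature: SignatureList | None = None,
    outdir: str | Path | None = None,
    input_checksums: dict | None = None,
) -> PipelineResult:
    """Run the full analysis.  See the module docstring for stage order.

    ``signature`` (optional) triggers the signature-restricted PCA of the
    QC-passing cells; symbols are matched against the count matrix's
    annotated gene symbols.  When ``bulk_counts`` carries a ``group``
    metadata column with two levels, the single-cell vs. bulk fold-change
    correlation is computed between the first two clusters.
    """
    config.validate()
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
        "input_checksums": input_checksums or {},
        "stages": [],
        "outputs": {},
    }

    # --- cell QC ------------------------------------------------------------
    thresholds = QCThresholds(
        max_mito=config.max_mito,
        min_alignments=config.min_alignments,
        min_genes=config.min_genes,
        min_mrna=config.min_mrna,
    )
    qc = compute_cell_qc(counts, thresholds)
    filtered = filter_cells(counts, qc)
    _stage(manifest, "cell_qc", cells_in=counts.n_cells, cells_out=filtered.n_cells)

    # --- expression gene filter + log2 CPM for clustering ---------------------
    genes_expr = filter_genes_expression(
        filtered, min_log2_cpm=config.min_log2_cpm, min_cells=config.min_cells_expression
    )
    if genes_expr.empty:
        raise ValidationError("no genes pass the expression filter")
    clustering_input = log_transform(
        cpm(filtered.subset_genes(genes_expr)), pseudocount=config.pseudocount
    )
    _stage(manifest, "gene_filter_expression", genes_in=filtered.n_genes, genes_out=len(genes_expr))

    # --- consensus clustering + markers --------------------------------------
    clusters = consensus_cluster(
        clustering_input,
        k=config.k,
        seed=config.seed,
        distances=config.distances,
        transforms=config.transforms,
        dim_fraction_range=(config.dim_fraction_low, config.dim_fraction_high),
    )
    markers = find_markers(
        clustering_input, clusters, min_auroc=config.min_auroc, max_p=config.max_p
    )
    _stage(
        manifest,
        "clustering",
        cells=filtered.n_cells,
        k=clusters.k,
        cluster_sizes=clusters.sizes.to_dict(),
        n_markers=int(markers["is_marker"].sum()),
    )

    # --- seeded 2-D embedding of the cells -----------------------------------
    n_cells = clustering_input.values.shape[1]
    cell_perplexity = min(config.perplexity, (n_cells - 1) / 3.0)
    cell_embedding = embed_tsne(
        clustering_input,
        perplexity=cell_perplexity,
        initial_dims=max(config.initial_dims, 2),
        seed=config.seed,
    )

    # --- tissue classification ------------------------------------------------
    classification = classify_clusters(
        filtered,
        clusters,
        panel,
        bulk_counts=bulk_counts,
        top_n=config.top_n,
        perplexity=config.perplexity,
        initial_dims=config.initial_dims,
        n_components=config.n_components,
        biotype=config.biotype,
        min_count=config.min_count,
        min_cells=config.min_cells_count,
        pseudocount=config.pseudocount,
        seed=config.seed,
    )
    _stage(
        manifest,
        "tissue_classification",
        genes_used=len(classification.genes_used),
        signature_genes=len(classification.signature.gene_union),
        best_tissue=classification.similarity.best_tissue.to_dict(),
    )

    # --- single-cell vs. bulk fold-change correlation -------------------------
    sc_de = bulk_de = None
    correlation = None
    if bulk_counts is not None and bulk_counts.cell_metadata is not None \
            and "group" in bulk_counts.cell_metadata.columns:
        groups = bulk_counts.cell_metadata["group"]
        levels = sorted(groups.unique())
        if len(levels) == 2 and clusters.k >= 2:
            cells_a = clusters.members(1)
            cells_b = clusters.members(2)
            sc_de = de_lfc(
                filtered, cells_a, cells_b,
                min_count=config.min_count, min_cells=config.min_cells_count,
                source="single_cell",
            )
            bulk_de = de_lfc(
                bulk_counts,
                groups.index[groups == levels[0]],
                groups.index[groups == levels[1]],
                min_count=config.min_count, min_cells=config.min_cells_count,
                source="bulk",
            )
            correlation = lfc_correlation(sc_de, bulk_de, min_bulk_mean=config.min_bulk_mean)
            _stage(
                manifest,
                "lfc_correlation",
                r=correlation["r"],
                n_genes=correlation["n_genes"],
            )

    # --- signature-restricted PCA ---------------------------------------------
    projection = None
    if signature is not None:
        symbol_map = filtered.require_annotation("symbol")
        cell_tpm = tpm_from_counts(filtered)
        projection = project_on_signature(
            cell_tpm, signature, symbol_map, pseudocount=config.pseudocount
        )
        _stage(
            manifest,
            "signature_projection",
            n_signature_genes=projection.params["n_signature_genes"],
        )

    result = PipelineResult(
        manifest=manifest,
        qc=qc,
        clusters=clusters,
        markers=markers,
        classification=classification,
        cell_embedding=cell_embedding,
        sc_de=sc_de,
        bulk_de=bulk_de,
        correlation=correlation,
        projection=projection,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_frame(frame: pd.DataFrame, path: Path, index_name: str) -> None:
    out = frame.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_frame(result.qc.table, outdir / "cell_qc.tsv", "cell_id")
    _write_frame(result.clusters.labels.to_frame(), outdir / "clusters.tsv", "cell_id")
    _write_frame(result.clusters.consensus, outdir / "consensus.tsv", "cell_id")
    _write_frame(result.markers, outdir / "markers.tsv", "gene_id")
    tio.write_signature(result.classification.signature, outdir / "signature.tsv")
    tio.write_similarity(result.classification.similarity, outdir / "similarity.tsv")
    _write_frame(
        result.classification.hcpc.partition.to_frame(), outdir / "hcpc_partition.tsv", "sample"
    )
    _write_frame(
        result.classification.hcpc.component_scores, outdir / "hcpc_scores.tsv", "sample"
    )
    _write_frame(result.classification.embedding.coords, outdir / "combined_tsne.tsv", "sample")
    if result.cell_embedding is not None:
        _write_frame(result.cell_embedding.coords, outdir / "cell_tsne.tsv", "cell_id")
    if result.sc_de is not None:
        tio.write_de_table(result.sc_de, outdir / "sc_de.tsv")
    if result.bulk_de is not None:
        tio.write_de_table(result.bulk_de, outdir / "bulk_de.tsv")
    if result.correlation is not None:
        _write_frame(result.correlation["table"], outdir / "lfc_pairs.tsv", "gene_id")
        tio.write_json(
            {k: result.correlation[k] for k in ("r", "p_value", "n_genes", "sc_source", "bulk_source")},
            outdir / "lfc_correlation.json",
        )
    if result.projection is not None:
        _write_frame(result.projection.coords, outdir / "signature_pca.tsv", "cell_id")
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            result.manifest["outputs"][f.name] = tio.sha256_file(f)
    tio.write_json(result.manifest, outdir / "manifest.json")


# ---------------------------------------------------------------------------
# dataset directories (as produced by `tissuemap simulate`)
# ---------------------------------------------------------------------------


def write_dataset(study: StudyData, outdir: str | Path, fmt: str = "mtx") -> Path:
    """Write a simulated study as a dataset directory with ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_counts(study.counts, outdir / "counts", fmt=fmt)
    tio.write_panel(study.panel, outdir / "panel.tsv", outdir / "tissues.tsv")
    if study.bulk_counts is not None:
        tio.write_counts(study.bulk_counts, outdir / "bulk", fmt=fmt)
    truth = pd.concat(
        [study.truth.cell_program, study.truth.cell_cluster], axis=1
    )
    truth["qc_fail_rule"] = pd.Series(study.truth.qc_fail_cells).reindex(truth.index).fillna("")
    _write_frame(truth, outdir / "truth_cells.tsv", "cell_id")
    markers = pd.DataFrame(
        [(t, g) for t, genes in study.truth.planted_markers.items() for g in genes],
        columns=["tissue", "gene_id"],
    )
    markers.to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
    if study.bulk_truth is not None:
        _write_frame(study.bulk_truth, outdir / "truth_bulk_lfc.tsv", "gene_id")
    return outdir


def load_dataset(path: str | Path) -> tuple[CountMatrix, TissuePanel, CountMatrix | None]:
    path = Path(path)
    counts = tio.read_counts(path / "counts")
    panel = tio.read_panel(path / "panel.tsv", path / "tissues.tsv")
    bulk = tio.read_counts(path / "bulk") if (path / "bulk").exists() else None
    return counts, panel, bulk


def run_pipeline_from_paths(
    config: PipelineConfig,
    dataset: str | Path,
    outdir: str | Path,
    signature_path: str | Path | None = None,
) -> PipelineResult:
    """Load a dataset directory, checksum the inputs, and run the pipeline."""
    dataset = Path(dataset)
    counts, panel, bulk = load_dataset(dataset)
    checksums = {
        str(f.relative_to(dataset)): tio.sha256_file(f)
        for f in sorted(dataset.rglob("*"))
        if f.is_file()
    }
    signature = None
    if signature_path is not None:
        signature = SignatureList(symbols=tuple(tio.read_signature_list(signature_path)))
    return run_pipeline(
        config,
        counts,
        panel,
        bulk_counts=bulk,
        signature=signature,
        outdir=outdir,
        input_checksums=checksums,
    )
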