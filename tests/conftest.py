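import numpy as np
import pandas as pd
import pytest

import tissuemap as tm
from tissuemap.synthdata import ClusterSpec, SimulationSpec, make_programs


def random_counts(
    rng: np.random.Generator,
    n_genes: int = 50,
    n_cells: int = 30,
    max_count: int = 40,
    with_annotation: bool = True,
    with_metadata: bool = False,
) -> tm.CountMatrix:
    """A random integer count matrix with optional annotation/metadata."""
    genes = pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id")
    cells = pd.Index([f"c{i:03d}" for i in range(n_cells)], name="cell_id")
    values = pd.DataFrame(rng.integers(0, max_count + 1, (n_genes, n_cells)),
                          index=genes, columns=cells)
    # guarantee no all-zero column
    for j in range(n_cells):
        if values.iloc[:, j].sum() == 0:
            values.iloc[rng.integers(n_genes), j] = 1
    annotation = None
    if with_annotation:
        annotation = pd.DataFrame(
            {
                "symbol": [g.upper() for g in genes],
                "length_bp": rng.integers(500, 10_001, n_genes),
                "biotype": rng.choice(["protein_coding", "lincRNA"], n_genes, p=[0.9, 0.1]),
                "is_mitochondrial": np.zeros(n_genes, dtype=bool),
            },
            index=genes,
        )
    metadata = None
    if with_metadata:
        metadata = pd.DataFrame(
            {
                "total_alignments": rng.integers(400_000, 2_000_000, n_cells),
                "mito_fraction": rng.uniform(0.0, 0.4, n_cells),
                "detected_genes": rng.integers(300, 6000, n_cells),
                "mrna_base_fraction": rng.uniform(0.1, 0.9, n_cells),
            },
            index=cells,
        )
    return tm.CountMatrix(values, gene_annotation=annotation, cell_metadata=metadata)


def pure_program_study(seed: int, n_cells: int = 30, n_genes: int = 5000,
                       markers_per_tissue: int = 200, marker_effect: float = 4.0):
    """Three pure-program clusters (no mixture) at default depth/dropout."""
    programs = make_programs(8, n_genes, markers_per_tissue, marker_effect, seed=seed)
    names = [p.tissue_name for p in programs[:3]]
    spec = SimulationSpec(
        programs=programs,
        cluster_spec=[
            ClusterSpec(f"C{i + 1}", n_cells, ((name, 1.0),)) for i, name in enumerate(names)
        ],
        seed=seed,
    )
    counts, truth = tm.simulate_cells(spec, programs[0].baseline_log_expression.index)
    return counts, truth, spec


@pytest.fixture(scope="session")
def small_study() -> tm.StudyData:
    """Scaled-down full study with QC failures injected for filter tests."""
    return tm.simulate_study(
        n_tissues=4,
        n_genes=1500,
        markers_per_tissue=60,
        marker_effect=4.0,
        replicates_per_tissue=3,
        cells_per_cluster=(25, 25, 25),
        qc_failure_fractions={"mito": 0.04, "alignments": 0.04, "genes": 0.04, "mrna": 0.04},
        seed=11,
    )


@pytest.fixture(scope="session")
def default_study() -> tm.StudyData:
    """Full-size default study: 3 clusters x 45 cells, 8-tissue panel."""
    return tm.simulate_study(seed=5)


@pytest.fixture(scope="session")
def default_clustered(default_study):
    """QC-filtered default study with consensus clusters attached."""
    qc = tm.compute_cell_qc(default_study.counts)
    filtered = tm.filter_cells(default_study.counts, qc)
    genes = tm.filter_genes_expression(filtered)
    logcpm = tm.log_transform(tm.cpm(filtered.subset_genes(genes)))
    clusters = tm.consensus_cluster(logcpm, k=3, seed=5)
    return filtered, logcpm, clusters
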