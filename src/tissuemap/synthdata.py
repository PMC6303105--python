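"""Synthetic single-cell and bulk inputs with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-tissue reference panel with planted tissue-enriched marker
genes, deep-coverage full-length single cells drawn from a small number of
latent expression programs (pure programs and 50/50 log-scale mixtures,
the analogue of complete vs. incomplete recombinant tumor cells),
expression-dependent dropout, lognormal library sizes, and a paired deep
bulk experiment contrasting two programs.

Count model: each cell's expected log2 expression is its program mean plus
i.i.d. per-cell noise; expected expression is converted to relative
abundances, genes are dropped with probability
``logistic(slope * (midpoint - log2 expression))``, and counts are drawn
multinomially at a lognormal library size.  A slope of 0 disables dropout.

Randomness is organised as one independent stream per cell (see
:mod:`tissuemap._rng`), so injecting a QC failure into one cell provably
leaves every other cell bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stage_rng
from .containers import CountMatrix, ValidationError
from .preprocess import QC_RULES
from .tissue_identity import TissuePanel

MILLION = 1_000_000.0

#: Default tissue labels for the reference panel (extended as tissueNN beyond 8).
DEFAULT_TISSUE_NAMES = (
    "lung",
    "glandular_stomach",
    "forestomach",
    "esophagus",
    "liver",
    "kidney",
    "spleen",
    "heart",
)


def _tissue_names(n: int) -> list[str]:
    names = list(DEFAULT_TISSUE_NAMES[:n])
    names += [f"tissue{i:02d}" for i in range(len(names) + 1, n + 1)]
    return names


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TissueProgram:
    """A latent expression program tied to one reference tissue.

    ``baseline_log_expression`` is shared across programs; the program's
    ``marker_genes`` sit ``marker_effect`` log2 units above baseline.
    Marker sets of distinct programs are disjoint by construction.
    """

    tissue_name: str
    baseline_log_expression: pd.Series
    marker_genes: tuple[str, ...]
    marker_effect: float

    def __post_init__(self) -> None:
        if self.marker_genes and self.marker_effect <= 0:
            raise ValidationError("marker_effect must be positive")

    def log2_mean(self) -> pd.Series:
        mean = self.baseline_log_expression.copy()
        if self.marker_genes:
            mean.loc[list(self.marker_genes)] += self.marker_effect
        return mean


@dataclass
class ClusterSpec:
    """One simulated cell cluster: a program or a weighted program mixture.

    ``members`` maps program names to mixture weights (log-scale blend,
    weights sum to 1); a single entry of weight 1 is a pure cluster.
    """

    name: str
    n_cells: int
    members: tuple[tuple[str, float], ...]
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValidationError(f"cluster {self.name!r}: n_cells must be positive")
        total = sum(w for _, w in self.members)
        if not self.members or abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cluster {self.name!r}: mixture weights must sum to 1")

    @property
    def program_label(self) -> str:
        return "+".join(name for name, _ in self.members)


@dataclass
class SimulationSpec:
    """Full description of a simulated single-cell experiment."""

    programs: list[TissueProgram]
    cluster_spec: list[ClusterSpec]
    library_size_lognormal: tuple[float, float] = (13.5, 0.5)
    dropout_midpoint: float = 2.0
    dropout_slope: float = 1.0
    cell_noise_sd: float = 0.35
    qc_failure_fractions: dict[str, float] = field(default_factory=dict)
    min_library_size: int = 600_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cluster_spec:
            raise ValidationError("cluster_spec must name at least one cluster")
        if self.library_size_lognormal[1] < 0:
            raise ValidationError("library size sigma must be non-negative")
        names = {p.tissue_name for p in self.programs}
        if len(names) != len(self.programs):
            raise ValidationError("program names must be unique")
        seen: set[str] = set()
        for prog in self.programs:
            overlap = seen.intersection(prog.marker_genes)
            if overlap:
                raise ValidationError(f"marker sets overlap: {sorted(overlap)[:3]}")
            seen.update(prog.marker_genes)
        for cl in self.cluster_spec:
            for prog_name, _ in cl.members:
                if prog_name not in names:
                    raise ValidationError(f"cluster {cl.name!r} references unknown program {prog_name!r}")
        for rule, frac in self.qc_failure_fractions.items():
            if rule not in QC_RULES:
                raise ValidationError(f"unknown QC rule {rule!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"qc_failure_fractions[{rule!r}] must be in [0, 1]")

    def program(self, name: str) -> TissueProgram:
        for prog in self.programs:
            if prog.tissue_name == name:
                return prog
        raise KeyError(name)

    def cluster_log2_mean(self, cluster: ClusterSpec) -> pd.Series:
        parts = [w * self.program(name).log2_mean() for name, w in cluster.members]
        return sum(parts[1:], parts[0])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    cell_program: pd.Series | None = None
    cell_cluster: pd.Series | None = None
    planted_markers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    qc_fail_cells: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# programs, annotation, panel
# ---------------------------------------------------------------------------


def make_programs(
    n_tissues: int,
    n_genes: int,
    markers_per_tissue: int,
    marker_effect: float,
    seed: int = 0,
    baseline_mean: float = 5.0,
    baseline_sd: float = 2.0,
) -> list[TissueProgram]:
    """Programs with a shared lognormal baseline and disjoint marker blocks."""
    if n_tissues < 2:
        raise ValidationError("need at least two tissues")
    if markers_per_tissue * n_tissues > n_genes:
        raise ValidationError(
            f"{n_tissues} tissues x {markers_per_tissue} markers exceed {n_genes} genes"
        )
    rng = stage_rng(seed, "panel")
    gene_ids = pd.Index([f"g{i:05d}" for i in range(1, n_genes + 1)], name="gene_id")
    baseline = pd.Series(rng.normal(baseline_mean, baseline_sd, n_genes), index=gene_ids)
    programs = []
    for t, name in enumerate(_tissue_names(n_tissues)):
        markers = tuple(gene_ids[t * markers_per_tissue : (t + 1) * markers_per_tissue])
        programs.append(
            TissueProgram(
                tissue_name=name,
                baseline_log_expression=baseline,
                marker_genes=markers,
                marker_effect=marker_effect,
            )
        )
    return programs


def make_gene_annotation(
    gene_ids: pd.Index,
    protected_genes: set[str] | None = None,
    seed: int = 0,
    noncoding_fraction: float = 0.08,
    n_mito: int = 10,
) -> pd.DataFrame:
    """Gene annotation table: symbol, length, biotype, mitochondrial flag.

    Lengths are log-uniform in [500 bp, 10 kb].  ``protected_genes``
    (typically planted markers) are always protein-coding and never
    mitochondrial; a small fraction of the remaining genes is labelled
    lincRNA and ``n_mito`` of them are flagged mitochondrial.
    """
    rng = stage_rng(seed, "annotation")
    n = len(gene_ids)
    protected = protected_genes or set()
    lengths = np.round(10 ** rng.uniform(np.log10(500), np.log10(10_000), n)).astype(int)
    biotype = np.array(["protein_coding"] * n, dtype=object)
    is_mito = np.zeros(n, dtype=bool)
    free = np.array([g not in protected for g in gene_ids])
    free_idx = np.flatnonzero(free)
    n_nc = int(round(noncoding_fraction * n))
    picked = rng.choice(free_idx, size=min(n_nc + n_mito, free_idx.size), replace=False)
    nc_idx, mito_idx = picked[:n_nc], picked[n_nc:]
    biotype[nc_idx] = "lincRNA"
    is_mito[mito_idx] = True
    symbols = [f"mt-{g.upper()}" if m else g.upper() for g, m in zip(gene_ids, is_mito)]
    return pd.DataFrame(
        {
            "symbol": symbols,
            "length_bp": lengths,
            "biotype": biotype,
            "is_mitochondrial": is_mito,
        },
        index=gene_ids,
    )


def panel_from_programs(
    programs: list[TissueProgram],
    replicates_per_tissue: int = 3,
    replicate_noise_sd: float = 0.5,
    seed: int = 0,
) -> TissuePanel:
    """Reference panel in TPM: ``2**(program log2 mean + noise)``, column-normalized.

    Replicate noise is i.i.d. normal per entry on the log2 scale.  Because
    every tissue carries the same number of equally elevated own-markers,
    TPM normalization shifts all columns by (in expectation) the same
    constant and preserves the planted marker contrast.
    """
    rng = stage_rng(seed, "panel", 1)
    columns, tissue_of_sample = {}, {}
    for prog in programs:
        mean = prog.log2_mean().to_numpy()
        for r in range(1, replicates_per_tissue + 1):
            sample = f"{prog.tissue_name}_r{r}"
            linear = 2.0 ** (mean + rng.normal(0.0, replicate_noise_sd, mean.size))
            columns[sample] = linear / linear.sum() * MILLION
            tissue_of_sample[sample] = prog.tissue_name
    values = pd.DataFrame(columns, index=programs[0].baseline_log_expression.index)
    return TissuePanel(values=values, tissue_of_sample=pd.Series(tissue_of_sample))


def generate_tissue_panel(
    n_tissues: int,
    n_genes: int,
    markers_per_tissue: int,
    marker_effect: float = 4.0,
    replicates_per_tissue: int = 3,
    seed: int = 0,
    replicate_noise_sd: float = 0.5,
) -> tuple[TissuePanel, SyntheticTruth]:
    """Generate a synthetic multi-tissue reference panel plus its truth."""
    programs = make_programs(n_tissues, n_genes, markers_per_tissue, marker_effect, seed=seed)
    panel = panel_from_programs(programs, replicates_per_tissue, replicate_noise_sd, seed=seed)
    truth = SyntheticTruth(
        planted_markers={p.tissue_name: p.marker_genes for p in programs}
    )
    return panel, truth


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------


def _draw_library(rng: np.random.Generator, mu: float, sigma: float, floor: int) -> int:
    """Lognormal library size, resampled (bounded) to stay above ``floor``."""
    for _ in range(100):
        lib = int(round(rng.lognormal(mu, sigma)))
        if lib >= floor:
            return lib
    return max(int(round(rng.lognormal(mu, sigma))), floor)


def _select_qc_failures(spec: SimulationSpec, cell_ids: list[str]) -> dict[str, str]:
    """Pick distinct cells to violate exactly one QC rule each (own RNG stream)."""
    rng = stage_rng(spec.seed, "qc_select")
    available = list(range(len(cell_ids)))
    assigned: dict[str, str] = {}
    for rule in QC_RULES:
        frac = spec.qc_failure_fractions.get(rule, 0.0)
        n_rule = int(round(frac * len(cell_ids)))
        if n_rule == 0:
            continue
        if n_rule > len(available):
            raise ValidationError("qc_failure_fractions exceed the number of cells")
        chosen = rng.choice(available, size=n_rule, replace=False)
        for idx in chosen:
            assigned[cell_ids[idx]] = rule
            available.remove(idx)
    return assigned


def simulate_cells(
    spec: SimulationSpec, panel_genes: pd.Index | list[str]
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate the single-cell count matrix described by ``spec``.

    Returns counts over ``panel_genes`` with per-cell metadata
    (``total_alignments``, ``mito_fraction``, ``detected_genes``,
    ``mrna_base_fraction``, ``genotype``, ``cluster``) and the ground
    truth (cell program and cluster labels, planted markers, injected QC
    failures).  Un-perturbed cells are generated to pass default QC:
    library sizes are floored at ``spec.min_library_size`` and the
    alignment-level fractions are drawn inside their passing ranges.
    """
    panel_genes = pd.Index(panel_genes)
    if panel_genes.empty:
        raise ValidationError("panel_genes is empty")
    mu, sigma = spec.library_size_lognormal

    cell_ids: list[str] = []
    cell_cluster: list[str] = []
    cell_program: list[str] = []
    cluster_means: list[np.ndarray] = []
    genotypes: list[str] = []
    for c, cl in enumerate(spec.cluster_spec):
        mean = spec.cluster_log2_mean(cl).reindex(panel_genes).to_numpy()
        if np.any(np.isnan(mean)):
            raise ValidationError("cluster program genes missing from panel_genes")
        geno = cl.genotype or f"genotype{c + 1}"
        for _ in range(cl.n_cells):
            i = len(cell_ids)
            cell_ids.append(f"cell{i:04d}")
            cell_cluster.append(cl.name)
            cell_program.append(cl.program_label)
            cluster_means.append(mean)
            genotypes.append(geno)

    qc_fail = _select_qc_failures(spec, cell_ids)

    n_genes = len(panel_genes)
    counts = np.zeros((n_genes, len(cell_ids)), dtype=np.int64)
    meta_rows = []
    for i, cell in enumerate(cell_ids):
        rng = stage_rng(spec.seed, "cells", i)
        log2cell = cluster_means[i] + rng.normal(0.0, spec.cell_noise_sd, n_genes)
        if spec.dropout_slope == 0:
            keep = np.ones(n_genes, dtype=bool)
        else:
            p_drop = expit(spec.dropout_slope * (spec.dropout_midpoint - log2cell))
            keep = rng.random(n_genes) >= p_drop
        lib = _draw_library(rng, mu, sigma, spec.min_library_size)
        rel = np.where(keep, 2.0**log2cell, 0.0)
        total_rel = rel.sum()
        if total_rel > 0:
            rel = rel / total_rel
            counts[:, i] = rng.multinomial(lib, rel)
        mito = rng.uniform(0.01, 0.15)
        mrna = rng.uniform(0.30, 0.80)

        rule = qc_fail.get(cell)
        if rule is not None:
            prng = stage_rng(spec.seed, "cell_perturb", i)
            if rule == "mito":
                mito = 0.25 + 0.40 * prng.random()
            elif rule == "mrna":
                mrna = 0.02 + 0.16 * prng.random()
            elif rule == "alignments":
                small_lib = int(prng.uniform(100_000, 450_000))
                counts[:, i] = prng.multinomial(small_lib, rel) if total_rel > 0 else 0
            elif rule == "genes":
                # restrict sampling to 400 genes so < 500 are detectable
                keep_idx = prng.choice(n_genes, size=min(400, n_genes), replace=False)
                mask = np.zeros(n_genes)
                mask[keep_idx] = rel[keep_idx]
                if mask.sum() > 0:
                    counts[:, i] = prng.multinomial(lib, mask / mask.sum())

        meta_rows.append(
            {
                "total_alignments": int(counts[:, i].sum()),
                "mito_fraction": mito,
                "detected_genes": int((counts[:, i] > 0).sum()),
                "mrna_base_fraction": mrna,
                "genotype": genotypes[i],
                "cluster": cell_cluster[i],
            }
        )

    values = pd.DataFrame(counts, index=panel_genes, columns=pd.Index(cell_ids, name="cell_id"))
    marker_union = {g for p in spec.programs for g in p.marker_genes}
    annotation = make_gene_annotation(panel_genes, protected_genes=marker_union, seed=spec.seed)
    metadata = pd.DataFrame(meta_rows, index=values.columns)
    matrix = CountMatrix(values, gene_annotation=annotation, cell_metadata=metadata)
    truth = SyntheticTruth(
        cell_program=pd.Series(cell_program, index=values.columns, name="program"),
        cell_cluster=pd.Series(cell_cluster, index=values.columns, name="cluster"),
        planted_markers={p.tissue_name: p.marker_genes for p in spec.programs},
        qc_fail_cells=qc_fail,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# paired bulk
# ---------------------------------------------------------------------------


def simulate_paired_bulk(
    spec: SimulationSpec,
    n_per_group: int = 3,
    seed: int | None = None,
    group_programs: tuple[str, str] | None = None,
    sample_noise_sd: float = 0.15,
    library_lognormal: tuple[float, float] = (17.0, 0.2),
) -> tuple[CountMatrix, pd.DataFrame]:
    """Deep bulk RNA-seq contrast of two programs, with true per-gene LFCs.

    No dropout; libraries are lognormal around ~2.4e7.  Returns the bulk
    count matrix (group labels in the metadata) and a truth table whose
    ``true_lfc`` column is the difference of the two program log2 means —
    by construction ``marker_effect`` for group A's planted markers,
    ``-marker_effect`` for group B's, and 0 elsewhere.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be at least 2")
    if group_programs is None:
        if len(spec.programs) < 2:
            raise ValidationError("need two programs to contrast")
        group_programs = (spec.programs[0].tissue_name, spec.programs[1].tissue_name)
    seed = spec.seed if seed is None else seed
    prog_a, prog_b = (spec.program(name) for name in group_programs)
    mean_a, mean_b = prog_a.log2_mean(), prog_b.log2_mean()
    genes = mean_a.index
    mu, sigma = library_lognormal

    columns, meta_rows = {}, []
    for g, (label, mean) in enumerate([("A", mean_a), ("B", mean_b)]):
        for j in range(1, n_per_group + 1):
            rng = stage_rng(seed, "bulk", g, j)
            log2s = mean.to_numpy() + rng.normal(0.0, sample_noise_sd, len(genes))
            rel = 2.0**log2s
            rel /= rel.sum()
            lib = int(round(rng.lognormal(mu, sigma)))
            sample = f"bulk{label}_{j}"
            columns[sample] = rng.multinomial(lib, rel)
            meta_rows.append({"sample": sample, "group": label, "program": mean.name or label})
    values = pd.DataFrame(columns, index=genes)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    metadata["program"] = [group_programs[0]] * n_per_group + [group_programs[1]] * n_per_group
    marker_union = {g for p in spec.programs for g in p.marker_genes}
    annotation = make_gene_annotation(genes, protected_genes=marker_union, seed=spec.seed)
    matrix = CountMatrix(values, gene_annotation=annotation, cell_metadata=metadata)
    # exact by construction: shared baselines cancel, leaving only marker effects
    lfc = pd.Series(0.0, index=genes)
    lfc.loc[list(prog_a.marker_genes)] += prog_a.marker_effect
    lfc.loc[list(prog_b.marker_genes)] -= prog_b.marker_effect
    truth = pd.DataFrame({"true_lfc": lfc})
    return matrix, truth


# ---------------------------------------------------------------------------
# whole-study convenience bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    panel: TissuePanel
    counts: CountMatrix
    truth: SyntheticTruth
    programs: list[TissueProgram]
    spec: SimulationSpec
    bulk_counts: CountMatrix | None = None
    bulk_truth: pd.DataFrame | None = None


def default_study_spec(
    programs: list[TissueProgram],
    cells_per_cluster: tuple[int, int, int] = (45, 45, 45),
    qc_failure_fractions: dict[str, float] | None = None,
    seed: int = 0,
    **overrides,
) -> SimulationSpec:
    """Three-cluster study design: two pure programs and one 50/50 mixture.

    The clusters mirror the mixed tumor-cell population the analysis is
    built for: a pulmonary-like cluster, a gastric-like cluster, and a
    blended cluster whose profile matches neither pure program.
    """
    a, b = programs[0].tissue_name, programs[1].tissue_name
    clusters = [
        ClusterSpec("C1", cells_per_cluster[0], ((a, 1.0),), genotype="K"),
        ClusterSpec("C2", cells_per_cluster[1], ((b, 1.0),), genotype="KN"),
        ClusterSpec("C3", cells_per_cluster[2], ((a, 0.5), (b, 0.5)), genotype="KNF1F2"),
    ]
    return SimulationSpec(
        programs=programs,
        cluster_spec=clusters,
        qc_failure_fractions=qc_failure_fractions or {},
        seed=seed,
        **overrides,
    )


def simulate_study(
    n_tissues: int = 8,
    n_genes: int = 5000,
    markers_per_tissue: int = 200,
    marker_effect: float = 4.0,
    replicates_per_tissue: int = 3,
    cells_per_cluster: tuple[int, int, int] = (45, 45, 45),
    qc_failure_fractions: dict[str, float] | None = None,
    n_bulk_per_group: int = 3,
    with_bulk: bool = True,
    seed: int = 0,
    **spec_overrides,
) -> StudyData:
    """Simulate a full study: panel, single cells, and (optionally) paired bulk."""
    programs = make_programs(n_tissues, n_genes, markers_per_tissue, marker_effect, seed=seed)
    panel = panel_from_programs(programs, replicates_per_tissue, seed=seed)
    spec = default_study_spec(
        programs,
        cells_per_cluster=cells_per_cluster,
        qc_failure_fractions=qc_failure_fractions,
        seed=seed,
        **spec_overrides,
    )
    counts, truth = simulate_cells(spec, panel.values.index)
    bulk_counts = bulk_truth = None
    if with_bulk:
        bulk_counts, bulk_truth = simulate_paired_bulk(spec, n_per_group=n_bulk_per_group)
    return StudyData(
        panel=panel,
        counts=counts,
        truth=truth,
        programs=programs,
        spec=spec,
        bulk_counts=bulk_counts,
        bulk_truth=bulk_truth,
    )
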