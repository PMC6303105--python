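# Methods

This note documents the models, conventions and design choices behind
`tissuemap`, in the spirit of a package vignette: what each stage assumes,
which knobs matter, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model and orientation

Every matrix is genes × samples.  `CountMatrix` holds non-negative
integer counts with an aligned gene annotation table (symbol, length in
bp, Ensembl-style biotype, mitochondrial flag) and per-cell metadata
(total alignments, mitochondrial fraction, detected genes, mRNA-base
fraction, genotype).  `ExpressionMatrix` carries real values on a
declared scale (`CPM`, `TPM`, or their log2 forms with a recorded
pseudocount).  Containers validate identifiers, signs and integrality at
construction, so stage code can operate positionally.

## Quality control

Four per-cell rules, evaluated on alignment-level metadata (they are not
derivable from the count matrix — the mitochondrial-read and mRNA-base
fractions are properties of the alignment stage):

| rule | fails when | default |
|---|---|---|
| mito | mitochondrial fraction **>** max_mito | 0.20 |
| alignments | total alignments **<** min_alignments | 500 000 |
| genes | detected genes **<** min_genes | 500 |
| mrna | mRNA-base fraction **<** min_mrna | 0.20 |

All comparisons are strict, matching the wording each rule is
conventionally stated with; a cell sitting exactly on a threshold passes.
These defaults describe deep-coverage full-length (microfluidic C1-style)
data and are far too strict for shallow droplet data.

## Normalization

CPM divides each column by its sum (×10⁶).  TPM first divides by gene
length in kilobases, then renormalizes the per-base rates (×10⁶).
Effective gene length is the annotated length; when quantifier-estimated
effective lengths are available they can be supplied in the annotation
table instead.  Pseudo-bulk profiles sum integer counts over the member
cells of a cluster and then apply the TPM formula — never the mean of
per-cell TPMs, which weights cells by library size inconsistently.  The
two paths are verified bit-identical in the acceptance suite.

Log transforms are log2(x + pseudocount) with pseudocount 1 by default,
recorded in the output.  The clustering gene filter "log2(CPM) > 2 in at
least 10 cells" is applied as CPM > 4 on the linear scale, which needs no
pseudocount and is exact for zeros.  The count filter "≥10 counts in ≥10
cells" is inclusive on both sides.

## Consensus clustering

A compact re-implementation of the SC3-style scheme: for each cell-cell
distance (Euclidean, 1−Pearson, 1−Spearman), each transform (PCA of the
distance matrix with standardized columns; normalized graph Laplacian of
`exp(−D/max D)` with eigenvectors in ascending eigenvalue order), and
each retained dimension d in 4–7% of the cell count, seeded k-means
(n_init = 10) contributes a binary co-clustering matrix; the consensus is
their mean, and the final labels cut a complete-linkage dendrogram of
1 − consensus at k.  No internal gene filtering is applied — every gene
of the input participates, so the caller controls the gene set.  Labels
are arbitrary up to permutation; all evaluation uses the adjusted Rand
index.  k equal to the number of cells is special-cased to the forced
singleton partition.

Markers: per gene, one-vs-rest AUROC for every cluster of size ≥ 2 (via
the rank-sum identity), a one-sided Wilcoxon rank-sum p for the AUROC
argmax cluster, Holm adjustment across genes; a marker needs AUROC ≥ 0.85
and adjusted p ≤ 0.01 (the cited consensus method's defaults; both
configurable).  A gene can mark at most one cluster by construction.

## Tissue signatures and classification

Panel replicates are averaged within tissue on the linear scale first.
Signatures are built from log2(TPM + 1) tissue profiles: per gene, center
the tissue means across tissues and assign the gene to the argmax tissue
with the centered value as its score.  Exact ties (including constant
genes) are excluded — a tied gene carries no tissue information.  Ranked
lists are cut at top_n = 70 (a companion convention of 50 exists in the
field; both are supported via `top_n`).  "Ranked by expression" is read
as ranked by the enrichment score the procedure just assigned, the only
per-gene scalar it defines.  Ties in score break by gene identifier for
reproducibility.

The combined matrix intersects cluster pseudo-bulk TPM, optional bulk
TPM, and tissue TPM on the signature union, after restricting the
single-cell gene space to protein-coding genes with ≥10 counts in ≥10
cells.  The panel is accepted as TPM; selection nominally defined on
log2 CPM is performed on log2(TPM+1), recorded in the output metadata
(for a fixed gene set the two differ only by a per-sample constant once
lengths are fixed, and the mean-centering removes shared constants).

Three views are computed with one seed:

- **Cosine similarity** of every query (cluster, bulk) against every
  tissue on log2(TPM+1); values lie in [0, 1] for non-negative input.
  The argmax is the tissue call; the margin (best − second best) is the
  confidence.  Cosine is scale-invariant, so differing library
  conventions between query and reference columns do not bias the call.
- **HCPC**: features centered (variance scaling off by default), PCA to
  5 components, Ward linkage on the component scores, partition at the
  k ∈ [2, 10] maximizing the relative inertia-gain ratio
  (W(k−1)−W(k)) / (W(k)−W(k+1)), with zero denominators treated as +∞
  when the numerator is positive.  No k-means consolidation step is
  applied, so the partition is always consistent with cutting the tree.
- **t-SNE** with perplexity 13 and 5 initial PCA dimensions.  t-SNE
  requires 3·perplexity < n; `embed_tsne` errors when violated, while
  the classification report reduces the perplexity to (n−1)/3 for small
  combined matrices (a dozen columns cannot support perplexity 13) and
  logs the reduction.  Determinism is per-platform: fixed seed and input
  give identical output on one machine; cross-platform bit equality is
  not promised.

## Comparative analyses

`de_lfc` is a deliberately simple fold-change summary (the study design
it mirrors used a Bayesian dropout error model for single cells and a
negative-binomial GLM for bulk; neither is re-implemented here):
LFC = log2((mean CPM_a + 1)/(mean CPM_b + 1)), two-sided rank-sum p,
Benjamini–Hochberg adjustment, after the inclusive count filter (capped
at the number of compared samples so small bulk designs are not filtered
to zero).  Two caveats are inherent to the formula and tested explicitly:
the +1 pseudocount compresses fold changes for genes with CPM near 1, and
CPM renormalization introduces a compositional offset shared across genes
when the two groups express different total marker mass.  The correlation
step is agnostic to the DE source: any table with a `log2_fold_change`
column (plus group mean counts) can be supplied, and the result records
which source produced each axis.

`lfc_correlation` intersects gene sets, removes genes whose bulk average
count — the unweighted mean of the two group means by default,
configurable to a precomputed overall mean — is below 1000 (strict), and
reports the Pearson r with the paired table.

`project_on_signature` restricts a TPM matrix to a flat symbol list
(case-insensitive matching via the annotation's symbol column, suiting
human-vs-mouse casing; no orthology inference), log-transforms, and
returns the first two column-centered principal components with their
explained-variance fractions.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset:

- **Programs/panel.** A shared per-gene baseline log2 expression
  ~ N(5, 2); each tissue elevates its disjoint block of marker genes by
  `marker_effect` (default 4) log2 units.  Panel replicates add i.i.d.
  N(0, 0.5) log2 noise and are column-normalized to TPM.  Because every
  tissue carries the same number of equally elevated own-markers, the
  normalizers are exchangeable and the planted contrast survives
  normalization (verified to ±0.2 at the default sizes).
- **Cells.** A cell's expected log2 expression is its cluster's program
  mean (pure, or a weighted log-scale blend — the analogue of cells with
  partial regulator loss) plus N(0, 0.35) per-cell noise.  Expression is
  converted to relative abundances, genes are dropped with probability
  `logistic(slope·(midpoint − log2 expr))` (defaults: midpoint 2.0,
  slope 1.0; slope 0 disables dropout), and counts are drawn
  multinomially at a lognormal library size (defaults μ = 13.5, σ = 0.5
  on the natural-log scale, ≈10⁶ counts, floored at 600 000 so that
  un-perturbed cells pass default QC by construction).  Per-cell RNG
  streams are independent, so perturbing one cell provably leaves every
  other cell bit-identical.
- **QC failures.** A configurable fraction of cells per rule is
  perturbed to violate exactly that rule (metadata for mito/mRNA;
  resampled small library for alignments; sampling restricted to 400
  genes for detected-genes), recorded in the ground truth.
- **Paired bulk.** Two designated programs, n per group ≥ 2, deep
  lognormal libraries (≈2.4×10⁷), N(0, 0.15) per-sample log2 noise, no
  dropout; the truth table holds the exact planted log2 fold changes.
- **Default study.** Three clusters of 45 cells — two pure programs and
  one 50/50 blend — over an 8-tissue, 5000-gene panel with 200 markers
  per tissue at +4, three replicates, and a 3 vs. 3 bulk contrast.

What passing tests show: the implementation recovers planted structure
under compositional counting, expression-dependent dropout and library
variation.  What they do not show: robustness to batch effects, ambient
contamination, doublets, cell-cycle structure, unbalanced or correlated
marker blocks, or tissues absent from the panel — real data carry all of
these, and the panel-absent case is precisely the regime where the cosine
margin is the signal to inspect (a low maximum with a thin margin, as the
blended cluster exhibits).

## Determinism and seeds

One user seed is expanded into independent streams with
`SeedSequence([seed, stage_code, *extra])` (stage codes are fixed small
integers; extras index cells/samples/runs), so stages replay in
isolation and changing one stage's draws cannot perturb another.  The run
manifest records the configuration, input checksums, per-stage in/out
counts and output checksums, and contains no wallclock information;
replaying a run with the same inputs, configuration and seed produces
byte-identical outputs on one platform.

## Problem sizes

Defaults throughout target desk-scale verification: the full study is
135 cells × 5000 genes and runs the entire pipeline in a few seconds;
the multi-seed recovery checks use 20 seeds.  All sizes are ordinary
function arguments and scale up without code changes.

## Known limitations

- The consensus scheme is a faithful but simplified re-expression of the
  published procedure it mirrors (no gene filtering, no SVM hybrid for
  large n, fixed linkage); cluster-number selection is the caller's
  choice of k.
- `de_lfc` is a summary statistic, not an inference engine; use a
  dedicated DE package when calibrated p-values matter, and feed its
  table to `lfc_correlation`.
- Tissue calls are closed-world: the best match among supplied tissues,
  qualified by the margin, never an absolute identity.
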