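# tissuemap

Reference-based tissue-identity mapping for single-cell RNA-seq clusters.

`tissuemap` answers a recurring question in cancer and developmental
biology: *what tissue does each population of cells most resemble?*
Lineage-defining transcription factors (for example NKX2-1 and FoxA1/2 in
lung adenocarcinoma) can be lost during tumor evolution, leaving cells in
differentiation states that no marker panel anticipates — pulmonary-like,
gastric-like, or something in between.  Given a gene × cell count matrix
from deep-coverage full-length single-cell RNA-seq and a bulk expression
panel of candidate normal tissues, `tissuemap` runs the complete analysis:
cell and gene quality control, consensus clustering, cluster pseudo-bulk
aggregation, construction of tissue-enriched gene signatures, and
classification of each cluster against every tissue by cosine similarity,
hierarchical clustering on principal components (HCPC), and a seeded
t-SNE.  It also covers two companion analyses — the single-cell vs. bulk
fold-change correlation and projection of cells onto a published gene
signature — and ships a fully tested synthetic-data generator so the whole
pipeline can be exercised with known ground truth.

It is written for computational biologists who want each stage available
as a plain Python function over pandas data frames, with a thin CLI on
top.

## Method

**Pseudo-bulk TPM.** Counts are summed across the member cells of each
cluster *before* normalization.  With gene length `L_g` (kb) and summed
count `c_g`, the per-base rate is `r_g = c_g / L_g` and

```
TPM_g = r_g / Σ_j r_j × 10^6.
```

**Tissue-enriched signatures.** For each gene, average log2 expression
within each tissue, then center across tissues:
`s_{g,t} = m_{g,t} − mean_t(m_{g,t})`.  The gene is assigned to the tissue
with the largest centered value, carrying that value as its enrichment
score (exact ties are dropped: a tied gene carries no tissue information).
Each tissue's assigned genes are ranked by score and the top 70 kept.

**Classification.** Cluster, bulk and tissue profiles are intersected on
the signature gene union, log2(TPM+1)-transformed, and compared three
ways: cosine similarity `cos(q, r) = q·r / (‖q‖‖r‖)` for every
cluster × tissue pair (argmax = the tissue call, with the margin to the
runner-up), HCPC (unscaled PCA to 5 components, Ward linkage, cut at the
partition maximizing the relative inertia-gain ratio), and t-SNE
(perplexity 13, 5 initial dimensions, seeded).

**Upstream.** Cells are removed when >20% mitochondrial reads, <500 000
alignments, <500 detected genes, or <20% mRNA bases (all strict, so
boundary values pass).  Clustering uses genes with log2(CPM) > 2 in ≥10
cells; classification uses protein-coding genes with ≥10 counts in ≥10
cells.  Clustering is an SC3-style consensus over
{Euclidean, Pearson, Spearman} distances × {PCA, graph-Laplacian}
transforms × a grid of 4–7% of the cell count, with seeded k-means and a
complete-linkage cut of the consensus matrix; markers are one-vs-rest
AUROC ≥ 0.85 with Holm-adjusted rank-sum p ≤ 0.01.

## Worked example

Simulate a study (8-tissue panel, 5 000 genes, 200 planted markers per
tissue at +4 log2 units; three tumor-cell clusters of 45 cells — a
pulmonary-like program, a gastric-like program, and a 50/50 blend — plus
a 3 vs. 3 paired bulk contrast), then run everything:

```sh
tissuemap simulate --outdir demo_ds --seed 7
tissuemap run-all --dataset demo_ds --outdir demo_out
```

which prints:

```
cluster sizes: {1: 39, 2: 41, 3: 43}
C1 -> lung
C2 -> glandular_stomach
C3 -> glandular_stomach
...
sc/bulk LFC Pearson r = 0.994
```

123 of the 135 simulated cells pass QC (12 carried injected QC failures),
and consensus clustering recovers the three planted populations.  In
`demo_out/similarity.tsv` the pure clusters match their generating
tissues decisively — C1 vs. lung 0.980 (margin 0.045 over the runner-up),
C2 vs. glandular stomach 0.981 (margin 0.048) — while the blended cluster
C3 peaks at only 0.972 with a margin of 0.004: its best match is weaker
than either pure cluster's, the expected signature of a population that
is neither one identity nor the other.  The paired bulk contrast of the
same two programs correlates with the single-cell fold changes at
r = 0.994 over 2 661 genes.  Other outputs include the per-cell QC table,
consensus matrix, marker table, signature lists, HCPC partition, t-SNE
coordinates, and a JSON manifest that makes the run bit-replayable.

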