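# Methods

`scpdx` re-implements, as a tested and reusable pipeline, a single-cell
analysis workflow for patient-derived xenograft (PDX) tumors: droplet QC with
human–mouse demultiplexing, expression-based copy-number inference with a
two-cutoff malignancy caller, graph clustering with marker annotation,
rank-based gene-set scoring with cell-cycle state classification,
signature-correlation molecular subtyping, composition-shift testing, and
receptor–ligand cell-pair networks. This note documents the models, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Quality control and species demultiplexing

A PDX droplet run mixes human tumor cells with mouse stromal/immune cells, so
every barcode is first assigned a species from its UMI counts: the majority
genome is the candidate species, and a barcode whose minority-genome UMI
fraction is **≥ 1%** is called a cross-species multiplet and removed. The
fraction is computed on UMI counts, the unit a CellRanger count matrix
actually provides.

Cells then pass a conjunction of filters: 1,000 ≤ UMIs ≤ 150,000; 500 ≤
expressed genes ≤ 10,000 (a gene is "expressed" at count ≥ 1); mitochondrial
UMI fraction ≤ 10% (genes matched by the `MT-`/`mt-` name prefix,
configurable regex); and mean expression of two housekeeping genes
(beta-actin, GAPDH) ≥ 3. The housekeeping threshold is interpreted on the
log2(TPM-like + 1) scale — the only scale on which a cutoff of 3 is a
sensible viability gate — so that check runs after normalization of the
candidate cells. Because the retained set is a conjunction of per-cell
predicates, filter order cannot change it; the QC report attributes each
removal to the *first* failing rule in the fixed order multiplet → UMI →
genes → mitochondrial → housekeeping. Tumor-cell clusters get a stricter
gate (> 2,000 expressed genes, strictly greater). An optional, logged
cluster-purity filter (drop cells disagreeing with their k = 20 embedding
neighborhood's majority label) stands in for the otherwise unspecified
"outlier removal" step; it is never applied implicitly.

## Normalization, clustering, differential expression

Counts are depth-normalized to TPM-like values (per-cell scaling to a fixed
total of 10⁶; no gene-length correction, appropriate for 3′ UMI data) and
transformed as log2(x + 1). Genes expressed in < 1% of cells are dropped
(inclusive boundary: 2 of 200 cells stays). Variable genes are selected
Seurat-v2 style — genes binned by mean expression (20 equal-count bins),
dispersion = variance/mean z-scored within each bin — implemented directly
because the packaged variant assumes natural-log input while this pipeline is
log2 throughout. PCA uses 20 components of the per-gene z-scored (capped at
±10) variable-gene matrix; a fixed component count replaces permutation-based
significance testing, which would add runtime but nothing to the contract.
Clustering is Leiden community detection on the kNN graph (k = 15) of the
20-PC embedding, seeded and deterministic.

**Leiden resolution defaults to 0.5, not 1.0.** At this package's data scale
(populations of one- to a few hundred cells) modularity at resolution 1.0
reliably over-partitions even noise-only homogeneous populations — two
clean, disjoint-marker populations of 150 cells split into five clusters —
while 0.5 recovers exactly one cluster per population and still resolves the
default tumor's subclonal/cycle substructure. Resolution remains a parameter.

Clusters are annotated by arg-max over cell types of the cluster-mean of the
marker-set mean expression; ties break alphabetically with a warning. Because
a tumor population can legitimately subdivide (subclones, cycle states), the
pipeline's per-cell *type* call is the cluster→annotation composite, and
recovery is evaluated on those labels.

Differential expression is a per-gene two-sample t test on log-normalized
values. The unequal-variance (Welch) form is used: the equal/unequal-variance
behavior of the historical implementation this mirrors is not recoverable,
and Welch is the safer default under unequal group sizes. Genes are
pre-filtered to those expressed in ≥ 10% of either group with |log2 FC| ≥
0.25 (both settable to 0 — required for null-calibration checks, since the
fold-change prefilter deliberately biases the retained p-value set).
Adjustment is Bonferroni; a reporting flag marks |log2 FC| > 0.8 with
p < 0.001.

## Inferred CNVs and malignancy calling

The caller estimates chromosome-scale dosage from smoothed, position-ordered
expression:

1. drop genes with mean log-normalized expression < 0.2;
2. standardize each gene across cells (one center + unit-variance pass —
   the description mentions both centering and z-scoring, but centering is
   idempotent inside standardization; zero-variance genes become all-zero);
3. clip to ±3 *before* smoothing, so single extreme genes cannot distort the
   moving average;
4. sort genes by (chromosome, start) with chromosomes in karyotype order
   (1…22, X, Y; configurable);
5. per cell and per chromosome, take the 100-gene moving average (step 1,
   centered window, truncated at chromosome ends — windows never span
   chromosomes);
6. re-center each cell's smoothed profile to mean zero (the "adjusted as
   centered values" step is read per-cell; per-gene centering already
   happened in step 2).

Two per-cell summaries drive the call: the **CNV score** (mean of squared
inferred-CNV values) and the **CNV correlation** (Pearson r against the
putative-malignant reference profile, the per-gene mean over the cells in
the top 5% of CNV scores, taken once from the pre-call ranking). Cells with
score > 0.02 **and** correlation > 0.2 are tumor; both strictly below →
non-tumor; anything else — including values exactly at a cutoff or an
undefined correlation — is undetermined. A single recalibration pass then
subtracts the called non-tumor cells' mean profile (the empirical diploid
baseline) and recomputes scores, reference, correlations and calls once; if
no cell was called non-tumor the result is returned flagged uncalibrated.

## Gene-set scores, cell cycle, subtype, composition

The enrichment score is a per-cell rank statistic: with genes ranked by
expression within the cell (ties averaged), the score is (mean rank of
in-set genes − mean rank of out-of-set genes) / (G/2), which is ±1 exactly
when the set occupies the extreme ranks, for any set size. It replaces
kernel-density GSVA scoring deliberately: the downstream cell-cycle rule
consumes only score *signs*, so any monotone-equivalent scoring preserves
the classification, and the rank-difference form is exactly invariant to
monotone per-cell transforms of expression. Numerical agreement with the
GSVA package is explicitly out of scope.

Cell-cycle states come from G1/S and G2/M program scores: cycling if both
> 0, non-cycling if both < 0, otherwise intermediate; exact zeros satisfy
neither strict inequality and are classified intermediate. A canonical pair
of G1/S and G2/M gene lists ships as `data/cycle_genes.gmt`; the sets are
fully configurable.

Molecular subtyping correlates a bulk profile with each of five subtype
centroids over that subtype's signature genes (≥ 3 shared genes required,
else the subtype is skipped with a warning) and assigns the arg-max Pearson
r among those with two-sided p < 0.05 ("significant" is read as the
conventional two-sided 0.05); no significant centroid → "unclassified",
ties break by fixed column order with a warning. The bundled centroid table
(`data/subtype_centroids_synthetic.tsv`) is **synthetic** — five distinct
centroids over a 150-gene signature pool for testing and demonstration;
real signature centroids are supplied as a file.

Composition shifts between two groups of per-category cell counts use
Pearson's chi-squared on the 2×k table without continuity correction
(df = k − 1); a zero expected count raises an error advising category
merging rather than returning a degenerate statistic.

## Receptor–ligand networks

An interaction links a sender cell expressing a ligand to a receiver cell
expressing the matching receptor; for each (ligand, receptor) pair and each
ordered type pair, the edge count is (# sender cells expressing the ligand) ×
(# receiver cells expressing the receptor) — exactly the all-cell-pairs
enumeration, computed in closed form and verified against an O(n²) brute
force in tests. "Expressing" means normalized expression > 0 (threshold
configurable); counting is unweighted by expression level, per the verbatim
counting description. Node drawing sizes are cell counts × 1/20 and edge
widths are pair counts × 1/4,000,000; the 10%-of-sender-cells ligand rule is
a draw/reporting flag only and never modifies counts. A small curated pair
table covering the canonical immune-checkpoint axes (PD-L1/PD-L2→PD-1,
CD80/CD86→CTLA-4, PVR→TIGIT, FGL1→LAG-3) plus a few stromal pairs ships as
`data/lr_pairs.tsv`.

## The synthetic-data generator

The generator emulates the structure of a mixed-species PDX 10x run well
enough that every downstream stage sees the statistical features it assumes:
two genomes with genome-tagged features; cell-type expression programs with
scattered marker genes; highly expressed housekeeping genes; mitochondrial
genes holding a configured fraction of depth (higher in "dying" cells);
cross-species ambient contamination; human+mouse doublet barcodes (the only
multiplet kind the 1% rule can detect); log-normal per-cell depth; and
negative-binomial counts (gamma–Poisson, shape θ) around the per-cell
program. Copy-number dosage multiplies the NB mean *after* program
normalization, so a dosage-1.5 segment yields exactly 1.5× the expected
counts of a diploid cell at equal depth — the linear dosage–expression proxy
that expression-derived CNV inference presupposes. Chromosomes are contiguous
equal-size gene blocks with synthetic coordinates; only the ordering matters
downstream. One integer seed drives named sub-streams per stage, and a fixed
config reproduces byte-identical matrices.

Default conditions (chosen once, as the study conditions): ~2,000 cells —
500 human tumor cells, 500 human stromal/immune cells (fibroblast,
macrophage, T cell), 1,000 mouse TME cells; 3,000 human and 1,500 mouse
genes on 10 chromosomes; mean depth 15,000 UMIs/cell (log-normal, σ = 0.25);
NB shape θ = 10; 3% mitochondrial fraction (25% in dying cells, rate 0 by
default); 0.5% ambient cross-species contamination; 1% multiplets; cycle
programs at strength 4 with 40% of tumor cells cycling and 40% non-cycling.

**Why the default tumor has two subclones.** The tumor carries two equal
subclones, each with one whole-chromosome gain (dosage 1.5) and one
half-chromosome loss (dosage 0.5); the union covers 30% of the human genome.
This is not cosmetic. With a single clonal profile and a balanced 500:500
tumor:normal mix, per-gene centering over all cells makes every normal cell
an exact mirror image of a tumor cell — identical CNV scores, perfectly
anti-correlated profiles — and the two-cutoff caller provably cannot separate
the groups. Subclonal, largely private arm-level events are both the realistic
regime (urothelial tumors are highly aneuploid and subclonal) and the regime
in which global-mean-referenced CNV inference works: each segment's carrier
fraction is ¼, so carriers deviate 3× as much as non-carriers. The two
subclones are kept score-symmetric (same gain/loss composition) so the
top-5% reference set mixes both rather than being captured by the
higher-scoring loss-heavy clone. Depth and dispersion defaults were fixed at
design time such that the planted ±log2-dosage signal is comparable to the
per-gene noise after standardization — the regime the method's fixed
0.02/0.2 cutoffs presuppose.

What the generator does **not** emulate: read-level data (FASTQ/UMI
collisions), batch effects, within-species doublets, ambient profiles that
differ from the cell-type mix, gene-length effects, spliced/unspliced layers,
and real gene–gene correlation structure. Tests passing on this generator
therefore demonstrate correctness of the pipeline's logic and its parameter
recovery under the stated model, not performance on any particular real
dataset.

## Numerical and problem-size choices

Tolerances: exact-arithmetic oracles are compared at ≤ 10⁻¹² absolute;
stochastic recovery checks use the stated thresholds (malignancy accuracy
≥ 0.95 with ≤ 10% undetermined; annotated-type ARI ≥ 0.9; cycling recovery
≥ 0.90; subtype recovery ≥ 0.95 over 200 replicates; DE null KS p > 0.01 at
2,000 genes). Test and acceptance problem sizes (≈ 2,000 cells × 4,500
genes; 120 × 2,000 null DE; 1,000 enrichment draws) were chosen as the
smallest sizes at which those statistics are stable; the full acceptance
script runs in well under a minute per stage on one CPU. Degenerate inputs
are handled explicitly: zero-depth cells are a hard error at normalization
(QC removes them first); zero-variance genes standardize to zero and are
never "variable"; a constant CNV reference profile yields undefined
correlations and all-undetermined calls with a logged error; an empty
ligand–receptor pair table yields an empty network with a warning.

## Known limitations

The malignancy caller inherits the limitations of global-mean referencing:
a perfectly clonal tumor in a balanced mixture is unidentifiable without an
external diploid reference, and the fixed 0.02/0.2 cutoffs are calibrated to
the noise scale of typical droplet data rather than adaptive. The enrichment
score is monotone-equivalent to, but numerically different from, GSVA. The
subtype classifier assumes centroids and samples share a measurement scale
up to an affine transform (Pearson r is location/scale-free per gene set,
but cross-platform batch effects are out of scope). The chi-squared
composition test treats cells as independent draws, ignoring within-sample
correlation.
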