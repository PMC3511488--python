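# Methods

## Mixture model and notation

A biopsy from patient `i` is modeled as a two-component mixture with tumor
fraction `f_i ∈ (0, 1]`. The single-channel intensity of gene `k` is
`I_ik = α (f_i E_tumor,k + (1 − f_i) E_nontumor,k)` where `α` converts RNA
amount to signal; the matched universal-reference channel reads
`α E_ref,k`. Only one tumor population per sample is assumed, and the
tumor expression vector is shared across patients (the heterogeneity
between patients enters through `f_i` alone). The fusion-transcript
abundance is `R_i = f_i / β` with `β` unknown. Neither `α`, `β` nor any
`f_i` is ever estimated: all downstream inferences use only quantities in
which they cancel.

Two exact consequences of the model are used throughout:

* with `E_ref = E_nontumor`, observed and tumor-referenced expression
  ratios inter-convert by `<r> = f (r − 1) + 1` and `r = (<r> − 1)/f + 1`
  (mutual inverses on `f ∈ (0, 1]`);
* eliminating `f_i` gives `I_ik(R_i) = α_k + β_k R_i` with
  `sign(β_k) = sign(r_k − 1)`, and the sign is invariant to rescaling `R`
  by any positive constant.

The slope analysis is deliberately qualitative: experimental variation is
not cancelled in ratio form, so the method classifies direction
(tumor-enhanced vs tumor-reduced) and does not estimate expression ratios.

## Preprocessing

Genes are kept only when called Present on every sample array and every
reference duplicate (complete cases; no imputation). Ratios to the
reference are taken per array and then averaged across replicates in log2
space — i.e. the geometric mean of replicate ratios — before patients are
pooled by the arithmetic log-space mean. Log base 2 is the microarray
convention; reporting on the ratio scale is `2^x`. The ratio-then-average
order follows from the ratio being defined per array.

## PCA trimming

The pooled tissue profile and the cell profile form one 2-D point per
gene. The 2×2 covariance (not correlation — both axes share log2-ratio
units) is eigendecomposed; PC1 is oriented into the (+,+) quadrant and PC2
so that its positive side faces the tissue axis. For standardized inputs
with correlation ρ the PC1 variance fraction is `(1 + ρ)/2`, which the
tests verify by simulation.

Background elimination overlays an `n_x × n_y` grid (default 50×50) on the
bounding box of the scatter and removes every point whose cell count
strictly exceeds the 90th percentile of counts. The percentile is taken
over **occupied** cells: empty cells carry no density information, and at
the cohort sizes simulated here a fine grid is mostly empty, so a
percentile over all cells would degenerate to zero and erase the entire
scatter. Under this rule a perfectly uniform occupancy removes nothing
(all counts tie, strict inequality). Ties on the PC1 line are assigned to
the "below" side, deterministically. Trimming operates in log-ratio space;
the grid is configurable (`GridSpec`).

## Clustering routes

*Dendrogram route.* Ward linkage on Euclidean distances, cut to exactly
`k = 5` clades per side: the above-PC1 genes clustered on the pooled
tissue profile (clades A–E) and the below-PC1 genes on the cell profile
(clades F–J). Labels follow left-to-right dendrogram leaf order and carry
no semantic claim.

*SOM route.* A rectangular 20×12 Kohonen map (240 nodes) is batch-trained
on the per-gene vectors across all patient replicate arrays (no replicate
averaging; 14 columns for the default cohort). Training uses a Gaussian
neighborhood whose radius decays linearly from `max(rows, cols)/2` to 1
over 200 epochs, with codebooks initialized on the first principal plane
of the data so the procedure is deterministic; random initialization is
available behind the seed. The first batch update under the widest
neighborhood can contract the PCA-spread codebooks and transiently raise
the quantization error; it is non-increasing from the second epoch on,
which is what the tests assert. Codebook vectors are then Ward-clustered
and cut at `k = 10` meta-clades; each gene inherits its best-matching
node's clade. Grid contiguity of meta-clades is observed but not
enforced. The per-clade tissue/cell ratio is the count of above-PC1 genes
over below-PC1 genes, with `inf` flagged when the denominator is empty.

## Over-representation and route intersection

Each meta-clade is tested against a GMT collection by the upper-tail
hypergeometric probability of its overlap with each pathway, with the
universe defaulting to the Present-call-filtered gene set (the pool the
clusters were drawn from). Rows are reported when the overlap has at
least 2 genes and raw p ≤ 0.05 — no multiple-testing correction, matching
the classic raw-p reporting convention of this analysis style; a
Benjamini–Hochberg q-value is attached for information only. The
co-occurrence matrix counts, for every (dendrogram clade, SOM clade)
pair, the pathways significant in both; the shared-gene table unions the
overlap genes per co-occurring pathway and flags genes found by both
routes.

## Fusion-slope fits and classification

Per gene, ordinary least squares of intensity on `R_i`. Replicates are
collapsed to per-patient geometric means before fitting (n = 7) so
replicate pseudo-replication does not inflate the correlation
significance; a switch fits on all arrays instead. The p-value is the
two-sided t-test of the Pearson correlation; `fit_gene_slope` reports a
thresholded sign (null unless p ≤ 0.05, configurable).

Classification of the shared-pathway genes, however, defaults to the raw
slope sign with p reported per gene rather than gating on significance.
The sign is the inference target of the model — the analysis reduces to
identifying non-zero slopes, i.e. positively or negatively correlated
genes — and at n = 7 a hard p-gate discards a material fraction of
genuinely directional genes; biologically interesting positive
correlations can carry p-values above 0.05 in cohorts this small.
`require_significance=True` restores the gated behavior.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 7
patients × 2 replicate arrays plus one cell-line profile (duplicate
arrays), 2,000 genes by default, tumor fractions uniform on [0.1, 0.7],
`α = β = 1`. Reference expressions are log-normal (log2 mean 7, sd 1.2);
non-planted tumor/non-tumor baselines deviate from the reference with
correlated log2 noise (sd 1.0, correlation 0.95) so a dominant first PC
emerges as in real tissue/cell comparisons. Measurement noise is
multiplicative log-normal with log2 sd 0.25 per value — a typical
microarray replicate error — and detection calls threshold raw intensity
at 5. Fusion measurements are noise-free by default (`R_i` is treated as
observed), with optional log-normal noise.

Planted modules pin `E_nontumor = E_ref` and `E_tumor = r E_ref`, so
their observed ratios follow `<r> = f(r − 1) + 1` exactly and the ground
truth of every recovery test is analytic. The default cohort plants two
60-gene modules at r = 6 and r = 1/6. Planted genes' reference expression
is floored at `2^6` (about 13× the detection threshold): the modules
emulate disease genes drawn from the *detected* gene set, and ground
truth planted below the detection limit would be unrecoverable by
construction rather than by failure of the method. A
`nontumor_equals_reference` switch sets the whole cohort to the
`E_ref = E_nontumor` regime used by the ratio-transform identities.

What the generator does **not** emulate: probe-level effects and
per-probe detection p-values, batch/array spatial artifacts, correlated
gene-gene noise, multiple tumor subpopulations, and real pathway
structure (planted pathways are exact module blocks plus random decoys).
Passing recovery tests therefore demonstrates correctness of the
algorithms under the model's own assumptions, not performance on real
arrays.

## Problem sizes and numerical choices

Recovery suites run at the defaults above (2,000 genes; sign-recovery
experiments use 240 planted genes spanning two- to eight-fold changes in
both directions at 300 genes total); these sizes give stable estimates
while keeping the full suite fast. Degenerate inputs raise typed errors:
zero-variance PCA input, constant fusion abundance, non-positive
intensities at the log step (named gene), empty universe. A constant gene
yields slope 0, pcc 0, p 1, sign null rather than NaN propagation. All
randomness flows from a single integer seed; summaries embed a hash of
the scientific configuration (output paths excluded) and are
byte-reproducible for a fixed seed.

## Known limitations

* The slope model assumes one tumor population and a shared tumor
  expression profile across patients; two-population mixtures are out of
  scope.
* Quantitative ratio estimation from patient data is out of scope by
  design.
* At n = 7 patients the correlation p-values are coarse; they are
  reported per gene but classification does not gate on them by default.
* Headline gene counts from any particular real study (e.g. how many
  genes survive trimming) depend on the platform, the curated pathway
  database and the cohort, and are not reproducible from synthetic data;
  the pipeline reports its own counts per stage instead.
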