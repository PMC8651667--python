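# Methods

This note documents the models implemented in `genescout`, the defaults that
matter, the numerical choices, and what the synthetic studies do and do not
demonstrate.

## Data model and identity conventions

All tables are TSV with a header row, UTF-8, no quoting; gene sets are flat
GMT with the namespace (BP/CC/MF) encoded in the description field. Gene
identity is matched case-sensitively on `gene_id` everywhere; symbols are
display-only. The reader layer is strict: every container invariant
(non-negative integer counts, unique ids, one condition per timepoint,
non-empty gene sets, non-negative literature hits) has a corresponding error
path. Timepoints named `E<d>`/`P<d>` are ordered embryonic-before-postnatal,
numerically within stage; other names keep file order.

## Batch correction

Counts are modelled per gene g and batch b as NB(μ_gb(c), α_gb) with the
stage condition c (embryonic/postnatal) as covariate. Under a log link with a
batch-specific intercept and a categorical condition covariate the design is
saturated, so the ML mean of each (gene, batch, condition) cell is the cell's
sample mean; cell means are floored at 0.05 so the CDF map stays defined for
cells that happen to be all zero. Dispersion is estimated per (gene, batch)
by profile maximum likelihood over log α ∈ [log 1e−8, log 50] with a
vectorized golden-section search (all genes at once); rows whose optimum sits
at the upper search bound fall back to a method-of-moments estimate and are
flagged in the model diagnostics.

The batch-free target distribution pools the batch fits, weighting by
per-batch sample count; empirical-Bayes shrinkage of batch parameters (as in
the reference ComBat-seq implementation) is deliberately not reproduced — the
target is the method's two-moment structure, not numerical parity.

Adjustment maps each count y in batch b through the midpoint percentile
p = (F_gb(y−1) + F_gb(y))/2 (deterministic and unbiased for a discrete CDF,
unlike a randomized quantile) to q = min{q : F*(q) ≥ p}. The map is monotone
in y, produces non-negative integers, and is short-circuited to the exact
identity wherever source and target parameters coincide — in particular on
single-batch input. Genes with all-zero counts in any batch have an
unidentifiable batch distribution and are passed through unchanged, flagged
`excluded`. The condition covariate protects real biology from being absorbed
into batch means; it can be disabled (`include_condition=False` /
`--no-condition-covariate`). On simulated two-batch data with a planted 2.5×
batch effect and a 4× condition effect (2000 genes, 6+6 samples, α = 0.1) the
adjustment removes the batch ratio (median |log2 ratio| from ≈1.32 to <0.01)
while the condition ratio stays at 4× within a few percent — these numbers
are recomputed by the test suite and `scripts/acceptance.py`, never stored.

## Differential expression

A deliberately transparent stand-in for the usual NB DE machinery, keeping
its input/output contract (baseMean, log2FoldChange, lfcSE, pvalue, padj):

- **Size factors**: median-of-ratios in log space over reference genes
  (positive in every sample), rescaled to geometric mean 1. Rescaling one
  sample's column scales its factor proportionally; normalized counts shift
  only by the column's contribution to the per-gene geometric mean
  (const^(1/n_samples)), which with the ε pseudo-count bounds the fold-change
  drift at well under 1% for typical counts.
- **Dispersion**: pooled within-condition method of moments on normalized
  counts, α = (var − mean)/mean², weighted by within-condition degrees of
  freedom and floored at 1e−8 (the Poisson limit). No shrinkage toward a
  mean–dispersion trend.
- **Wald test**: log2FC = log2((m_B + ε)/(m_A + ε)) with ε = 0.5 so fold
  changes stay finite at zero means; the SE comes from the delta method with
  Var(m) = Σ_j (μ̂_j + αμ̂_j²)/s_j² / n². The statistic is referred to a
  **t distribution with (n_A − 1) + (n_B − 1) degrees of freedom**, not a
  normal: the dispersion is a plug-in estimate from few replicates, and with
  a normal reference the null rejection rate at 0.05 inflates to ≈0.085 at
  6 vs 6 replicates (measured), while the t reference restores ≈0.05.
- **BH adjustment** is the standard step-up, implemented directly (it is part
  of the package's contract and is cross-checked against statsmodels in the
  tests).
- **Top-DEG selection** defaults to the study design: genes at p < 0.05
  ranked by ascending p-value (configurable to padj), ties broken by
  |log2FC| descending then gene_id, truncated to n = 3000.

Omitted relative to full DESeq2: dispersion shrinkage, Cook's outlier
filtering, independent filtering, LFC moderation. Consequently p-values are
well calibrated but slightly less powerful at very low counts.

## Normalization to temporal profiles

TPM_gj = (c_gj/L_g) / Σ_h (c_hj/L_h) × 10⁶ with annotation union-exon
lengths; per-timepoint expression is the **median** TPM across replicates
(robust to a single aberrant replicate); each gene's profile is z-scored with
the sample standard deviation (n−1, matching common `scale()` semantics;
configurable). Constant genes are flagged and set to an all-zero profile
rather than dropped, so cluster membership accounting matches the selected
gene count.

## Cluster number and clustering

W_k is the within-cluster sum of squared Euclidean distances to centroids
(algebraically identical to the pairwise form Σ_r D_r/2n_r, asserted in the
tests). The reference null draws each feature uniformly over its observed
[min, max] — the simpler of the two classical choices; PCA-rotated references
are not implemented. Gap(k) = mean_b log W*_kb − log W_k and
s_k = sd_b(log W*_kb)·√(1 + 1/B). Defaults: kmax = 100 (clipped to
n_items − 1 with a warning), B = 50 references, k-means with 10 k-means++
restarts inside the gap evaluation. K selection defaults to the 1-SE rule
(smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}); `global_max` is available, and
the full curve is always exported so a human can choose from the plot. The
final gene assignment defaults to hierarchical clustering with Euclidean
distance and complete linkage (well-balanced clusters on temporal profiles);
gap evaluation and final assignment are independently configurable. All
randomness flows from one seed through a fixed-order draw of reference
datasets and per-fit k-means seeds, so curves are bit-reproducible.
scikit-learn's k-means relocates empty clusters internally, so the
empty-cluster restart case does not arise; `fcluster` can merge duplicate
points, in which case the assignment relabels contiguously and warns.

## Enrichment

One-sided hypergeometric over-representation per (cluster, term):
p = P(X ≥ k) for X ~ Hypergeom(N, K, n). The default universe is the set of
analyzed (DEG-selected) genes that appear in at least one gene set; term
sizes are filtered to 10–500 **after** intersecting with the universe. BH is
applied within each (cluster, namespace) — p-values in one cluster never
influence another cluster's padj. Depletion testing and q-value estimation
are out of scope. Cluster members outside the universe are dropped from the
tested list (clusterProfiler's behavior); calling `enrich_cluster` directly
with out-of-universe genes is an error.

## Discovery

A cluster is *functional* iff it contains ≥1 known gene **and** ≥1
user-specified target term with padj < α (default 0.05). Candidates are its
members that are not on the known list, have zero literature hits, and have
positive expression evidence. Genes with no evidence row are treated as
documented — absence of evidence data can only suppress candidates, never
fabricate them. An optional rising-trend filter (mean postnatal z above mean
embryonic z of the cluster profile) is available and off by default; each
functional cluster's mean temporal profile is exported so the trend judgment
can also be made by eye. Ranking uses the maximum z-score over postnatal
timepoints (descending, ties by gene_id); this criterion is the package's own
choice — no published ordering exists — and the report says so. Shrinking α
never adds candidates (designation is monotone in α).

## Synthetic data

The generator emulates the structure of a two-batch mouse retinal development
study: 12 timepoints E11–P28 (6 embryonic, 6 postnatal), 2 replicates per
timepoint with replicate r assigned to batch ((r−1) mod n_batches), NB counts
with per-gene log-normal base means (median ≈ 80, log-sd 1.0), dispersion
α = 0.1, batch factors 1.8× on the mean and 1.5× on dispersion for the second
batch (a moderate, realistic technical effect), and planted temporal modules:
rising to a P10–P14 peak (80 genes, containing 10 "known" genes and 3 planted
unannotated candidates), falling (80), transient early-postnatal (80), and
flat background (260). The generator also emits the evidence table (known
genes documented; candidates zero-hit with expression; a 5% sliver of
background genes zero-hit *without* expression to exercise the conjunction
rule), a target gene set holding exactly the functional module's
known+candidate genes, and 20 random decoy sets — so discovery needs no
external ontology. Independent RNG streams (counts, lengths, base means,
decoys, evidence) are spawned from one seed, so adding a stream never
perturbs another and fixtures are byte-stable.

A separate direct z-profile simulator plants k distinct smooth temporal
shapes (staggered sigmoids, mirrored, plus bumps) with iid Gaussian noise and
per-gene re-z-scoring, for clustering and gap-statistic studies where count
noise is not the object.

**What passing tests show — and don't.** The generator's NB/batch/module
structure matches the models the pipeline fits, so end-to-end recovery
(precision = recall = 1 for planted candidates; batch ratios removed;
calibrated DE) demonstrates internal correctness, not real-data performance.
Real data differ in ways the simulation does not capture: mean–dispersion
trends, gene–gene correlation, library-composition effects, annotation
errors, and literature evidence that is itself noisy. On real count data with
2 replicates per timepoint, profile noise also blurs pattern boundaries: in
the default synthetic study the 1-SE gap selection typically lands at K = 5–8
rather than the 3 planted shaped modules, splitting patterns — yet the
candidate set is recovered exactly because the functional module stays within
one enriched cluster. This mirrors the practical observation that discovery
is robust to the exact K, with coarser K costing curation effort and finer K
risking dropped genes.

## Problem sizes and determinism

The shipped studies use desk-scale sizes chosen to exercise every code path:
500-gene end-to-end runs, 2000-gene batch/DE studies at 6 vs 6 samples,
300-profile gap studies with B = 20 and kmax = 15. `run_pipeline` writes a
manifest (config hash excluding the output directory, seed, per-artifact
SHA-256) with no timestamps, so identical seed and config give byte-identical
manifests. All seeds derive from a single integer via `numpy.random.SeedSequence`.

## Known limitations

- Batch parameters are not shrunk across genes; very small batches rely on
  the MoM fallback and the mean floor.
- The DE stage's t-reference calibration assumes roughly balanced designs;
  heavily unbalanced designs would warrant a Satterthwaite-style df.
- The GMT reader handles flat namespaces only (no ontology graph, no term
  ancestry propagation).
- Evidence is a static local table; it reflects whatever curation produced
  it, and the candidate definition inherits its biases.
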