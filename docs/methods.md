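# Methods

This note documents the models implemented in `centfinder`, the
parameter defaults and why they were chosen, the numerical decisions
that affect reproducibility, and what the synthetic-data generator
does and does not emulate.

## Ingestion and normalisation

Sample inclusion applies four rules to SDRF-like metadata: an organism
whitelist, a label whitelist (biotin, i.e. Affymetrix-style
labelling), a platform-id prefix whitelist, and a case-insensitive
substring denylist on the free-text characteristics. The denylist
default (`carcinoma, tumor, tumour, cancer, hcc`) operationalises
"non-cancerous origin"; there is no canonical list, so it is a
configurable parameter, not a fixed rule.

Probe intensities are aggregated per gene by geometric mean (the mean
of log intensities), which is the natural average for multiplicative
intensity noise; non-positive intensities among mapped probes are an
error because their logarithm is undefined.

`quantile_normalize` forces every sample onto the common reference
distribution given by the pointwise mean of the sorted sample vectors.
Ties receive the mean of the reference values over the tied block, so
the map is deterministic and rank-preserving. This is a summary-level
convenience, deliberately weaker than probe-level RMA: background
correction and probe-level median polish are out of scope, and the
pipeline accepts externally normalised matrices as input.

Platform selection maximises (total samples) × (common genes) over
all platform subsets containing the forced set — exhaustive up to 20
platforms, greedy forward selection above that. Ties are broken by the
lexicographically smallest platform-id set. The `forced` parameter
exists because the rare cell type of interest may only be available on
a platform that the product rule would otherwise discard.

Linear-scale matrices are transformed with log2(x + 1); the +1 offset
tolerates zeros and stabilises low intensities.

## Batch adjustment

`CombatAdjuster` implements the parametric empirical-Bayes
location-scale model: expression is standardised gene-wise using the
batch-size-weighted grand mean and the variance pooled over
batch-centred residuals; per-batch gene-wise location (γ) and scale
(δ²) estimates are shrunk towards moment-matched priors (normal for γ,
inverse-gamma for δ²) by iterating the conditional posterior means to
a fixed point (tolerance 1e-4, ≤ 500 iterations — unstated in the
original description; chosen small enough that the result is
deterministic to ~1e-5). The adjusted value is
x* = σ·(z − γ*)/√δ²* + α. A unit test verifies the implementation
against frozen output of the standard R implementation (sva::ComBat)
on a fixed design, agreeing to ~2e-5.

Properties worth knowing:

- Shrinkage leaves a residual per-gene location effect of roughly half
  the sampling noise of the batch means when effects are homogeneous
  across genes; consequently batch means are equalised *in aggregate*
  and per gene only up to that residual, and the post-adjustment
  between-batch F statistic falls to or below chance level (exact
  per-gene removal would drive it to zero). The tests assert these
  behaviours rather than exact equality.
- Genes with zero pooled variance carry no batch information; they are
  passed through unadjusted (division guard) and flagged.
- One batch ⇒ the model is the identity. A batch with a single sample
  is an error (its variance is undefined).
- Covariates are not modelled (the workflow passes none); the
  non-parametric prior and reference-batch variants are non-goals.
  If both platform and study effects must be removed, the module can
  be applied sequentially with each key; the composition is the
  caller's choice.

## Gene filtering

TFs are kept iff their log2 range (max − min over samples) is ≥ 1,
i.e. at least a twofold change on linear scale — the max/min reading
of "changed at least twofold across samples", which is what a
variability filter means (the every-pairwise reading would be
stricter and exclude almost everything). Non-TF genes are ranked by
the standard deviation of their log2 values and either thresholded
(`sd_threshold`) or kept top-down until a total gene budget
(`total_cap`) is filled; ties at the boundary break by gene symbol so
the result is deterministic.

## Co-expression network and modules

The signed similarity s = (1 + cor)/2 maps Pearson correlation to
[0, 1] so that anti-correlated genes are *dissimilar* (an unsigned
network would conflate them). Raising s to a power β suppresses weak
correlations; β is chosen as the smallest value in 1..30 whose
scale-free fit index reaches `r2_cut = 0.8` (the customary criterion;
exposed as config), falling back to the best-fitting power when none
reaches it, with a warning when even the best fit is negligible.

The fit index regresses log10 degree-density on log10 mean
connectivity over 10 equal-occupancy connectivity bins and is
sign-corrected so that only decaying distributions score positively.
With equal-occupancy bins the raw bin frequencies are constant by
construction, so the density estimate count/(n·width) is used — this
is the quantity that is log-log linear under a power law, verified by
a test on an exactly Pareto-distributed degree sequence.

Topological overlap is
ω_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
ℓ_ij = Σ_{u≠i,j} a_iu a_uj; it is computed by matrix product with a
zeroed diagonal (exactly equivalent to the triple loop, which serves
as the oracle in tests). Modules are branches of the average-linkage
dendrogram of 1 − ω.

**Cut height.** The static cut is applied at
`cut_height × (maximum merge height)`, default 0.9, rather than at a
fixed absolute height. The absolute scale of TOM dissimilarities
varies with noise level and power — the all-noise merges concentrate
just below a data-dependent top (e.g. 0.989 at β = 7 but 0.999 at
β = 12 on the same data) — so any fixed absolute cut is brittle,
which is precisely why dynamic tree cutting exists. The relative cut
is deterministic, has one interpretable parameter, and cleanly
separates planted modules from noise across the regimes exercised in
the tests. Branches smaller than `min_module_size = 30` fall into the
grey (unassigned) pool.

Module labels are colours in decreasing size order
(turquoise, blue, brown, …), with size ties broken by first-gene
position. The eigengene is the first right singular vector over
samples of the gene-wise z-scored module submatrix, sign-oriented to
correlate non-negatively with the module's mean z-profile and
unit-norm by construction. kME is the Pearson correlation of each
gene's profile with each eigengene. Modules whose eigengene
dissimilarity 1 − cor falls below `merge_cut = 0.3` are merged
iteratively (closest pair first, absorbed into the larger module),
with eigengenes recomputed after every merge.

## Motif enrichment and regulons

For a module gene set S and motif m with ranking r_m over N genes,
the recovery curve rec_m(x) counts members of S with rank ≤ x, and
AUC_m = Σ_{x=1..T} rec_m(x)/(T·|S|) with T = ⌈`top_frac`·N⌉.
`top_frac` defaults to 0.05 — the creators of the reference method
recommend inspecting only the top few percent of the ranking; the
exact fraction is exposed as config. NES standardises AUC against all
motifs in the database for the same gene set (mean 0, sd 1 by
construction); motifs with NES ≥ 3 are reported. The leading edge
takes the members of S ranked at or before the position where rec_m
most exceeds the across-motif critical curve mean(rec) + 2·sd(rec), a
reimplementation of the reference method's significant-gene
extraction. Regulons union the leading edges of a TF's enriched
motifs within a module and record the best NES. Only direct motif→TF
annotations are used by default (the smallest defensible annotation
tier); orthology-inferred tiers can be merged upstream if desired.

## Module activity scoring

Gene-set variation scoring follows the reference method's defaults
(Gaussian kernel CDF, bandwidth s_g/4 floored at 1e-8 for constant
genes, τ = 1, `mx_diff` scoring): per gene a smoothed ECDF across
samples, per sample a descending ranking of those statistics, a
symmetric rank statistic |N/2 − rank|, and a weighted
Kolmogorov–Smirnov random walk whose in-set steps are weighted by the
rank statistic and out-of-set steps by 1/(N − |S|). With `mx_diff`
the score is (max positive deviation) + (min negative deviation),
bounded in [−1, 1]. Scores are relative to the cohort being scored
(each sample's ECDF uses all samples of the call).

"More active in the target cell type" compares the target samples'
mean score against the pooled mean of all other samples (strict
inequality); a stricter per-type mode (`per_type=True`) requires the
target mean to beat every other cell type individually.

GO annotation of modules uses the one-sided Fisher exact test on the
2×2 in-module × annotated table, keeping the top 15 terms per
category (BP/CC/MF), ties broken by term id. Annotations are expected
pre-propagated to ancestors; `propagate_obo` provides a minimal
is_a/part_of propagation so ontology releases need not be bundled.

## Differential expression

Merged exon length is the total length of the union of a gene's
1-based inclusive exon intervals (strand-independent, adjacent
intervals merge); TPM divides counts by these lengths and rescales
each sample to 10⁶.

`nb_wald_de` is a deliberately plain two-group negative-binomial Wald
test: median-of-ratios size factors over genes with all-positive
counts; a method-of-moments gene-wise dispersion
α = max((s²_within − μ̄)/μ̄², 1e-8) from pooled within-group
variability of normalised counts; an IRLS fit of the log-linear group
model with size-factor offsets, vectorised across genes; Wald
z = β̂/SE with two-sided normal p; BH adjustment; and the combined
significance rule padj < 0.05 *and* |log2FC| ≥ 1 (twofold biological
relevance). There is no dispersion shrinkage towards a mean trend and
no fold-change shrinkage — the estimator is exercised only on
synthetic data, where its null calibration (raw-p rejection ≈ 0.065
at nominal 0.05 with 10 samples/group, the residual inflation coming
from plug-in dispersion estimates) and planted-effect recovery are
verified directly.

Marker testing uses the two-sided Wilcoxon rank-sum test — exact
enumeration when both sides have ≤ 8 observations and no ties, the
tie-corrected normal approximation otherwise — with linear-scale
fold changes of group means. The cross-dataset consensus rule keeps
genes whose fold change exceeds the threshold (default 7) in every
supplied dataset, ranked by the compendium fold change; infinite fold
changes (zero denominators) survive the threshold by design and are
logged. A configurable quality gate (all required marker genes at
TPM > 1) screens out mislabelled samples before DE.

## TF ranking and export

A (TF, module) pair is a candidate iff (a) the TF is significantly
up in the target cell type (padj and twofold via the significance
rule; `require_twofold=False` relaxes to padj-only), (b) its kME in
that module exceeds 0.5 — the module need not be the TF's assigned
module, so one TF can legitimately appear for several modules,
(c) the module is more active in the target cell type, and (d) the TF
has a regulon there with NES ≥ 3. Ranking is by fraction of the
module covered by the regulon, ties by |log2FC| then symbol. Export
caps edges at the 20 most differentially expressed targets per TF;
node colour is the module colour (cross-module central TFs are
recoloured to the module of interest), shape encodes the DE direction
(ellipse up, rectangle down), and size is 10 + 2·out-degree — the
underlying convention is only that size grows with the number of
targets; the affine map is a rendering choice.

## Synthetic data

`simulate_expression` draws
x_gj = loading_g · f_{m(g),j} + batch_b(j) + ε_gj + 8, with a latent
factor per module and sample, f ~ N(mean_{m,celltype(j)}, 1),
loadings ~ U(0.5, 1) (keeping every module gene informative),
ε ~ N(0, 0.5), and an additive baseline of 8 mimicking log2 intensity
levels. Defaults: 2000 genes, 60 samples, three 50-gene modules,
three cell types (module m active with factor mean 2 in cell type m),
no batch shift. One planted TF per module carries a fixed loading of
0.9 so its centrality is high by construction. Batches alternate
within cell types so batch and cell type are never confounded.

`simulate_ranking_db` places each planted TF's targets uniformly at
distinct ranks within the top quantile of its motif's ranking and
fills everything else, and all decoy motifs, with random
permutations. `simulate_counts` draws NB counts with the planted
log2FC split symmetrically between the groups
(mean·2^{±lfc/2}; mean 100, dispersion 0.05, 10 samples/group by
default). `simulate_study` ties the three generators together: one
planted TF per module, regulons covering 60% of their module, top
quantile 0.02 (wide enough to hold a 30-target regulon in a
2000-gene universe), counts per cell type against a shared reference
with the cell type's TF strongly (log2FC 3) and its module genes
moderately (log2FC 1.5) upregulated, and a two-batch shift of 1.0
removed by the pipeline's adjustment step.

What the generator does *not* emulate: probe-level microarray noise,
mean–variance trends across the dynamic range, correlated noise
between modules, dropout or library-size extremes of single-cell
data, motif rankings with realistic rank correlations between related
motifs, and annotation noise. Passing the planted-truth tests
therefore demonstrates correctness of the algorithms under their own
model assumptions — not performance on real compendia, where
preprocessing quality and confounding dominate.

`positivity_summary` is the small reporting helper for imaging-style
count data (n positive of N cells): percentage to two decimals plus a
95% Wilson score interval, preferred over the Wald interval for its
behaviour near 0% and 100%.

## Problem sizes and determinism

The test suite and the acceptance script run on the generator
defaults above (2000 genes × 60 samples; 200-motif databases;
2000-gene × 20-sample count matrices; 50-replicate null calibrations)
— sizes at which every planted structure is comfortably recoverable
and the whole suite completes in well under a minute of compute per
stage. All generators are bit-reproducible given a seed;
`scripts/acceptance.py` derives every sub-seed from its `--seed`
argument. The pipeline itself is seed-free: given the same inputs it
is fully deterministic (tie-breaks are lexicographic or
position-based throughout).

## Known limitations

- The scale-free fit index is meaningless for very small gene sets;
  power selection should be overridden manually below a few hundred
  genes (the small-fixture tests pass β = 12, the conventional signed
  default).
- The static relative cut has no notion of branch shape; deeply
  nested sub-modules that dynamic tree cutting would split stay
  merged unless the eigengene merge step separates them (it cannot —
  it only merges), so module granularity is governed entirely by
  `cut_height`.
- The NB Wald test's mild anticonservatism at small n (see above) is
  inherent to plug-in dispersion estimation; a shrinkage or
  quasi-likelihood t reference would tighten it but is out of scope.
- GSVA scores are cohort-relative; scoring different sample subsets
  changes individual values (not their ordering within a cohort).
- The greedy platform-selection mode (> 20 platforms) is a heuristic
  and can miss the optimum; the exhaustive mode is exact.
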