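# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices that were
genuinely open.

## Per-feature OLS machinery

All associations and corrections run through one code path
(`linear_models`). Design matrices are one-hot encoded with drop-first
contrasts and explicit reference levels — Disease→Control, Region→VC,
Sex→Female — so the disease main effect is the AD−Control contrast in VC and
the Disease×Region interactions test whether that contrast differs in PFC or
TC. Inference is classical OLS: normal-equations coefficients, standard
errors from σ̂²(XᵀX)⁻¹, and two-sided t-tests on residual degrees of freedom
(statsmodels serves as the independent cross-check in the tests, never as
the implementation). Conventions where the procedure is otherwise silent:

- a zero-variance response reports all-zero coefficients with P = 1;
- features observed in fewer than 5 unique donors, with all values missing,
  or with a rank-deficient design are flagged (`skipped_min_donors`,
  `skipped_all_missing`, `rank_deficient`) and excluded from FDR;
- observations missing any covariate are dropped listwise per feature;
- Benjamini–Hochberg q-values are computed per model term across features,
  with missing p-values propagated.

Batch correction fits the full covariate model (batch + age + sex + region
+ disease + donor) and subtracts only the fitted batch component B·β̂_batch,
preserving the intercept and all biological terms. Because donor determines
disease, age and sex, this design is rank deficient by construction; the fit
uses a minimum-norm (pseudo-inverse) solution, under which the batch
component is still identified as long as batch varies within donors. When
batch is perfectly confounded with the kept covariates the values are
returned unchanged with a warning. Donor enters the batch-correction design
but not the association design, matching the two procedures' printed forms.

## Hypomethylation score

For each cell, the expected methylation probability p is the mean per-bin
methylation fraction over that cell's covered bins. The printed form of this
expectation reuses the coverage symbol ambiguously; the fraction reading is
the only one that yields a probability, and it is the one implemented. Each
bin's score is the binomial survival probability P(X > m), X ~ Binomial(c, p),
evaluated through the regularized incomplete beta (stable for coverages up
to 10⁷) rather than naive pmf summation. Scores are antitone in m at fixed
(c, p). Bins with zero coverage are missing and binarize to 0; binarization
is strictly score > 0.9. QC thresholds are strict inequalities as printed
(a cell at mCCC = 0.05 exactly fails).

## Global-methylation cell states

Global CG/CH levels measured on the second instrument are mapped onto the
first through an OLS line fit on shared libraries (the same library
sequenced on both machines); with fewer than two usable pairs the identity
map is applied with a warning. K-means (k = 3, 10 seeded restarts) runs on
the normalized (CG, CH) plane separately for neurons and non-neurons, and
raw cluster ids are relabeled to fixed semantics by centroid rank: lowest
CG → subgroup 0; of the remaining two, lower CH → subgroup 1, higher
CH → subgroup 2. This relabeling is a bijection whenever centroids are
distinct; the (CH, CG) tie-break cannot fire otherwise.

Subtype similarity clustering consumes a genes × `celltype:A_vs_B` log2FC
table. The source description of the per-gene adjacency fill is corrupted
mid-sentence; this implementation fills A(g)[i,j] with the signed log2FC of
i vs j and antisymmetrizes (A(g)[j,i] = −A(g)[i,j], diagonal and missing
entries 0) — the only reading consistent with a directed adjacency feeding
cosine geometry. The stacked tensor is flattened to (S·S) × G, gene-columns
are mean-centered (standard PCA convention; the source is silent), PCA is
capped at min(50, rank) so small instances remain valid, each subtype is
embedded as the mean of its row of transformed contrasts, and average-
linkage clustering of D = 1 − K is cut at two clusters. Which cluster is
"Stressed" is decided by the caller through a labeling hook (the pipeline
uses the subgroup-1 majority; a real analysis would use marker enrichment).

## Contact-distance score and classification

Distance bins are geometric (factor 2) from 25 kb to half the largest
chromosome — the binning behind the published analysis is a package default
that is not printed, so it is configurable here. The kernel uses 1-based bin
indices with center (N+1)/2 (for even N the center falls between bins) and
σ = N/6, normalized to sum to 1. Higher score ⇔ short-range enrichment is
not a mathematical law of this kernel; it holds empirically for geometric
binnings whose range extends well past the bulk of the contact mass, and the
test suite verifies the direction on the planted decay classes rather than
assuming it. Classification applies PCA (2 components) to the profile
matrix and k-means (k = 2) in PC space; the cluster with the higher mean
contact score is labeled Short. Score standardization (z-scoring across
cells) is flag-controlled, default on, and applied after scoring.

## TAD-boundary density

Boundary calls are binary per (cell, 25-kb bin); any signal in a bin counts
once per cell. Densities are events per cell within 1-Mb windows (window
assignment by genomic start coordinate), per (region, disease, donor, cell
type) sample. The mean cis-long-contact covariate (anchor separation
> 2,500 bp, matching the QC definition) is regressed out per window by OLS
and the residuals are the adjusted densities; windows with fewer than three
samples are mean-centered with a warning. The insulation boundary caller
(w×w diamond mean, local minima deeper than `min_depth` relative to
flanking maxima, tied-plateau minima deduplicated to their first bin, edge
bins excluded) is deliberately plain plumbing so the single-cell pipeline
runs end to end; its `min_depth` default (0.05) is a package choice, not a
published constant.

## Compartments, saddles, arm-scaled averages, deletions

ICE balancing iterates a multiplicative bias vector until its relative
change drops below 1e-5 (at most 200 iterations; non-convergence returns
the last iterate with a warning); all-zero rows are masked, and balanced
row sums over unmasked rows agree to better than 1e-3 relative. The
expected matrix replaces each diagonal band with its mean, so O/E of a
band-constant matrix is all ones. PC1 is the leading eigenvector of the
Pearson correlation matrix of O/E columns over unmasked bins, sign-flipped
so corr(PC1, GC) ≥ 0. Note that band-mean expectation depends on genomic
bin order, so PC1 is equivariant under order reversal but not under
arbitrary bin shuffles. Saddles rank bins by PC1 into equal-size quantile
groups (ties broken by bin order) and average cis O/E over group pairs,
pooled across chromosomes; the state comparison divides the Stressed saddle
elementwise by the Homeostatic one (zero denominators → missing).

Centromere-aligned averages split each eligible autosome (≥ 50 bins, known
centromere) at the centromere bin (binary search on bin starts), resize the
four blocks to a fixed 50 + 50 arm shape with corner-mapped bilinear
interpolation (clamped edges), form per-chromosome O/E from the resized
observed and band-mean expected (0 where expected is 0), and average;
NaN/Inf are coerced to 0. The fixed arm shape is not printed in the source
procedure; 50/50 is this package's default.

Putative deletions: per 100-kb bin and per (region × cell type × state)
balanced pseudo-bulk, the row sum is computed; zeros are recoded to
missing; bins missing in ≥ `min_missing` (default 10, as printed against
a dozen-plus pseudo-bulk columns — the parameter is exposed because the
source does not say whether it scales) but not all pseudo-bulks are
flagged and annotated with min(bin_start, chrom_length − bin_end). Whether
the published row sums used balanced or raw values at masked rows is not
stated; masked rows are treated as missing here.

## Differential loops

Group accumulators are reconstructed exactly as described: per-sample mean
and squared-mean matrices multiplied by contributing cell counts and
summed. The F transform itself is never printed in the source; this package
uses the standard one-way ANOVA F with df (g−1, N−g), isolated in a single
function so an alternative variance ratio is a one-line swap. SSW = 0 with
SSB > 0 yields a +inf sentinel ranked above all finite F; SST = 0 yields
F = 0 by convention. Masks: upper triangle only, 5–500-bin distance range,
±7-bin pad around blacklisted bins. Per-cell input values may be raw counts
or imputed probabilities; the accumulator contract is agnostic.

## Synthetic cohorts

The generator emulates the study conditions: 11 AD + 9 control donors, each
sampled in VC, PFC and TC (60 samples), 100 cells per sample by default, on
a 3 × 20 Mb synthetic genome with centromeres at 40% of each chromosome —
small enough that the full pipeline runs in well under a minute while every
downstream stage remains non-degenerate. Within that genome:

- **Methylomes**: negative-binomial coverage (mean 20, dispersion 5) per
  100-kb bin; methylated counts binomial with probability = context
  baseline (CG 0.75, CH 0.03, CCC 0.005, neurons +0.02 CH) + subgroup
  offset (CG −0.08/+0.04/+0.04; CH 0/0/+0.05) + region×disease shift
  (TC-AD +0.02, VC-AD −0.02, PFC-AD +0.01) + Gaussian jitter at
  `noise_scale`, mapped through an affine instrument relation
  (measured = 0.02 + 0.96 × true on the second instrument) and clipped to
  [0, 1] with a clip counter. With `noise_scale = 0` the emission is fully
  deterministic (constant coverage, expected counts), giving exact-fraction
  degenerate tests. The CH offset of the high-CH subgroup and the region
  shifts were fixed once at values giving visibly separated subgroup clouds
  and subtle-but-many-sigma-detectable global shifts, the regime the
  original statistics operate in.
- **Contacts**: exactly `contacts_per_cell` (default 1,500) rows per cell.
  Cis distances follow a truncated power law whose *density* exponent is the
  cell's decay class (Short 1.5, Long 0.8 — the contact-probability P(s)
  convention); 35% of cis contacts are resampled within the anchor's 1-Mb
  TAD block and 20% within same-parity 2-Mb compartment blocks
  (checkerboard); 5% are trans. For Stressed cells, contacts touching the
  20 planted deleted bins (all within 2 Mb of a chromosome end) are
  resampled until clean, so pooled Stressed coverage at those bins is
  exactly zero while per-cell depth is conserved.
- **Boundary calls**: planted boundaries every 1 Mb; per cell each planted
  boundary is dropped at 10%, jittered ±1 bin at 10%, and extra boundaries
  appear per 25-kb bin at 0.002 (0.004 in Stressed cells).
- **log2FC tables**: between-cluster comparisons carry a per-gene signed
  effect of magnitude δ (default 2), within-cluster comparisons are pure
  Gaussian noise (default 0.1).
- **Truth channel**: the Stressed state is planted as subgroup 1 (high
  CG/low CH, the TC-AD-enriched subgroup); the truth sidecar records every
  planted label, bin and effect, sufficient to score all recovery tests.

Randomness derives from a single seed; substreams are keyed by stable
CRC-32 hashes of sample ids (contact generation, vectorized per sample) or
cell ids (methylome emission, boundary calls), so outputs are byte-identical
across runs and machines for a given configuration.

What the generator does **not** emulate: read-level bisulfite chemistry and
non-conversion error, realistic karyotypes and chromatin-state-specific
contact structure, donor-level genetic variation, doublets, and expression
data (the log2FC tables are drawn directly). Passing tests therefore
demonstrate that the statistics recover the effects they were designed for
under their stated noise models — not that those effects are identifiable
in any particular real data set.

## Known limitations and observed sensitivities

- **Deletion detection requires near-pure state labels.** The strict
  zero-row-sum rule means a single misassigned cell contributes contacts to
  a deleted bin. With the planted state labels the detector achieves
  recall 1.0 with zero false calls across 20 deletion-free cohorts; with
  the pipeline's own k-means-predicted labels (≈ 99% accurate), the ~1%
  contamination suppresses essentially all calls at default depth. This is
  a real property of the method, visible in the end-to-end demo.
- The Stressed-state saddle ratio in the demo shows mild AA/BB weakening
  because the uniform resampling of deleted-bin contacts dilutes the
  planted checkerboard in Stressed cells; the generator does not plant a
  directional compartment-strength difference between states.
- The insulation boundary caller is a stand-in for a published TAD caller
  and is only exercised on block-structured synthetic matrices.
- PC1 equivariance holds under bin-order reversal but not arbitrary
  shuffles (band-mean expectation is order-dependent).

## Problem sizes

Defaults were chosen so the full test suite runs in about two minutes and
the demo pipeline in under half a minute on one CPU: 60 samples × 100
cells, 1,500 contacts per cell, 600 methylation bins (100 kb), 600 contact
bins (100 kb), 2,400 boundary bins (25 kb). All sizes are configuration
fields and scale up without code changes.
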