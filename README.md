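# epistate3c

Statistics for joint single-nucleus DNA-methylation + chromosome-conformation
(snm3C-style) cohort studies of the brain, where disease effects are
region-resolved and cell-state-resolved. The package implements the analysis
layer such studies build on top of mapped data — and a seeded synthetic-cohort
generator with planted ground truth so every stage is testable end to end
without any sequencing data.

## What it computes

**Methylome side**

- Cell-level QC (mCCC < 0.05, mCH < 0.2, mCG > 0.5, 0.5–10 M reads, mapping
  rate > 0.5, optionally > 50,000 cis long-range contacts with anchors
  > 2,500 bp apart) and genomic-bin selection (coverage window, < 20%
  blacklist overlap, autosomes, top-k most variable bins).
- The **hypomethylation score** of bin *i* in a cell with expected
  methylation probability *p* (mean per-bin methylation fraction over the
  cell's covered bins):

  score(i) = P(X > mᵢ),  X ~ Binomial(cᵢ, p)

  evaluated as the binomial survival function and binarized at a strict 0.9
  cutoff.
- Per-feature OLS associations `value ~ Disease × Region + Age + Sex` with
  explicit reference levels (Control, VC, Female), per-term Benjamini–
  Hochberg FDR, batch correction by subtracting only the fitted
  instrument-batch component, and strict selection cutoffs
  (P < 0.05, |β| > 0.01; P < 0.05, |β| > 0.25 for compartment scores).

**Cell states**

- Instrument normalization of global CG/CH levels through the linear
  relationship measured on shared libraries; k-means (k = 3) partition into
  the low-CG/low-CH, high-CG/low-CH and high-CG/high-CH subgroups per
  neuron/non-neuron stratum; subgroup-proportion associations with disease.
- **Subtype similarity clustering**: per-gene antisymmetric log2-fold-change
  adjacency over subtypes → tensor PCA (50 components) → per-subtype
  embedding e_S → cosine similarity K and distance D = 1 − K →
  average-linkage clustering into the two expression-defined cell states
  (Homeostatic / Stressed); module-score state labels at ±2.5.

**3D genome side**

- Per-cell contact-decay profiles R_{i,c} and the **contact score**
  Σᵢ KᵢR_{i,c} with a Gaussian kernel over the distance-bin axis
  (center (N+1)/2, σ = N/6, normalized to sum to 1); PCA + k-means (k = 2)
  classification into Short- vs Long-range-enriched cells.
- Pseudo-bulk merging, ICE balancing, band-mean expected matrices and O/E,
  compartment PC1 (leading eigenvector of the O/E correlation matrix,
  sign-corrected so corr(PC1, GC) ≥ 0), saddle matrices by PC1 quantile and
  the Stressed/Homeostatic saddle ratio.
- 1-Mb **TAD-boundary density** per sample (boundary events per cell) with
  the mean cis-long-contact covariate regressed out per window; a plain
  insulation-minimum boundary caller is included as pipeline plumbing.
- **Putative deletion detection**: per 100-kb bin, balanced row sums across
  (region × cell type × state) pseudo-bulks, zeros recoded to missing, bins
  missing in ≥ 10 pseudo-bulks (but not all) flagged and annotated with the
  distance to the nearest telomere; centromere-aligned arm-scaled average
  O/E maps for state comparisons.
- Per-pixel differential loops: group cumulative Σx / Σx² matrices from
  per-sample mean matrices × cell counts, one-way ANOVA F per pixel,
  distance (5–500 bins), blacklist (±7 bins) and upper-triangle masks, and
  covariate regression on candidate pixels.

## Worked example

```python
import numpy as np
from epistate3c import synthetic_data as sd, methylome, cell_states, genome3d

cfg = sd.SimConfig(seed=7, n_ad_donors=4, n_control_donors=4, cells_per_sample=50)
meta, truth = sd.simulate_cohort(cfg)
counts = sd.simulate_methylome(meta, truth, cfg)

levels = methylome.cell_global_levels(counts)
shared = sd.simulate_shared_libraries(meta, truth, cfg)
normalized = cell_states.normalize_instruments(levels, meta, shared)
groups = cell_states.kmeans_subgroups(normalized, meta, seed=0)
acc = (groups["subgroup"] == truth.subgroup.loc[groups.index]).mean()
print(f"cells: {len(meta)}   subgroup recovery: {acc:.3f}")

contacts = sd.simulate_contacts(meta, truth, cfg)
membership = (truth.state.astype(str) + "_" + meta["cell_type"].astype(str)
              + "_" + meta["region"].astype(str))
bulks = genome3d.pseudo_bulk_by_group(
    contacts, membership, dict(cfg.chrom_lengths), cfg.bin_size_contact)
balanced = {name: {c: genome3d.balance_ice(m)[0] for c, m in per.items()}
            for name, per in bulks.items()}
calls = genome3d.detect_putative_deletions(
    balanced, dict(cfg.chrom_lengths), cfg.bin_size_contact)
called = {(r.chrom, r.bin_start // cfg.bin_size_contact) for r in calls.itertuples()}
recall = len(called & truth.deleted_bins) / len(truth.deleted_bins)
print(f"deletion calls: {len(calls)}   recall vs planted: {recall:.2f}   "
      f"median telomere distance: {calls['telomere_distance'].median()/1e3:.0f} kb")
```

Output:

```
cells: 1200   subgroup recovery: 0.993
deletion calls: 20   recall vs planted: 1.00   median telomere distance: 700 kb
```

The 1,200-cell cohort's three global-methylation subgroups are recovered at
99.3% after mapping the second sequencing instrument onto the first, and all
20 planted telomere-proximal deleted bins — zeroed only in Stressed cells —
are flagged by the balanced-row-sum rule, with no false calls.

## Command-line pipeline

```
epistate3c validate examples/demo.yaml
epistate3c run --config examples/demo.yaml
```

runs simulate → methylome → states → contacts → genome3d → loops on the
default cohort (11 AD + 9 control donors × 3 regions × 100 cells on a
3 × 20 Mb genome) and writes per-stage result tables plus a `manifest.json`
with SHA-256 hashes of every output; a rerun with the same configuration
reproduces identical hashes. Stage subcommands (`simulate`, `methylome`, …)
run prefixes of the pipeline.

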