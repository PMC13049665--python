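# Methods

This note documents the models, parameters, and design choices behind
`spatialimc`: what each stage computes, what the synthetic-tissue generator
does and does not emulate, and where the genuinely open decisions were made.

## Pipeline model

The analysis treats one *sample* as a set of tumor ROIs, each a multichannel
image (one channel per metal-tagged antibody, 1 μm²/pixel by default) with a
labeled cell-segmentation mask. `ImmunotypeModel.fit()` executes:

1. **Hot-pixel filtering.** For each pixel and channel, let `m` be the
   maximum over the eight neighbors. If the pixel exceeds `m` by more than
   the threshold (default 50 counts), it is replaced by `m`, in a single
   pass computed from the pre-filter image. The rule is idempotent and
   never increases a value. The threshold is a count scale, not a fraction:
   genuine biological signal is spatially extended, so a pixel that towers
   over its entire neighborhood is an acquisition artifact.

2. **Percentile normalization.** Per channel, a scale `(P_low, P_high)` is
   estimated from the *nonzero* pixels pooled across all ROIs of the sample
   (defaults: percentiles 0 and 99.5), and values are mapped by
   `clip((v − P_low)/(P_high − P_low), 0, 1)`; results below the background
   threshold (default 0.1) are set to zero. Percentiles are taken over
   nonzero pixels because IMC images are mostly empty background — over all
   pixels the percentiles collapse to zero. Pooling across ROIs applies one
   consistent scale to every ROI of a sample, mirroring how per-channel
   settings are tuned once on sample images and then reused. Channels with
   no nonzero values, or with `P_low == P_high`, are *degenerate*: output is
   all zeros and a warning is recorded in the result diagnostics.
   Percentiles use linear interpolation (NumPy default).

3. **Spillover compensation.** Crosstalk follows the linear mixing model
   `observed = true · SM` with `SM[i,j]` the fraction of channel *i*
   appearing in channel *j* (diagonal exactly 1, off-diagonals in [0, 0.2]).
   Compensation solves the per-event non-negative least squares problem.
   Implementation: a vectorized unconstrained solve, which *is* the NNLS
   optimum wherever it is non-negative; remaining events go through a
   vectorized active-set iteration (drop negative variables, re-solve on
   the support, grouped by support pattern) whose KKT conditions are
   verified, with the scalar Lawson–Hanson solver as the fallback for any
   event failing verification. This is exact NNLS at vectorized speed.

   Two modes exist. The default, **per-cell**, extracts raw per-cell mean
   intensities first and compensates the means — the mean is a linear
   functional of the pixels, so this equals averaging per-pixel compensated
   values whenever the non-negativity constraint is inactive, at a fraction
   of the cost. **Per-pixel** mode (`compensation_mode="per-pixel"`)
   compensates every pixel before filtering and normalization; it is the
   mode to use when exporting corrected images. In per-cell mode the
   per-cell means are normalized with the same pooled channel scales used
   at pixel level, so cluster gating thresholds refer to one scale
   throughout.

4. **Feature extraction.** One row per mask label: area (pixel count ×
   pixel area), centroid at pixel-center convention
   (`(mean index + 0.5) × pixel size`, μm), and the mean intensity over the
   label's pixels for every non-ignore marker. An empty mask yields an
   empty table.

5. **Phenotyping.** PhenoGraph construction: Euclidean kNN (k = 30 default)
   in the space of normalized clustering markers (phenotyping + tumor +
   stroma roles); edge weights are the Jaccard overlap of the endpoints'
   directed kNN sets including self; Louvain modularity maximization with a
   seeded RNG (Leiden optional). Cells are processed in a canonical
   lexicographic-by-feature order so the partition depends only on the set
   of points, not on row order; community ids are arbitrary. Clusters are
   then annotated by priority-ordered gating rules on cluster mean
   expression: a rule matches when all its required-high markers average
   ≥ 0.25 and required-low markers ≤ 0.15 (configurable); the first match
   names the cluster, unmatched clusters become `other`. Over-partitioning
   by Louvain is harmless here: several subclusters of one phenotype all
   match the same rule.

6. **Compartments.** Parenchyma is the morphologically closed region
   (disk radius 5 μm) of tumor-marker signal at or above 0.05 normalized;
   stroma the closed stroma-marker region minus parenchyma; remaining
   tissue pixels (any-channel signal) join the nearest compartment by
   distance transform; pixels without signal are background. Zero-area
   parenchyma or stroma aborts with a "compartment degenerate" error —
   the ratio stage cannot be evaluated. Cells are assigned the compartment
   under their centroid; background centroids are `unassigned` and excluded
   from compartment densities.

7. **Densities and classification.** Per ROI, density = count / tissue
   area (mm²); the tissue-masked area (parenchyma + stroma), not the
   nominal ROI area, is the denominator, and the per-phenotype mean over
   tumor ROIs is reported. The immunotype rule is two-stage: whole-tissue
   CD8 density below 200 cells/mm² → *depleted*; otherwise the
   parenchymal:stromal density ratio decides — above 0.6 *enriched*, below
   0.6 *compartmentalized*. Both thresholds are configuration. Edge cases:
   a ratio exactly at the threshold is assigned compartmentalized (the
   enriched rule requires strict excess) with a boundary warning; zero
   stromal density with positive parenchymal density is an infinite ratio,
   hence enriched, with a warning; zero density in both compartments when
   the whole-tissue density passed stage 1 is an error (cells exist but
   none could be placed in a compartment).

   The sample-level ratio is, by default, the ratio of the mean parenchymal
   to the mean stromal density across ROIs (**aggregate** mode) — robust to
   single ROIs with few stromal cells. The alternative reading, the mean of
   per-ROI ratios, is available as `ratio_mode="per-roi-mean"`. This was a
   genuinely open choice: computing ratios per ROI and then aggregating is
   equally defensible; both are implemented and the mode is recorded in the
   output.

## Synthetic tissue generator

The generator provides ground truth for every stage. Per ROI (default four
ROIs of 1 mm² at 1 μm/pixel):

* **Compartment geometry** — a coarse Gaussian random field, bilinearly
  upsampled and lightly smoothed, thresholded at the exact area quantile so
  the parenchyma fraction (default 0.4) is hit exactly. This produces both
  interleaved and banded parenchyma/stroma geometries.
* **Cell placement** — hard-core (non-overlapping disk) sequential
  placement with radii uniform in 3-7 μm. CD8 cells are placed as two
  Poisson populations, one per compartment, with densities solving
  `d_par·f + d_str·(1−f) = D` and `d_par/d_str = r` for the scenario's
  whole-tissue target `D` and ratio target `r`. Non-CD8 populations
  (default 800 cells/mm² total) are tumor cells (parenchyma), stromal cells
  (stroma), and immune bystanders (CD4 T, B, macrophage, M2, NK; anywhere).
  Requested densities beyond ~45% disk coverage of a compartment raise
  "infeasible density".
* **Expression** — per-phenotype per-marker lognormal expected counts
  (signature markers: location log 25, scale 0.3; nuclear channel on every
  cell), painted uniformly over each cell's disk.
* **Diffuse compartment signal** — CA19-9 across the parenchyma and
  collagen across the stroma (expected 10 counts/pixel) *outside* cell
  disks. This stands in for densely packed epithelium and extracellular
  matrix: real parenchyma is marker-dense at pixel level even between
  segmented nuclei, and without it no compartment map could be derived
  from images at the sparse cell densities a desk-scale simulation uses.
* **Noise, in order** — Poisson count noise on the expected image; linear
  channel mixing by the spillover matrix (default: 3% into the next
  acquisition channel, 1.5% into the previous); scattered single-count
  background events (0.02/pixel/channel); isolated hot pixels (rate 1e-5,
  set to the constant 200); quantization to 16-bit unsigned counts.
  Mixing is applied *after* count noise, so the forward corruption is
  exactly the linear model compensation inverts, and the only residual is
  ±0.5-count quantization; placing Poisson sampling after mixing instead
  would merely add channel-independent noise on top of the same linear
  structure without changing what the compensation test demonstrates.

Scenario presets pin the three study conditions: depleted (100 CD8/mm²,
ratio 0.3), compartmentalized (250, 0.25), enriched (250, 1.2). Scenario
validation rejects any preset whose targets contradict its label under the
classifier thresholds.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: segmentation error (masks are ground truth;
Mesmer-style segmentation is out of scope), spatially varying staining
intensity and batch effects, cell-shape irregularity (cells are disks),
marker co-expression continua (expression is a clean per-phenotype
signature plus noise), spillover-matrix estimation error (the matrix is
known), and acquisition physics (ablation artifacts, tiling seams).
End-to-end recovery on this generator validates the pipeline's logic and
numerics, not its robustness to real-world staining variation.

## Numerical choices

* Percentile definition: linear interpolation; recorded here for
  reproducibility, as different definitions shift `P_high` by a fraction of
  a count.
* NNLS tolerance: unconstrained solutions with components above
  `−1e−9 × event scale` are accepted as non-negative; KKT verification uses
  `1e−6 × scale` on the dual. Final outputs are clipped at zero.
* Cell-table CSVs are written with six-decimal floats; image and mask
  round trips are bit-identical.
* Louvain runs on a seeded RNG; identical (table, k, seed) reproduce the
  identical partition. The canonical vertex order additionally makes the
  partition invariant to row permutation (identical points excepted, a
  measure-zero case for continuous features).
* The 16-bit image quantization means per-cell means carry ≤ 0.5-count
  rounding; tests that compare against noiseless expectation use that as
  the tolerance.
* Degenerate inputs: empty masks give empty tables; channels without
  signal normalize to zero with a warning; compartmentless ROIs raise
  rather than silently producing densities over undefined areas.

## Problem sizes

Test and acceptance runs use the 12-marker reduced panel (nuclear,
membrane, seven immune lineage markers, CA19-9, α-SMA, collagen) — a
desk-scale stand-in for a full 40+ marker panel, configurable per study.
The end-to-end recovery study runs 3 scenarios × 50 seeds at 4 ROIs of
1 mm² each; unit tests use 2 ROIs of 0.25 mm². The acceptance script runs
10 seeds per scenario and reports the problem size next to every value.

## Known limitations

* The phenotype gating thresholds (0.25/0.15 on normalized cluster means)
  are calibrated to the synthetic expression model; real panels need
  per-marker tuning, which is why rules ship as configuration.
* The compartment map derives from two marker roles only; tissues where
  tumor and stroma markers co-localize (e.g. desmoplastic reaction inside
  tumor nests) will blur the parenchyma/stroma boundary.
* The classifier is a threshold rule on two numbers; it inherits all
  sampling noise of the upstream densities, and samples near 200 cells/mm²
  or ratio 0.6 can flip label between acquisitions. The decision trace and
  boundary warnings exist precisely to surface this.
* Whole-sample clustering assumes ROIs share a staining scale; the pooled
  percentile scale enforces this within a sample but nothing corrects
  scale differences between samples.
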