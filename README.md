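# spatialimc

Spatial immune profiling of imaging mass cytometry (IMC) data: from
multichannel pixel data and cell-segmentation masks, through single-cell
phenotyping, to a three-class **spatial immunotype** of the tumor immune
microenvironment — *immune depleted*, *immune compartmentalized*, or
*immune enriched*.

## Who this is for

IMC produces ~40-plex images of tissue sections at 1 μm resolution: one
channel per metal-tagged antibody. Translating those images into a
clinically interpretable statement about T-cell infiltration requires a
chain of standard but fiddly steps — channel-crosstalk (spillover)
compensation, hot-pixel removal, percentile normalization, per-cell feature
extraction, graph-based phenotyping, and tissue-compartment analysis. This
package implements that chain as a reusable, tested pipeline for
translational researchers quantifying CD8+ T-cell infiltration in tumor
tissue, together with a synthetic-tissue simulator so that every stage can
be validated against known ground truth without patient data.

## The method

**Preprocessing.** Observed counts mix across neighboring mass channels:
`observed = true · SM`, where `SM` is the spillover matrix
(`SM[i, j]` = fraction of channel *i* leaking into channel *j*, diagonal 1).
Compensation solves, per cell or per pixel, the non-negative least squares
problem `min_x ‖x·SM − observed‖₂, x ≥ 0`. Isolated hot pixels are removed
by the neighborhood-maximum rule (a pixel exceeding its 8-neighbor maximum
by more than a threshold is replaced by that maximum). Channel intensities
are scaled to [0, 1] between per-channel low/high percentiles of their
nonzero values (default 0 / 99.5), with values below a background threshold
(default 0.1) set to zero.

**Phenotyping.** Cells are clustered PhenoGraph-style: a k-nearest-neighbor
graph (k = 30) in normalized marker space, edges re-weighted by the Jaccard
overlap of the endpoints' neighbor sets, partitioned by Louvain modularity
maximization (Leiden available as an option). Clusters are mapped to named
phenotypes (CD8 T, CD4 T, B, NK, macrophage, M2 macrophage, tumor, stromal)
by marker high/low gating rules on cluster mean expression.

**Spatial immunotype.** Each tumor ROI is partitioned into *parenchyma*
(tumor-marker signal, e.g. CA19-9) and *stroma* (collagen/α-SMA). With
per-ROI CD8 densities `d = cells / tissue area (mm²)` averaged across tumor
ROIs, the two-stage rule is:

```
d_whole < 200 cells/mm²                  →  immune depleted
otherwise, r = d_parenchyma / d_stroma:
    r > 0.6                              →  immune enriched
    r < 0.6                              →  immune compartmentalized
```

Both thresholds are configuration (defaults 200 and 0.6). The result
carries the full decision trace, densities, and any boundary warnings.

## Worked example

```python
from spatialimc import ImmunotypeModel, scenario_preset

# synthetic sample with parenchyma-infiltrating CD8 cells:
# 4 tumor ROIs of 1 mm², target 250 CD8/mm², parenchyma:stroma ratio 1.2
scenario = scenario_preset("enriched", seed=7)
model, truth = ImmunotypeModel.from_simulation(scenario)
results = model.fit()
print(results.summary())
```

prints

```
Spatial immunotype analysis
================================================================
sample:              sim-enriched
ROIs (tumor):        4
cells:               2903
clusters:            22 (modularity 0.917, k=30)
----------------------------------------------------------------
CD8 whole-tissue density:     241.25 cells/mm2
CD8 parenchymal density:      272.23 cells/mm2
CD8 stromal density:          220.56 cells/mm2
parenchyma:stroma ratio:       1.234
----------------------------------------------------------------
thresholds: density < 200 -> depleted; ratio > 0.6 -> enriched
immunotype: ENRICHED
```

The whole-tissue CD8 density (241.25 cells/mm², mean over the four ROIs)
exceeds the 200 cells/mm² threshold, and the parenchymal:stromal density
ratio (1.234) exceeds 0.6, so the sample is called immune **enriched** —
matching the simulator's intended immunotype. The generator's realized
density for this seed is `truth.realized_cd8_density()` = 241.25 cells/mm²,
i.e. the pipeline recovered every CD8 cell.

The same analysis runs from the shell:

```bash
spatialimc simulate enriched --out sim/ --seed 7
spatialimc run --config config.json          # paths + parameters + seed
spatialimc classify 252.08 280 230           # rule applied to given densities
```

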