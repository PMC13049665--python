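"""The modelling facade: build an ImmunotypeModel from data, fit, inspect results.

`ImmunotypeModel` bundles one sample's ROIs (multichannel image stacks plus
segmentation masks) with the analysis parameters; ``fit()`` executes the
stages in order — spillover compensation, hot-pixel filtering, percentile
normalization, feature extraction, PhenoGraph clustering, phenotype
annotation, compartment derivation, density computation, immunotype
classification — and returns an `ImmunotypeResults` carrying the estimates
(densities, ratio, label), the intermediate tables, diagnostics, and a
``summary()`` report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __about__
from .cells import (
    ClusterModel,
    PhenotypeRule,
    annotate_clusters,
    cluster_mean_matrix,
    cluster_phenograph,
    extract_features,
)
from .io import (
    CSV_FLOAT_FORMAT,
    ImageStack,
    LabelMask,
    read_image_stack,
    read_label_mask,
    read_panel,
    read_spillover_csv,
    write_cell_table,
)
from .panel import Panel
from .preprocess import (
    ChannelNormalization,
    NormalizationSpec,
    SpilloverMatrix,
    apply_percentile_scale,
    compensate_image,
    compensate_spillover,
    filter_hot_pixels,
    normalize_stack,
    percentile_scale,
)
from .spatial import (
    ClassifierThresholds,
    CompartmentMap,
    DensityReport,
    ImmunotypeResult,
    assign_compartment,
    classify_immunotype,
    compute_density,
    derive_compartments,
)


@dataclass
class PipelineConfig:
    """Source of truth for one pipeline run; loadable from YAML/JSON."""

    images: list[str] = field(default_factory=list)
    masks: list[str] = field(default_factory=list)
    panel: str | None = None
    spillover: str | None = None
    rules: str | None = None
    out_dir: str | None = None
    seed: int | None = None
    sample_id: str = "sample"
    k_neighbors: int = 30
    clustering_method: str = "louvain"
    compensation_mode: str = "per-cell"
    hot_pixel_threshold: float = 50.0
    density_threshold: float = 200.0
    ratio_threshold: float = 0.6
    ratio_mode: str = "aggregate"
    normalization: dict = field(default_factory=dict)
    save_images: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config validation error: seed is mandatory")
        if self.ratio_mode not in ("aggregate", "per-roi-mean"):
            raise ValueError("ratio_mode must be 'aggregate' or 'per-roi-mean'")
        if self.compensation_mode not in ("per-cell", "per-pixel"):
            raise ValueError("compensation_mode must be 'per-cell' or 'per-pixel'")
        if len(self.images) != len(self.masks):
            raise ValueError(
                f"{len(self.images)} images but {len(self.masks)} masks in config"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        cfg = cls.from_dict(d)
        for p in [*cfg.images, *cfg.masks, cfg.panel, cfg.spillover, cfg.rules]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config references missing path: {p}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Config without the output location (analysis-relevant keys only)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.analysis_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def normalization_spec(self) -> NormalizationSpec:
        per_channel = {
            marker: ChannelNormalization(
                low_percentile=v.get("low_percentile", 0.0),
                high_percentile=v.get("high_percentile", 99.5),
                background_threshold=v.get("background_threshold", 0.1),
            )
            for marker, v in self.normalization.items()
        }
        return NormalizationSpec(per_channel=per_channel)

    def thresholds(self) -> ClassifierThresholds:
        return ClassifierThresholds(density=self.density_threshold, ratio=self.ratio_threshold)


def load_rules(path: str | Path) -> tuple[PhenotypeRule, ...]:
    """Read phenotype gating rules from a YAML or JSON list."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        entries = yaml.safe_load(text)
    else:
        entries = json.loads(text)
    rules = []
    for e in entries:
        rules.append(
            PhenotypeRule(
                phenotype_name=e["phenotype"],
                required_high=tuple(e.get("high", ())),
                required_low=tuple(e.get("low", ())),
                threshold_high=float(e.get("threshold_high", 0.25)),
                threshold_low=float(e.get("threshold_low", 0.15)),
            )
        )
    return tuple(rules)


class ImmunotypeModel:
    """Spatial immunotype analysis of one sample's IMC ROIs.

    Parameters
    ----------
    stacks, masks
        One multichannel image stack and one segmentation mask per ROI.
    panel
        The channel→marker panel (taken from the first stack if omitted).
    spillover
        Optional spillover matrix; when given, NNLS compensation is applied
        (per-cell by default, per-pixel via ``config.compensation_mode``).
    rules
        Phenotype gating rules (defaults to the canonical immune rule set).
    config
        Remaining parameters (k, thresholds, normalization, seed).
    """

    def __init__(
        self,
        stacks: list[ImageStack],
        masks: list[LabelMask],
        *,
        panel: Panel | None = None,
        spillover: SpilloverMatrix | None = None,
        rules: tuple[PhenotypeRule, ...] | None = None,
        config: PipelineConfig | None = None,
    ):
        if len(stacks) != len(masks):
            raise ValueError(f"{len(stacks)} stacks but {len(masks)} masks")
        if not stacks:
            raise ValueError("need at least one ROI")
        for s, m in zip(stacks, masks):
            if s.shape_yx != m.labels.shape:
                raise ValueError(f"ROI {s.roi_id}: image and mask shapes differ")
        self.stacks = stacks
        self.masks = masks
        self.panel = panel if panel is not None else stacks[0].panel
        self.spillover = spillover
        self.rules = rules
        self.config = config if config is not None else PipelineConfig(seed=0)

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "ImmunotypeModel":
        if config.panel is None:
            raise ValueError("config must name a panel CSV")
        panel = read_panel(config.panel)
        stacks = [read_image_stack(p, panel) for p in config.images]
        masks = [read_label_mask(p) for p in config.masks]
        for s, m in zip(stacks, masks):
            m.roi_id = s.roi_id if m.roi_id != s.roi_id else m.roi_id
        spill = read_spillover_csv(config.spillover) if config.spillover else None
        rules = load_rules(config.rules) if config.rules else None
        return cls(stacks, masks, panel=panel, spillover=spill, rules=rules, config=config)

    @classmethod
    def from_simulation(cls, scenario, *, config: PipelineConfig | None = None):
        """Simulate a synthetic sample and build the model on it (compensating
        with the simulator's true spillover matrix).  Returns (model, truth)."""
        from .simulate import simulate_tissue

        stacks, masks, gt = simulate_tissue(scenario)
        if config is None:
            config = PipelineConfig(seed=scenario.seed, sample_id=f"sim-{scenario.immunotype_label}")
        model = cls(
            stacks,
            masks,
            panel=scenario.panel,
            spillover=gt.spillover_matrix,
            config=config,
        )
        return model, gt

    # ------------------------------------------------------------------
    def _compartment_panel(self) -> Panel:
        entries = [e for e in self.panel if e.role in ("tumor", "stroma")]
        return Panel.from_records(
            [(i, e.metal_tag, e.marker_name, e.role) for i, e in enumerate(entries)]
        )

    def _compartment_stack(self, stack: ImageStack, scales: dict, norm_spec) -> ImageStack:
        """Normalized stack holding only the tumor/stroma channels."""
        cpanel = self._compartment_panel()
        pixels = np.stack(
            [
                apply_percentile_scale(
                    stack.pixels[self.panel.index_of(m)],
                    scales[m],
                    norm_spec.for_marker(m),
                )
                for m in cpanel.markers
            ]
        )
        return ImageStack(
            pixels=pixels,
            panel=cpanel,
            roi_id=stack.roi_id,
            pixel_size_um=stack.pixel_size_um,
            tissue_region=stack.tissue_region,
        )

    def _raw_tissue_mask(self, stack: ImageStack, scales: dict, norm_spec) -> np.ndarray:
        """Pixels with above-background signal in any channel, on the raw scale.

        A raw value maps to a nonzero normalized value exactly when it is at
        least ``P_low + background_threshold * (P_high - P_low)``; testing
        the raw values against that threshold avoids normalizing channels
        that are otherwise unused at pixel level.
        """
        tissue = np.zeros(stack.shape_yx, dtype=bool)
        for e in self.panel:
            if e.role == "ignore":
                continue
            sc = scales[e.marker_name]
            if sc is None:
                continue
            spec_ch = norm_spec.for_marker(e.marker_name)
            thr = sc[0] + spec_ch.background_threshold * (sc[1] - sc[0])
            tissue |= stack.pixels[e.channel_index] >= thr
        return tissue

    def fit(self) -> "ImmunotypeResults":
        """Run all stages and return the results object.

        Default (``compensation_mode="per-cell"``): hot-pixel filtering of
        the raw images; a pooled per-channel percentile scale from the
        nonzero pixels of all ROIs; raw per-cell mean extraction; NNLS
        spillover compensation of the per-cell means; percentile
        normalization of the means on the pooled scale.  The per-pixel mode
        instead compensates every pixel first, then filters, normalizes and
        extracts features directly from the normalized images.
        """
        cfg = self.config
        norm_spec = cfg.normalization_spec()
        diagnostics: list[str] = []
        per_pixel = cfg.compensation_mode == "per-pixel" and self.spillover is not None

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            filtered: list[ImageStack] = []
            for stack in self.stacks:
                s = stack
                if per_pixel:
                    s = compensate_image(s, self.spillover)
                filtered.append(filter_hot_pixels(s, cfg.hot_pixel_threshold))

            # one scale per channel, pooled over all ROIs of the sample
            scales = {
                e.marker_name: percentile_scale(
                    [s.pixels[e.channel_index] for s in filtered],
                    norm_spec.for_marker(e.marker_name),
                    marker=e.marker_name,
                )
                for e in self.panel
            }
            if per_pixel:
                normalized = [normalize_stack(s, norm_spec, scales=scales) for s in filtered]
            else:
                # compartment derivation only needs the tumor/stroma channels
                # normalized; the tissue mask comes from raw thresholds
                normalized = [
                    self._compartment_stack(s, scales, norm_spec) for s in filtered
                ]

            if per_pixel:
                tables = [
                    extract_features(s, m, self.panel) for s, m in zip(normalized, self.masks)
                ]
                cells = pd.concat(tables, ignore_index=True)
            else:
                tables = [
                    extract_features(s, m, self.panel) for s, m in zip(filtered, self.masks)
                ]
                cells = pd.concat(tables, ignore_index=True)
                if self.spillover is not None and len(cells):
                    order = {t: i for i, t in enumerate(self.spillover.tags)}
                    markers_by_tag = sorted(
                        (e for e in self.panel if e.metal_tag in order),
                        key=lambda e: order[e.metal_tag],
                    )
                    cols = [f"mean_{e.marker_name}" for e in markers_by_tag]
                    if len(markers_by_tag) == self.spillover.n and all(
                        c in cells.columns for c in cols
                    ):
                        cells[cols] = compensate_spillover(
                            cells[cols].to_numpy(dtype=float), self.spillover
                        )
                    else:
                        warnings.warn(
                            "per-cell spillover compensation skipped: spillover "
                            "matrix channels do not match extracted marker columns"
                        )
                # normalize per-cell means with the same pooled channel scales
                for e in self.panel:
                    col = f"mean_{e.marker_name}"
                    if col in cells.columns:
                        cells[col] = apply_percentile_scale(
                            cells[col].to_numpy(dtype=float),
                            scales[e.marker_name],
                            norm_spec.for_marker(e.marker_name),
                        )
        diagnostics.extend(str(w.message) for w in caught)

        feature_markers = self.panel.feature_markers
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cluster_model = cluster_phenograph(
                cells,
                feature_markers,
                k=cfg.k_neighbors,
                seed=int(cfg.seed),
                method=cfg.clustering_method,
            )
            cells = annotate_clusters(cluster_model, cells, self.rules)
        diagnostics.extend(str(w.message) for w in caught)

        cmaps: dict[str, CompartmentMap] = {}
        if per_pixel:
            for s in normalized:
                cmaps[s.roi_id] = derive_compartments(s, self.panel)
        else:
            for s, comp_stack in zip(filtered, normalized):
                tissue = self._raw_tissue_mask(s, scales, norm_spec)
                cmaps[s.roi_id] = derive_compartments(
                    comp_stack, comp_stack.panel, tissue=tissue
                )
        for cmap in cmaps.values():
            cells = assign_compartment(cells, cmap)

        tumor_rois = [s.roi_id for s in self.stacks if s.tissue_region == "tumor"]
        tissue_areas = {rid: cmaps[rid].tissue_area_mm2 for rid in tumor_rois}
        par_areas = {rid: cmaps[rid].parenchyma_area_mm2 for rid in tumor_rois}
        str_areas = {rid: cmaps[rid].stroma_area_mm2 for rid in tumor_rois}

        tumor_cells = cells[cells["roi_id"].isin(tumor_rois)]
        density_report = compute_density(tumor_cells, tissue_areas)

        cd8 = tumor_cells[tumor_cells["phenotype"] == "CD8_T"]
        whole = float(
            np.mean([
                (cd8["roi_id"] == rid).sum() / tissue_areas[rid] for rid in tumor_rois
            ])
        )
        par_d = [
            ((cd8["roi_id"] == rid) & (cd8["compartment"] == "parenchyma")).sum()
            / par_areas[rid]
            for rid in tumor_rois
        ]
        str_d = [
            ((cd8["roi_id"] == rid) & (cd8["compartment"] == "stroma")).sum()
            / str_areas[rid]
            for rid in tumor_rois
        ]
        mean_par, mean_str = float(np.mean(par_d)), float(np.mean(str_d))

        precomputed_ratio = None
        if cfg.ratio_mode == "per-roi-mean":
            per_roi_ratios = [
                p / s if s > 0 else (np.inf if p > 0 else np.nan)
                for p, s in zip(par_d, str_d)
            ]
            precomputed_ratio = float(np.mean(per_roi_ratios))

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            call = classify_immunotype(
                whole,
                mean_par,
                mean_str,
                cfg.thresholds(),
                sample_id=cfg.sample_id,
                precomputed_ratio=precomputed_ratio,
            )
        diagnostics.extend(str(w.message) for w in caught)

        return ImmunotypeResults(
            model=self,
            immunotype=call,
            density_report=density_report,
            cell_table=cells,
            cluster_model=cluster_model,
            compartment_maps=cmaps,
            normalized_stacks=normalized,
            diagnostics=diagnostics,
        )


@dataclass
class ImmunotypeResults:
    """Fit output: the immunotype call plus all intermediate estimates."""

    model: ImmunotypeModel
    immunotype: ImmunotypeResult
    density_report: DensityReport
    cell_table: pd.DataFrame
    cluster_model: ClusterModel
    compartment_maps: dict[str, CompartmentMap]
    normalized_stacks: list[ImageStack]
    diagnostics: list[str]

    # convenience accessors -------------------------------------------------
    @property
    def label(self) -> str:
        return self.immunotype.label

    @property
    def whole_density(self) -> float:
        return self.immunotype.whole_density

    @property
    def ratio(self) -> float:
        return self.immunotype.ratio

    @property
    def n_cells(self) -> int:
        return len(self.cell_table)

    def to_json_dict(self) -> dict:
        d = self.immunotype.to_dict()
        d["n_cells"] = int(self.n_cells)
        d["n_clusters"] = int(self.cluster_model.n_communities)
        d["modularity"] = round(float(self.cluster_model.modularity), 6)
        d["phenotype_mean_densities_cells_per_mm2"] = {
            k: round(v, 6) for k, v in sorted(self.density_report.mean_density.items())
        }
        d["tissue_areas_mm2"] = {
            rid: round(cm.tissue_area_mm2, 6) for rid, cm in sorted(self.compartment_maps.items())
        }
        d["diagnostics"] = list(self.diagnostics)
        return d

    def summary(self) -> str:
        imt = self.immunotype
        lines = [
            "Spatial immunotype analysis",
            "=" * 64,
            f"sample:              {imt.sample_id}",
            f"ROIs (tumor):        {len(self.model.stacks)}",
            f"cells:               {self.n_cells}",
            f"clusters:            {self.cluster_model.n_communities} "
            f"(modularity {self.cluster_model.modularity:.3f}, k={self.cluster_model.k_neighbors})",
            "-" * 64,
            f"CD8 whole-tissue density:   {imt.whole_density:8.2f} cells/mm2",
            f"CD8 parenchymal density:    {imt.parenchymal_density:8.2f} cells/mm2",
            f"CD8 stromal density:        {imt.stromal_density:8.2f} cells/mm2",
            f"parenchyma:stroma ratio:    {imt.ratio:8.3f}",
            "-" * 64,
            f"thresholds: density < {imt.thresholds.density:g} -> depleted; "
            f"ratio > {imt.thresholds.ratio:g} -> enriched",
            f"immunotype: {imt.label.upper()}",
        ]
        if self.diagnostics:
            lines.append("-" * 64)
            lines.append("diagnostics:")
            lines.extend(f"  - {d}" for d in self.diagnostics)
        return "\n".join(lines)

    # persistence -----------------------------------------------------------
    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write result JSON, cell table, density report, compartment maps and
        run manifest to ``outdir`` (byte-stable across reruns of one config)."""
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        result_path = outdir / "immunotype_result.json"
        result_path.write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")
        paths["result"] = result_path

        cells_path = outdir / "cells.csv"
        write_cell_table(self.cell_table, cells_path)
        paths["cells"] = cells_path

        dens_path = outdir / "density_report.csv"
        self.density_report.per_roi.to_csv(dens_path, index=False, float_format=CSV_FLOAT_FORMAT)
        paths["densities"] = dens_path

        heat_path = outdir / "cluster_means.csv"
        cluster_mean_matrix(self.cell_table, self.model.panel.feature_markers).to_csv(
            heat_path, float_format=CSV_FLOAT_FORMAT
        )
        paths["cluster_means"] = heat_path

        for rid, cmap in self.compartment_maps.items():
            p = outdir / f"compartments_{rid}.tiff"
            tifffile.imwrite(p, cmap.labels.astype(np.uint8))
            paths[f"compartments_{rid}"] = p

        manifest = {
            "config": self.model.config.analysis_dict(),
            "config_hash": self.model.config.content_hash(),
            "seed": self.model.config.seed,
            "package": {"name": "spatialimc", "version": __about__.__version__},
        }
        man_path = outdir / "run_manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = man_path

        if self.model.config.save_images:
            from .io import write_image_stack

            for s in self.normalized_stacks:
                p = outdir / f"normalized_{s.roi_id}.tiff"
                write_image_stack(
                    ImageStack(
                        pixels=s.pixels.astype(np.float32),
                        panel=s.panel,
                        roi_id=s.roi_id,
                        pixel_size_um=s.pixel_size_um,
                        tissue_region=s.tissue_region,
                    ),
                    p,
                )
                paths[f"normalized_{s.roi_id}"] = p
        return paths

    # plotting --------------------------------------------------------------
    def plot_densities(self, ax=None):
        """Bar plot of mean phenotype densities (cells/mm²) across tumor ROIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        dens = self.density_report.mean_density
        names = sorted(dens, key=dens.get, reverse=True)
        ax.bar(names, [dens[n] for n in names], color="steelblue")
        ax.set_ylabel("density (cells/mm$^2$)")
        ax.set_title(f"{self.immunotype.sample_id}: {self.label}")
        ax.tick_params(axis="x", rotation=45)
        return ax

    def plot_compartments(self, roi_id: str, ax=None):
        """Show one ROI's parenchyma/stroma map with CD8 centroids overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        cmap = self.compartment_maps[roi_id]
        ax.imshow(cmap.labels, cmap="viridis", interpolation="nearest")
        cd8 = self.cell_table[
            (self.cell_table["roi_id"] == roi_id)
            & (self.cell_table["phenotype"] == "CD8_T")
        ]
        px = cmap.pixel_size_um
        ax.scatter(
            cd8["centroid_x_um"] / px, cd8["centroid_y_um"] / px, s=4, c="red", label="CD8+ T"
        )
        ax.set_title(f"{roi_id} compartments")
        ax.legend(loc="lower right")
        return ax


# ---------------------------------------------------------------------------
# orchestration entry points


def run_pipeline(config: PipelineConfig) -> ImmunotypeResults:
    """Execute the full pipeline from a config; write artifacts if out_dir set."""
    model = ImmunotypeModel.from_config(config)
    results = model.fit()
    if config.out_dir:
        results.save(config.out_dir)
    return results


def simulate_and_run(scenario, **config_overrides):
    """Simulate a synthetic sample, run the full pipeline on it.

    Returns ``(ground_truth, results)`` so test harnesses can compare the
    recovered immunotype and densities against the generator's truth.
    """
    overrides = dict(config_overrides)
    overrides.setdefault("seed", scenario.seed)
    overrides.setdefault("sample_id", f"sim-{scenario.immunotype_label}")
    config = PipelineConfig(**overrides)
    model, gt = ImmunotypeModel.from_simulation(scenario, config=config)
    results = model.fit()
    if config.out_dir:
        results.save(config.out_dir)
    return gt, results
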