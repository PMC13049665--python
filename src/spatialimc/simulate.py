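"""Synthetic IMC tissue: multichannel images with known single-cell truth.

The generator emulates the features of an IMC acquisition that the pipeline
must cope with — sparse antibody signal, channel crosstalk, Poisson count
noise, salt-like background, hot pixels — on top of a ground-truth tissue
layout: a parenchyma/stroma compartment geometry from a smoothed Gaussian
random field, hard-core (non-overlapping disk) cell placement, and
per-phenotype lognormal marker expression.  Three CD8+ T-cell arrangements
mirror the spatial immunotypes: depleted (low density), compartmentalized
(stroma-restricted) and enriched (parenchyma-infiltrating).

Forward model per ROI, in order:

1. expected count image per channel: per-cell lognormal expression painted
   on the cell's disk, plus diffuse compartment signal (CA19-9 across the
   parenchyma, collagen across the stroma — a stand-in for densely packed
   epithelium and extracellular matrix);
2. Poisson count noise per pixel;
3. linear channel mixing by the spillover matrix;
4. scattered single-count background events and isolated hot pixels;
5. quantization to 16-bit unsigned counts.

Mixing is applied after count noise so that the forward corruption is
exactly the linear model the compensation stage inverts; quantization
noise (±0.5 counts) remains.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .io import ImageStack, LabelMask, write_cell_table, write_image_stack, write_label_mask, write_panel
from .panel import Panel, default_panel
from .preprocess import SpilloverMatrix, make_spillover_matrix
from .spatial import (
    PARENCHYMA,
    STROMA,
    ClassifierThresholds,
    CompartmentMap,
)

#: cell radii are drawn uniformly from this range (μm)
CELL_RADIUS_RANGE_UM = (3.0, 7.0)

#: fraction of a compartment's area that requested disks may cover before
#: placement is declared infeasible (random close packing of disks ~0.55)
MAX_PACKING_FRACTION = 0.45

IMMUNOTYPES = ("depleted", "compartmentalized", "enriched")


def default_expression_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Lognormal (location, scale) of expected counts, per phenotype per marker.

    Markers not listed for a phenotype are not expressed by it.  Every cell
    expresses the nuclear channel.
    """
    hi = (math.log(25.0), 0.3)
    dna = (math.log(20.0), 0.25)
    return {
        "CD8_T": {"DNA1": dna, "CD3": hi, "CD8a": hi},
        "CD4_T": {"DNA1": dna, "CD3": hi, "CD4": hi},
        "B": {"DNA1": dna, "CD20": hi},
        "NK": {"DNA1": dna, "CD7": hi},
        "macrophage": {"DNA1": dna, "CD68": hi},
        "M2_macrophage": {"DNA1": dna, "CD68": hi, "CD204": hi},
        "tumor": {"DNA1": dna, "CA19-9": (math.log(30.0), 0.3), "E-cadherin": hi},
        "stromal": {"DNA1": dna, "aSMA": hi},
    }


#: non-CD8 population mix: phenotype -> (fraction of background_cell_density,
#: compartment restriction: "parenchyma" | "stroma" | "any")
DEFAULT_POPULATION_MIX: dict[str, tuple[float, str]] = {
    "tumor": (0.45, "parenchyma"),
    "stromal": (0.35, "stroma"),
    "CD4_T": (0.06, "any"),
    "macrophage": (0.06, "any"),
    "B": (0.03, "any"),
    "M2_macrophage": (0.03, "any"),
    "NK": (0.02, "any"),
}


def default_spillover_fractions(panel: Panel) -> dict[tuple[str, str], float]:
    """Crosstalk into the neighboring acquisition channels (by metal tag)."""
    tags = panel.metals
    fr: dict[tuple[str, str], float] = {}
    for i in range(len(tags) - 1):
        fr[(tags[i], tags[i + 1])] = 0.03
        fr[(tags[i + 1], tags[i])] = 0.015
    return fr


@dataclass(frozen=True)
class NoiseParams:
    """Acquisition-noise settings of the forward model."""

    poisson_scale: float = 1.0  # 0 disables count noise (noiseless expectation)
    hot_pixel_rate: float = 1e-5  # per pixel per channel
    hot_pixel_value: float = 200.0  # counts; "isolated single pixel at a high constant"
    background_rate: float = 0.02  # salt events per pixel per channel
    spillover_fractions: dict | None = None  # None -> neighbor-channel default

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.hot_pixel_rate < 0 or self.background_rate < 0:
            raise ValueError("noise rates must be non-negative")


@dataclass(frozen=True)
class DiffuseSignal:
    marker: str
    compartment: str  # "parenchyma" | "stroma"
    expected_counts: float


def default_diffuse_signals() -> tuple[DiffuseSignal, ...]:
    return (
        DiffuseSignal("CA19-9", "parenchyma", 10.0),
        DiffuseSignal("collagen", "stroma", 10.0),
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """One synthetic study condition: an immunotype with its density targets."""

    immunotype_label: str
    cd8_density_target: float  # cells/mm² over whole tissue
    parenchyma_to_stroma_ratio_target: float
    seed: int | None = None
    roi_size_um: float = 1000.0
    n_rois: int = 4
    parenchyma_fraction: float = 0.4
    background_cell_density: float = 800.0  # cells/mm², non-CD8 populations
    panel: Panel = field(default_factory=default_panel)
    expression_params: dict = field(default_factory=default_expression_params)
    population_mix: dict = field(default_factory=lambda: dict(DEFAULT_POPULATION_MIX))
    diffuse_signals: tuple = field(default_factory=default_diffuse_signals)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory: synthetic data must be reproducible")
        if self.immunotype_label not in IMMUNOTYPES:
            raise ValueError(f"immunotype_label must be one of {IMMUNOTYPES}")
        if self.roi_size_um <= 0 or self.n_rois < 1:
            raise ValueError("roi_size_um must be positive and n_rois >= 1")
        if not (0 < self.parenchyma_fraction < 1):
            raise ValueError("parenchyma_fraction must lie strictly between 0 and 1")
        if self.cd8_density_target < 0 or self.background_cell_density < 0:
            raise ValueError("densities must be non-negative")
        if self.parenchyma_to_stroma_ratio_target < 0:
            raise ValueError("ratio target must be non-negative")
        for name in ("CD3", "CD8a", "DNA1"):
            if name not in self.panel.markers:
                raise ValueError(f"panel must contain marker {name!r}")
        if not self.panel.markers_with_role("tumor") or not self.panel.markers_with_role("stroma"):
            raise ValueError("panel must contain a tumor-role and a stroma-role marker")
        implied = _implied_label(
            self.cd8_density_target, self.parenchyma_to_stroma_ratio_target
        )
        if implied != self.immunotype_label:
            raise ValueError(
                f"scenario targets imply immunotype {implied!r} under the classifier "
                f"thresholds, but immunotype_label is {self.immunotype_label!r}"
            )

    @property
    def roi_size_px(self) -> int:
        return int(round(self.roi_size_um / self.pixel_size_um))

    @property
    def roi_area_mm2(self) -> float:
        return (self.roi_size_um / 1000.0) ** 2

    def compartment_cd8_densities(self) -> tuple[float, float]:
        """CD8 densities (parenchyma, stroma) in cells/mm² realizing the targets.

        Solves ``d_par * f + d_str * (1 - f) = D`` with ``d_par = r * d_str``
        for whole-tissue target ``D``, ratio target ``r`` and parenchyma
        fraction ``f``.
        """
        f = self.parenchyma_fraction
        r = self.parenchyma_to_stroma_ratio_target
        d_str = self.cd8_density_target / (r * f + (1.0 - f))
        return r * d_str, d_str

    def to_json_dict(self) -> dict:
        d = {
            "immunotype_label": self.immunotype_label,
            "cd8_density_target": self.cd8_density_target,
            "parenchyma_to_stroma_ratio_target": self.parenchyma_to_stroma_ratio_target,
            "seed": self.seed,
            "roi_size_um": self.roi_size_um,
            "n_rois": self.n_rois,
            "parenchyma_fraction": self.parenchyma_fraction,
            "background_cell_density": self.background_cell_density,
            "pixel_size_um": self.pixel_size_um,
            "noise_params": dataclasses.asdict(self.noise_params),
        }
        return d


def _implied_label(
    density: float, ratio: float, thresholds: ClassifierThresholds | None = None
) -> str:
    t = thresholds or ClassifierThresholds()
    if density < t.density:
        return "depleted"
    return "enriched" if ratio > t.ratio else "compartmentalized"


_PRESETS = {
    # (cd8_density_target, parenchyma:stroma ratio target)
    "depleted": (100.0, 0.3),
    "compartmentalized": (250.0, 0.25),
    "enriched": (250.0, 1.2),
}


def scenario_preset(label: str, seed: int, **overrides) -> SyntheticScenario:
    """A ready-made scenario for one of the three immunotypes."""
    if label not in _PRESETS:
        raise ValueError(f"unknown preset {label!r}; choose from {sorted(_PRESETS)}")
    density, ratio = _PRESETS[label]
    kwargs = {
        "immunotype_label": label,
        "cd8_density_target": density,
        "parenchyma_to_stroma_ratio_target": ratio,
        "seed": seed,
    }
    kwargs.update(overrides)
    return SyntheticScenario(**kwargs)


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for downstream tests."""

    cell_table: pd.DataFrame  # with true phenotype and compartment columns
    expression: pd.DataFrame  # per-cell expected counts per marker
    compartment_maps: dict[str, CompartmentMap]
    spillover_matrix: SpilloverMatrix
    intended_label: str
    scenario: SyntheticScenario

    @property
    def tissue_areas_mm2(self) -> dict[str, float]:
        return {rid: cm.tissue_area_mm2 for rid, cm in self.compartment_maps.items()}

    def realized_cd8_density(self) -> float:
        """Whole-tissue CD8 density (cells/mm²), mean over ROIs."""
        per_roi = []
        for rid, cm in self.compartment_maps.items():
            n = int(
                (
                    (self.cell_table["roi_id"] == rid)
                    & (self.cell_table["phenotype"] == "CD8_T")
                ).sum()
            )
            per_roi.append(n / cm.tissue_area_mm2)
        return float(np.mean(per_roi))


# ---------------------------------------------------------------------------
# geometry and placement


def _compartment_field(rng: np.random.Generator, size_px: int, parenchyma_fraction: float):
    """Smoothed Gaussian random field, thresholded at the exact area quantile."""
    coarse = max(8, size_px // 40)
    noise = rng.standard_normal((coarse, coarse))
    fld = ndi.zoom(noise, size_px / coarse, order=1, grid_mode=True, mode="nearest")
    if fld.shape != (size_px, size_px):  # zoom rounding on odd sizes
        fld = np.pad(
            fld,
            ((0, size_px - fld.shape[0]), (0, size_px - fld.shape[1])),
            mode="edge",
        )[:size_px, :size_px]
    fld = ndi.gaussian_filter(fld, sigma=max(2.0, size_px / 200.0))
    thr = np.quantile(fld, 1.0 - parenchyma_fraction)
    labels = np.where(fld >= thr, PARENCHYMA, STROMA).astype(np.int8)
    return labels


class _HardCoreSampler:
    """Sequential hard-core disk placement with a uniform grid hash."""

    def __init__(self, size_px: int, max_radius_px: float, rng: np.random.Generator):
        self.size = size_px
        self.cell = 2.0 * max_radius_px
        self.nbins = max(1, int(size_px / self.cell))
        self.grid: dict[tuple[int, int], list[int]] = {}
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.rs: list[float] = []
        self.rng = rng

    def _bin(self, x: float, y: float) -> tuple[int, int]:
        s = self.size / self.nbins
        return min(int(x / s), self.nbins - 1), min(int(y / s), self.nbins - 1)

    def try_place(self, region_idx: np.ndarray, radius: float, max_attempts: int = 200):
        w = self.size
        for _ in range(max_attempts):
            flat = int(region_idx[self.rng.integers(len(region_idx))])
            y = flat // w + self.rng.random()
            x = flat % w + self.rng.random()
            bx, by = self._bin(x, y)
            ok = True
            for nx in range(max(0, bx - 1), min(self.nbins, bx + 2)):
                for ny in range(max(0, by - 1), min(self.nbins, by + 2)):
                    for j in self.grid.get((nx, ny), ()):
                        dx = x - self.xs[j]
                        dy = y - self.ys[j]
                        rr = radius + self.rs[j] + 1e-6  # margin: rasterized disks stay disjoint
                        if dx * dx + dy * dy < rr * rr:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                j = len(self.xs)
                self.xs.append(x)
                self.ys.append(y)
                self.rs.append(radius)
                self.grid.setdefault((bx, by), []).append(j)
                return x, y
        raise ValueError(
            "infeasible density: could not place a cell without overlap "
            f"after {max_attempts} attempts"
        )


def _check_packing(scenario: SyntheticScenario) -> None:
    r_lo, r_hi = CELL_RADIUS_RANGE_UM
    mean_disk_um2 = math.pi * (r_hi**2 + r_hi * r_lo + r_lo**2) / 3.0  # E[pi r^2]
    d_par, d_str = scenario.compartment_cd8_densities()
    per_comp = {"parenchyma": d_par, "stroma": d_str}
    for ph, (frac, comp) in scenario.population_mix.items():
        dens = frac * scenario.background_cell_density
        if comp == "any":
            for c in per_comp:
                per_comp[c] += dens
        else:
            per_comp[comp] += dens
    for comp, dens in per_comp.items():
        covered = dens * mean_disk_um2 * 1e-6  # fraction of compartment area
        if covered > MAX_PACKING_FRACTION:
            raise ValueError(
                f"infeasible density: requested populations would cover "
                f"{covered:.2f} of the {comp} (limit {MAX_PACKING_FRACTION})"
            )


# ---------------------------------------------------------------------------
# simulation


def _roi_ground_truth(scenario: SyntheticScenario, rng: np.random.Generator, roi_id: str):
    """Place cells and draw expression for one ROI (no images yet)."""
    size = scenario.roi_size_px
    comp_labels = _compartment_field(rng, size, scenario.parenchyma_fraction)
    cmap = CompartmentMap(comp_labels, roi_id=roi_id, pixel_size_um=scenario.pixel_size_um)

    regions = {
        "parenchyma": np.flatnonzero((comp_labels == PARENCHYMA).ravel()),
        "stroma": np.flatnonzero((comp_labels == STROMA).ravel()),
        "any": np.arange(comp_labels.size),
    }
    area = {
        "parenchyma": cmap.parenchyma_area_mm2,
        "stroma": cmap.stroma_area_mm2,
        "any": cmap.tissue_area_mm2,
    }

    d_par, d_str = scenario.compartment_cd8_densities()
    populations: list[tuple[str, str, float]] = [
        ("CD8_T", "parenchyma", d_par),
        ("CD8_T", "stroma", d_str),
    ]
    for ph, (frac, comp) in scenario.population_mix.items():
        populations.append((ph, comp, frac * scenario.background_cell_density))

    r_lo, r_hi = (r / scenario.pixel_size_um for r in CELL_RADIUS_RANGE_UM)
    sampler = _HardCoreSampler(size, r_hi, rng)
    records = []
    for ph, comp, dens in populations:
        n = int(rng.poisson(dens * area[comp]))
        for _ in range(n):
            radius = rng.uniform(r_lo, r_hi)
            x, y = sampler.try_place(regions[comp], radius)
            records.append((ph, comp, x, y, radius))

    # stable ordering: left-to-right, top-to-bottom, so mask labels are
    # independent of population processing order
    records.sort(key=lambda t: (t[3], t[2]))
    n_cells = len(records)

    markers = scenario.panel.markers
    expr = np.zeros((n_cells, len(markers)), dtype=float)
    midx = {m: i for i, m in enumerate(markers)}
    for i, (ph, *_rest) in enumerate(records):
        for marker, (mu, sigma) in scenario.expression_params.get(ph, {}).items():
            if marker in midx:
                expr[i, midx[marker]] = rng.lognormal(mu, sigma)

    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "roi_id": roi_id,
            "centroid_x_um": [r[2] * scenario.pixel_size_um for r in records],
            "centroid_y_um": [r[3] * scenario.pixel_size_um for r in records],
            "radius_um": [r[4] * scenario.pixel_size_um for r in records],
            "phenotype": [r[0] for r in records],
            "compartment": [r[1] if r[1] != "any" else None for r in records],
        }
    )
    # resolve "any"-population compartments and centroid-based truth
    cy = np.clip(table["centroid_y_um"].to_numpy().astype(int), 0, size - 1)
    cx = np.clip(table["centroid_x_um"].to_numpy().astype(int), 0, size - 1)
    codes = comp_labels[cy, cx]
    table["compartment"] = np.where(codes == PARENCHYMA, "parenchyma", "stroma")
    expr_df = pd.DataFrame(expr, columns=markers)
    return cmap, table, expr_df


def _render_roi(
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    cmap: CompartmentMap,
    table: pd.DataFrame,
    expr: pd.DataFrame,
    sm: SpilloverMatrix,
    roi_id: str,
) -> tuple[ImageStack, LabelMask, np.ndarray]:
    size = scenario.roi_size_px
    markers = scenario.panel.markers
    n_ch = len(markers)
    noise = scenario.noise_params

    lam = np.zeros((n_ch, size, size), dtype=np.float32)
    mask = np.zeros((size, size), dtype=np.int32)
    areas_px = np.zeros(len(table), dtype=int)
    expr_np = expr.to_numpy()

    cys = table["centroid_y_um"].to_numpy() / scenario.pixel_size_um
    cxs = table["centroid_x_um"].to_numpy() / scenario.pixel_size_um
    rads = table["radius_um"].to_numpy() / scenario.pixel_size_um
    ids = table["cell_id"].to_numpy()
    for i in range(len(table)):
        cy, cx, rad = cys[i], cxs[i], rads[i]
        y0, y1 = max(0, int(cy - rad)), min(size, int(cy + rad) + 2)
        x0, x1 = max(0, int(cx - rad)), min(size, int(cx + rad) + 2)
        yy = np.arange(y0, y1, dtype=float) - cy
        xx = np.arange(x0, x1, dtype=float) - cx
        inside = (yy * yy)[:, None] + (xx * xx)[None, :] <= rad * rad
        mask[y0:y1, x0:x1][inside] = ids[i]
        areas_px[i] = int(inside.sum())
        for ch in np.flatnonzero(expr_np[i]):
            lam[ch, y0:y1, x0:x1][inside] = expr_np[i, ch]

    # diffuse compartment signal only outside cells (ECM / packed epithelium)
    free = mask == 0
    comp_code = {"parenchyma": PARENCHYMA, "stroma": STROMA}
    for sig in scenario.diffuse_signals:
        if sig.marker not in markers:
            continue
        ch = markers.index(sig.marker)
        sel = free & (cmap.labels == comp_code[sig.compartment])
        lam[ch][sel] += sig.expected_counts

    # Poisson count noise (sampled only where expectation is nonzero;
    # lam is not reused, so sampling happens in place)
    if noise.poisson_scale > 0:
        nz = lam > 0
        lam[nz] = rng.poisson(lam[nz].astype(np.float64) * noise.poisson_scale) / noise.poisson_scale
    counts = lam

    # channel crosstalk: observed = true . SM  (per pixel)
    flat = counts.reshape(n_ch, -1)
    mixed = (sm.matrix.T.astype(np.float32) @ flat).reshape(n_ch, size, size)

    # scattered background salt events
    if noise.background_rate > 0:
        flat = mixed.reshape(n_ch, -1)
        for ch in range(n_ch):
            k = int(rng.poisson(noise.background_rate * size * size))
            if k:
                idx = rng.integers(0, size * size, size=k)
                np.add.at(flat[ch], idx, 1.0)

    # isolated hot pixels: set to a high constant
    if noise.hot_pixel_rate > 0:
        flat = mixed.reshape(n_ch, -1)
        for ch in range(n_ch):
            k = int(rng.poisson(noise.hot_pixel_rate * size * size))
            if k:
                idx = rng.integers(0, size * size, size=k)
                flat[ch][idx] = noise.hot_pixel_value

    np.rint(mixed, out=mixed)
    np.clip(mixed, 0, np.iinfo(np.uint16).max, out=mixed)
    pixels = mixed.astype(np.uint16)
    stack = ImageStack(
        pixels=pixels,
        panel=scenario.panel,
        roi_id=roi_id,
        pixel_size_um=scenario.pixel_size_um,
        tissue_region="tumor",
    )
    label_mask = LabelMask(labels=mask, roi_id=roi_id)
    return stack, label_mask, areas_px


def simulate_tissue(
    scenario: SyntheticScenario, *, render_images: bool = True
) -> tuple[list[ImageStack], list[LabelMask], GroundTruth]:
    """Generate the full synthetic sample: one image + mask per ROI, plus truth.

    With ``render_images=False`` only the geometric/expression ground truth is
    produced (images and masks are empty lists); this is the fast path for
    statistical checks of the placement process itself.
    """
    _check_packing(scenario)
    root = np.random.SeedSequence(scenario.seed)
    roi_seeds = root.spawn(scenario.n_rois)

    sm = make_spillover_matrix(
        scenario.panel.metals,
        scenario.noise_params.spillover_fractions
        if scenario.noise_params.spillover_fractions is not None
        else default_spillover_fractions(scenario.panel),
    )

    stacks: list[ImageStack] = []
    masks: list[LabelMask] = []
    tables = []
    exprs = []
    cmaps: dict[str, CompartmentMap] = {}
    for r in range(scenario.n_rois):
        rng = np.random.default_rng(roi_seeds[r])
        roi_id = f"roi{r + 1}"
        cmap, table, expr = _roi_ground_truth(scenario, rng, roi_id)
        cmaps[roi_id] = cmap
        if render_images:
            stack, mask, areas_px = _render_roi(scenario, rng, cmap, table, expr, sm, roi_id)
            table = table.copy()
            table["area_um2"] = areas_px * scenario.pixel_size_um**2
            stacks.append(stack)
            masks.append(mask)
        else:
            table = table.copy()
            table["area_um2"] = np.pi * table["radius_um"] ** 2
        tables.append(table)
        exprs.append(expr)

    cell_table = pd.concat(tables, ignore_index=True)
    expression = pd.concat(exprs, ignore_index=True)
    gt = GroundTruth(
        cell_table=cell_table,
        expression=expression,
        compartment_maps=cmaps,
        spillover_matrix=sm,
        intended_label=scenario.immunotype_label,
        scenario=scenario,
    )
    return stacks, masks, gt


def save_simulation(
    scenario: SyntheticScenario,
    stacks: list[ImageStack],
    masks: list[LabelMask],
    gt: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write all simulator artifacts: TIFFs, masks, panel, truth table, scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for stack, mask in zip(stacks, masks):
        img_path = outdir / f"{stack.roi_id}_image.tiff"
        mask_path = outdir / f"{mask.roi_id}_mask.tiff"
        write_image_stack(stack, img_path)
        write_label_mask(mask, mask_path)
        paths[f"image_{stack.roi_id}"] = img_path
        paths[f"mask_{mask.roi_id}"] = mask_path
    panel_path = outdir / "panel.csv"
    write_panel(scenario.panel, panel_path)
    paths["panel"] = panel_path
    truth_path = outdir / "ground_truth_cells.csv"
    write_cell_table(gt.cell_table, truth_path)
    paths["cell_table"] = truth_path
    from .io import write_spillover_csv

    sm_path = outdir / "spillover.csv"
    write_spillover_csv(gt.spillover_matrix, sm_path)
    paths["spillover"] = sm_path
    scenario_path = outdir / "scenario.json"
    scenario_path.write_text(json.dumps(scenario.to_json_dict(), indent=2, sort_keys=True) + "\n")
    paths["scenario"] = scenario_path
    return paths
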