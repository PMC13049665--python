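"""Compartment maps, cell densities, and the spatial immunotype classifier.

The decision layer of the pipeline.  A tumor ROI is partitioned into
*parenchyma* (the malignant-epithelial compartment, identified by
tumor-marker signal such as CA19-9) and *stroma* (the connective-tissue
compartment, identified by collagen / alpha-SMA).  CD8+ T-cell densities are
computed per ROI against tissue area, and the sample is assigned one of
three spatial immunotypes:

``depleted``
    whole-tissue CD8 density below the density threshold (200 cells/mm²);
``enriched``
    density at or above the threshold and a parenchymal:stromal CD8 density
    ratio exceeding the ratio threshold (0.6) — T cells infiltrate the tumor
    parenchyma itself;
``compartmentalized``
    density at or above the threshold but ratio below 0.6 — T cells are
    present yet confined to the stroma.

The thresholds are configuration, defaulting to the published 200 cells/mm²
and 0.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.morphology import closing as _binary_closing
from skimage.morphology import disk, remove_small_objects

from .io import ImageStack
from .panel import Panel

IMMUNOTYPE_LABELS = ("depleted", "compartmentalized", "enriched")

PARENCHYMA, STROMA, BACKGROUND = 1, 2, 0
_COMPARTMENT_NAMES = {PARENCHYMA: "parenchyma", STROMA: "stroma", BACKGROUND: "unassigned"}


@dataclass
class CompartmentMap:
    """Per-pixel compartment labeling of one ROI.

    ``labels`` holds 0 = background (no tissue), 1 = parenchyma, 2 = stroma.
    """

    labels: np.ndarray
    roi_id: str
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("compartment map must be 2-D")
        extra = set(np.unique(self.labels)) - {PARENCHYMA, STROMA, BACKGROUND}
        if extra:
            raise ValueError(f"unexpected compartment codes: {sorted(extra)}")

    def _area_mm2(self, code: int) -> float:
        px_mm2 = (self.pixel_size_um / 1000.0) ** 2
        return float(np.count_nonzero(self.labels == code)) * px_mm2

    @property
    def parenchyma_area_mm2(self) -> float:
        return self._area_mm2(PARENCHYMA)

    @property
    def stroma_area_mm2(self) -> float:
        return self._area_mm2(STROMA)

    @property
    def tissue_area_mm2(self) -> float:
        return self.parenchyma_area_mm2 + self.stroma_area_mm2

    @property
    def areas(self) -> dict[str, float]:
        return {
            "parenchyma": self.parenchyma_area_mm2,
            "stroma": self.stroma_area_mm2,
            "tissue": self.tissue_area_mm2,
        }


@dataclass(frozen=True)
class CompartmentSpec:
    """Parameters for deriving compartments from normalized marker images."""

    signal_threshold: float = 0.05
    closing_radius_um: float = 5.0
    min_object_um2: float = 100.0


def derive_compartments(
    img: ImageStack,
    panel: Panel | None = None,
    spec: CompartmentSpec | None = None,
    *,
    tissue: np.ndarray | None = None,
) -> CompartmentMap:
    """Partition an ROI into parenchyma / stroma / background.

    Operates on *normalized* channels.  Parenchyma is the morphologically
    closed region of tumor-marker signal; stroma the closed region of
    stroma-marker signal minus parenchyma; remaining tissue pixels are
    assigned to the nearest compartment by distance transform; pixels with
    no tissue signal at all are background.

    ``tissue`` optionally supplies the raw any-signal mask (pixels with
    signal in any channel, before morphological closing); otherwise it is
    taken as any nonzero pixel across the stack's channels.
    """
    panel = panel if panel is not None else img.panel
    spec = spec or CompartmentSpec()
    tumor_markers = panel.markers_with_role("tumor")
    stroma_markers = panel.markers_with_role("stroma")
    if not tumor_markers or not stroma_markers:
        raise ValueError("panel must declare at least one tumor-role and one stroma-role marker")

    px = img.pixel_size_um
    radius_px = max(1, int(round(spec.closing_radius_um / px)))
    min_px = max(1, int(round(spec.min_object_um2 / px**2)))
    footprint = disk(radius_px, decomposition="sequence")

    def _signal(markers: list[str]) -> np.ndarray:
        return np.max([img.channel(m) for m in markers], axis=0)

    def _region(signal: np.ndarray) -> np.ndarray:
        raw = signal >= spec.signal_threshold
        closed = _binary_closing(raw, footprint)
        return remove_small_objects(closed, max_size=min_px - 1)

    tumor_signal = _signal(tumor_markers)
    stroma_signal = _signal(stroma_markers)
    if tissue is None:
        tissue = img.pixels.max(axis=0) > 0

    tissue = _binary_closing(tissue, footprint)
    tissue = remove_small_objects(tissue, max_size=min_px - 1)
    if not tissue.any():
        raise ValueError("compartment degenerate: no tissue signal in ROI")

    par = _region(tumor_signal) & tissue
    stro = _region(stroma_signal) & tissue & ~par
    if not par.any() or not stro.any():
        missing = "parenchyma" if not par.any() else "stroma"
        raise ValueError(f"compartment degenerate: zero-area {missing}")

    labels = np.zeros(img.shape_yx, dtype=np.int8)
    labels[par] = PARENCHYMA
    labels[stro] = STROMA

    gaps = tissue & (labels == BACKGROUND)
    if gaps.any():
        # nearest assigned compartment, one EDT with index return
        _, (iy, ix) = ndi.distance_transform_edt(labels == BACKGROUND, return_indices=True)
        labels[gaps] = labels[iy[gaps], ix[gaps]]

    return CompartmentMap(labels=labels, roi_id=img.roi_id, pixel_size_um=px)


def assign_compartment(table: pd.DataFrame, cmap: CompartmentMap) -> pd.DataFrame:
    """Label each cell of one ROI by the compartment containing its centroid.

    Cells whose centroid pixel is background are labeled ``unassigned`` and
    excluded from compartment densities downstream.
    """
    out = table.copy()
    if "compartment" not in out.columns:
        out["compartment"] = pd.Series(index=out.index, dtype=object)
    rows = out["roi_id"] == cmap.roi_id
    if not rows.any():
        return out
    h, w = cmap.labels.shape
    px = cmap.pixel_size_um
    cx = np.clip((out.loc[rows, "centroid_x_um"].to_numpy() / px).astype(int), 0, w - 1)
    cy = np.clip((out.loc[rows, "centroid_y_um"].to_numpy() / px).astype(int), 0, h - 1)
    codes = cmap.labels[cy, cx]
    out.loc[rows, "compartment"] = [_COMPARTMENT_NAMES[int(c)] for c in codes]
    return out


@dataclass
class DensityReport:
    """Cell densities per (ROI, phenotype), with per-phenotype means over ROIs.

    ``per_roi`` has columns roi_id, phenotype, count, area_mm2, density;
    density is exactly count / area.  ``mean_density`` is the arithmetic
    mean of the per-ROI densities for each phenotype.
    """

    per_roi: pd.DataFrame
    area_definition: str = "tissue"

    @property
    def mean_density(self) -> dict[str, float]:
        return self.per_roi.groupby("phenotype")["density"].mean().to_dict()

    def density_of(self, phenotype: str, roi_id: str | None = None) -> float:
        df = self.per_roi
        sel = df["phenotype"] == phenotype
        if roi_id is not None:
            sel &= df["roi_id"] == roi_id
            row = df[sel]
            return float(row["density"].iloc[0]) if len(row) else 0.0
        return float(self.mean_density.get(phenotype, 0.0))


def compute_density(
    table: pd.DataFrame,
    areas_mm2: dict[str, float],
    phenotype: str | None = None,
) -> DensityReport:
    """Normalize per-phenotype cell counts to tissue area per ROI (cells/mm²).

    ``areas_mm2`` maps roi_id to the analyzed tissue area of that ROI.  Every
    ROI listed in ``areas_mm2`` is reported (zero counts included), so that
    means over ROIs are taken over all analyzed ROIs.  With more than one
    ROI, the per-phenotype mean over ROIs is exposed via ``mean_density``.
    """
    for roi, area in areas_mm2.items():
        if area <= 0:
            raise ValueError(f"zero or negative tissue area for ROI {roi!r}")
    if "phenotype" not in table.columns:
        raise ValueError("cell table has no phenotype column")
    phenotypes = (
        [phenotype] if phenotype is not None else sorted(table["phenotype"].dropna().unique())
    )
    counts = (
        table.groupby(["roi_id", "phenotype"]).size() if len(table) else pd.Series(dtype=int)
    )
    records = []
    for roi_id, area in areas_mm2.items():
        for ph in phenotypes:
            n = int(counts.get((roi_id, ph), 0)) if len(counts) else 0
            records.append(
                {
                    "roi_id": roi_id,
                    "phenotype": ph,
                    "count": n,
                    "area_mm2": area,
                    "density": n / area,
                }
            )
    return DensityReport(per_roi=pd.DataFrame(records))


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the spatial immunotype rule (published defaults)."""

    density: float = 200.0
    ratio: float = 0.6


@dataclass
class ImmunotypeResult:
    """The three-class spatial immunotype call with its full decision trace."""

    sample_id: str
    whole_density: float
    parenchymal_density: float
    stromal_density: float
    ratio: float
    label: str
    thresholds: ClassifierThresholds
    decision_trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "whole_density_cells_per_mm2": self.whole_density,
            "parenchymal_density_cells_per_mm2": self.parenchymal_density,
            "stromal_density_cells_per_mm2": self.stromal_density,
            "parenchyma_stroma_ratio": self.ratio,
            "label": self.label,
            "thresholds": {
                "density_cells_per_mm2": self.thresholds.density,
                "ratio": self.thresholds.ratio,
            },
            "decision_trace": self.decision_trace,
            "warnings": self.warnings,
        }


def classify_immunotype(
    whole_density: float,
    parenchymal_density: float,
    stromal_density: float,
    thresholds: ClassifierThresholds | None = None,
    *,
    sample_id: str = "sample",
    precomputed_ratio: float | None = None,
) -> ImmunotypeResult:
    """Apply the two-stage spatial immunotype rule.

    Stage 1: samples with whole-tissue CD8 density below ``thresholds.density``
    are immune *depleted*.  Stage 2 (otherwise): the parenchymal:stromal
    density ratio decides — above ``thresholds.ratio`` the sample is immune
    *enriched*, below it immune *compartmentalized*.  A ratio exactly at the
    threshold is assigned compartmentalized (the enriched rule requires the
    ratio to exceed the threshold) with a boundary warning.  Zero stromal
    density with positive parenchymal density gives an infinite ratio, hence
    enriched, with a warning.

    ``precomputed_ratio`` substitutes an externally aggregated ratio (the
    per-ROI-mean mode) for the default ratio of mean densities.
    """
    thresholds = thresholds or ClassifierThresholds()
    for name, d in (
        ("whole", whole_density),
        ("parenchymal", parenchymal_density),
        ("stromal", stromal_density),
    ):
        if d < 0 or not np.isfinite(d):
            raise ValueError(f"{name} density must be finite and non-negative, got {d}")

    trace: list = []
    warns: list[str] = []
    if precomputed_ratio is not None:
        ratio = float(precomputed_ratio)
        if ratio < 0:
            raise ValueError(f"ratio must be non-negative, got {ratio}")
    elif stromal_density > 0:
        ratio = parenchymal_density / stromal_density
    elif parenchymal_density > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")

    depleted = whole_density < thresholds.density
    trace.append(
        {
            "stage": "density",
            "comparison": f"whole_density {whole_density:g} < {thresholds.density:g}",
            "outcome": bool(depleted),
        }
    )
    if depleted:
        label = "depleted"
    else:
        if np.isnan(ratio) or (parenchymal_density == 0 and stromal_density == 0):
            raise ValueError(
                "no compartment-assigned CD8 cells despite whole-tissue density "
                "above threshold; cannot evaluate the parenchyma:stroma ratio"
            )
        if np.isinf(ratio):
            warns.append("stromal CD8 density is zero; ratio treated as +inf (enriched)")
            label = "enriched"
        elif ratio == thresholds.ratio:
            warns.append(
                f"ratio exactly at threshold {thresholds.ratio:g}; assigned "
                "compartmentalized (enriched requires ratio to exceed the threshold)"
            )
            label = "compartmentalized"
        elif ratio > thresholds.ratio:
            label = "enriched"
        else:
            label = "compartmentalized"
        trace.append(
            {
                "stage": "ratio",
                "comparison": f"ratio {ratio:g} > {thresholds.ratio:g}",
                "outcome": label == "enriched",
            }
        )
    for w in warns:
        warnings.warn(w)
    return ImmunotypeResult(
        sample_id=sample_id,
        whole_density=float(whole_density),
        parenchymal_density=float(parenchymal_density),
        stromal_density=float(stromal_density),
        ratio=float(ratio),
        label=label,
        thresholds=thresholds,
        decision_trace=trace,
        warnings=warns,
    )
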