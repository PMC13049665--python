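"""On-disk formats: multichannel TIFF stacks, label masks, panel and cell tables.

All readers validate strictly and raise rather than coerce; all writers are
set up so that write→read round trips are lossless at the declared precision
(bit-identical for images and masks, six decimals for cell-table floats).

Coordinate convention: pixel ``(0, 0)`` is the image's top-left corner, ``x``
increases rightward (columns), ``y`` downward (rows).  Centroids are reported
at pixel centers in micrometres: ``(centroid_px + 0.5) * pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .panel import Panel, PanelEntry

#: acquisition resolution in micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 1.0

VALID_TISSUE_REGIONS = frozenset({"tumor", "margin", "adjacent"})
VALID_COMPARTMENTS = frozenset({"parenchyma", "stroma", "unassigned"})

#: float format used for every CSV the package writes
CSV_FLOAT_FORMAT = "%.6f"

_REQUIRED_CELL_COLUMNS = ["cell_id", "roi_id", "centroid_x_um", "centroid_y_um", "area_um2"]


@dataclass
class ImageStack:
    """A multichannel ROI acquisition: ``pixels[channel, y, x]`` plus identity."""

    pixels: np.ndarray
    panel: Panel
    roi_id: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    tissue_region: str = "tumor"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be 3-D (channel, y, x), got {self.pixels.ndim}-D")
        if self.pixels.shape[0] != len(self.panel):
            raise ValueError(
                "panel/stack channel mismatch: stack has "
                f"{self.pixels.shape[0]} channels, panel has {len(self.panel)}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.tissue_region not in VALID_TISSUE_REGIONS:
            raise ValueError(
                f"tissue_region {self.tissue_region!r} not in {sorted(VALID_TISSUE_REGIONS)}"
            )
        # unsigned dtypes cannot hold negatives; skip the full scan for them
        if not np.issubdtype(self.pixels.dtype, np.unsignedinteger) and np.any(self.pixels < 0):
            raise ValueError("image stack contains negative values")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, marker: str) -> np.ndarray:
        return self.pixels[self.panel.index_of(marker)]


@dataclass
class LabelMask:
    """Integer segmentation mask: 0 = background, k > 0 = cell k."""

    labels: np.ndarray
    roi_id: str
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("label mask contains negative labels")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


# ---------------------------------------------------------------------------
# panel


def read_panel(path: str | Path) -> Panel:
    df = pd.read_csv(path)
    required = {"channel", "metal", "marker", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    entries = tuple(
        PanelEntry(int(r.channel), str(r.metal), str(r.marker), str(r.role))
        for r in df.itertuples(index=False)
    )
    return Panel(entries)


def write_panel(panel: Panel, path: str | Path) -> None:
    panel.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image stacks and masks


def read_image_stack(
    path: str | Path,
    panel: Panel | str | Path,
    *,
    roi_id: str | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    tissue_region: str = "tumor",
) -> ImageStack:
    """Read a single- or multi-page TIFF as an ImageStack in panel channel order."""
    if not isinstance(panel, Panel):
        panel = read_panel(panel)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D TIFF, got {arr.ndim}-D")
    if arr.shape[0] != len(panel):
        raise ValueError(
            f"panel/stack channel mismatch: TIFF has {arr.shape[0]} channels, "
            f"panel has {len(panel)}"
        )
    meta = _read_sidecar(path)
    return ImageStack(
        pixels=arr,
        panel=panel,
        roi_id=roi_id if roi_id is not None else meta.get("roi_id", Path(path).stem),
        pixel_size_um=float(meta.get("pixel_size_um", pixel_size_um)),
        tissue_region=str(meta.get("tissue_region", tissue_region)),
    )


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    _write_sidecar(
        path,
        {
            "roi_id": stack.roi_id,
            "pixel_size_um": stack.pixel_size_um,
            "tissue_region": stack.tissue_region,
            "markers": stack.panel.markers,
        },
    )


def read_label_mask(path: str | Path, *, roi_id: str | None = None) -> LabelMask:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got {arr.ndim}-D")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {arr.dtype}")
    meta = _read_sidecar(path)
    return LabelMask(
        labels=arr.astype(np.int32),
        roi_id=roi_id if roi_id is not None else meta.get("roi_id", Path(path).stem),
        connectivity=int(meta.get("connectivity", 8)),
    )


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32), photometric="minisblack")
    _write_sidecar(path, {"roi_id": mask.roi_id, "connectivity": mask.connectivity})


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def _write_sidecar(path: str | Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _read_sidecar(path: str | Path) -> dict:
    sp = _sidecar_path(path)
    if sp.exists():
        return json.loads(sp.read_text())
    return {}


# ---------------------------------------------------------------------------
# cell tables


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the cell-table schema; returns the (unmodified) frame.

    Required columns: cell_id, roi_id, centroid_x_um, centroid_y_um, area_um2.
    Optional: cluster_id, phenotype, compartment, and any number of
    ``mean_<marker>`` intensity columns.
    """
    missing = [c for c in _REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if len(df):
        if df.duplicated(subset=["roi_id", "cell_id"]).any():
            dupes = df[df.duplicated(subset=["roi_id", "cell_id"], keep=False)]
            raise ValueError(
                f"duplicate (roi_id, cell_id) pairs in cell table: "
                f"{dupes[['roi_id', 'cell_id']].drop_duplicates().values.tolist()[:5]}"
            )
        if (df["area_um2"] <= 0).any():
            raise ValueError("cell table contains non-positive cell areas")
        intensity_cols = [c for c in df.columns if c.startswith("mean_")]
        for col in intensity_cols:
            if (df[col] < 0).any():
                raise ValueError(f"negative intensities in column {col!r}")
        if "compartment" in df.columns:
            bad = set(df["compartment"].dropna().unique()) - VALID_COMPARTMENTS
            if bad:
                raise ValueError(f"unknown compartment values: {sorted(bad)}")
    return df


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_cell_table(df)


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(df)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# spillover matrices (square CSV, header row and index column = metal tags)


def read_spillover_csv(path: str | Path):
    from .preprocess import SpilloverMatrix

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("spillover CSV must be square with identical row/column tags")
    return SpilloverMatrix(matrix=df.to_numpy(dtype=float), tags=list(df.columns))


def write_spillover_csv(sm, path: str | Path) -> None:
    pd.DataFrame(sm.matrix, index=sm.tags, columns=sm.tags).to_csv(
        path, float_format=CSV_FLOAT_FORMAT
    )
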