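"""Image conditioning: spillover compensation, hot-pixel filtering, normalization.

The conditioning chain mirrors standard IMC practice and is applied in this
order: (1) channel-crosstalk compensation by non-negative least squares
against a known spillover matrix, (2) removal of isolated spuriously bright
pixels by a neighborhood-maximum rule, (3) per-channel percentile scaling of
intensities into [0, 1] with background suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import nnls

from .io import ImageStack

#: default hot-pixel threshold, in raw counts (pixel must exceed its
#: 8-neighborhood maximum by more than this to be treated as an artifact)
DEFAULT_HOT_PIXEL_THRESHOLD = 50.0

MAX_SPILL_FRACTION = 0.2


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square channel-crosstalk matrix.

    ``matrix[i, j]`` is the fraction of channel *i*'s true signal that is
    recorded in channel *j* (isotope impurity / oxide formation between
    neighboring mass channels).  The diagonal is exactly 1; off-diagonal
    fractions are small (at most 0.2).
    """

    matrix: np.ndarray
    tags: tuple[str, ...]

    def __init__(self, matrix, tags):
        object.__setattr__(self, "matrix", np.asarray(matrix, dtype=float))
        object.__setattr__(self, "tags", tuple(tags))
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"spillover matrix must be square, got shape {m.shape}")
        if m.shape[0] != len(self.tags):
            raise ValueError("tag count does not match matrix dimension")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("duplicate channel tags")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover matrix diagonal must be exactly 1")
        off = m - np.diag(np.diag(m))
        if off.min() < 0 or off.max() > MAX_SPILL_FRACTION:
            raise ValueError(
                f"off-diagonal spillover fractions must lie in [0, {MAX_SPILL_FRACTION}]"
            )
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("spillover matrix is singular")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def identity(cls, tags) -> "SpilloverMatrix":
        tags = tuple(tags)
        return cls(np.eye(len(tags)), tags)


def make_spillover_matrix(
    channels: list[str], fractions: dict[tuple[str, str], float] | None = None
) -> SpilloverMatrix:
    """Build a SpilloverMatrix from sparse (source, target) -> fraction entries.

    Unspecified off-diagonals are 0; the diagonal is implied 1.  Fractions
    outside [0, 0.2] are rejected as physically implausible for IMC crosstalk.
    """
    tags = list(channels)
    index = {t: i for i, t in enumerate(tags)}
    m = np.eye(len(tags))
    for (src, dst), frac in (fractions or {}).items():
        if src not in index or dst not in index:
            unknown = [c for c in (src, dst) if c not in index]
            raise ValueError(f"unknown channel name(s): {unknown}")
        if src == dst:
            raise ValueError("diagonal entries are implied 1 and cannot be set")
        if not (0.0 <= frac <= MAX_SPILL_FRACTION):
            raise ValueError(
                f"fraction out of plausible range [0, {MAX_SPILL_FRACTION}]: "
                f"({src}->{dst}) = {frac}"
            )
        m[index[src], index[dst]] = frac
    return SpilloverMatrix(m, tags)


_NNLS_TOL = 1e-9


def _batch_restricted_lsq(a: np.ndarray, b: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Least-squares solutions of ``a[:, S] @ x_S = b_i`` per row, grouped by support.

    ``a`` is the (channels x channels) mixing matrix, ``b`` the observed rows,
    ``active`` a boolean support mask per row.  Rows sharing a support pattern
    are solved together with one pseudo-inverse.
    """
    n, c = b.shape
    x = np.zeros((n, c))
    keys = active @ (1 << np.arange(c, dtype=np.int64))
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_keys) != 0])
    bounds = np.r_[starts, n]
    for s, e in zip(bounds[:-1], bounds[1:]):
        rows = order[s:e]
        support = np.flatnonzero(active[rows[0]])
        if support.size == 0:
            continue
        sol = np.linalg.pinv(a[:, support]) @ b[rows].T
        x[np.ix_(rows, support)] = sol.T
    return x


def compensate_spillover(values: np.ndarray, sm: SpilloverMatrix) -> np.ndarray:
    """Invert channel crosstalk by non-negative least squares.

    Solves, per event (pixel or cell), ``min_x || x @ SM - observed ||_2``
    subject to ``x >= 0``.  The unconstrained linear solve is used wherever
    its solution is already non-negative (there it *is* the NNLS optimum).
    Remaining events go through a vectorized active-set iteration (drop
    negative variables, re-solve on the support, repeat), whose KKT
    conditions are then verified; the rare event failing verification is
    re-solved with the exact scalar Lawson–Hanson routine.

    Parameters
    ----------
    values
        Observed intensities, shape ``(n_channels,)`` or ``(n_events,
        n_channels)``.
    sm
        The spillover matrix (row = source channel).

    Returns
    -------
    Corrected intensities with the same shape as ``values``.
    """
    v = np.asarray(values, dtype=float)
    single = v.ndim == 1
    if single:
        v = v[None, :]
    if v.ndim != 2 or v.shape[1] != sm.n:
        raise ValueError(
            f"observed vectors have {v.shape[-1]} channels, spillover matrix has {sm.n}"
        )
    if v.size and np.any(v < 0):
        raise ValueError("observed intensities must be non-negative")

    # x @ SM = obs  <=>  SM.T @ x.T = obs.T
    a = sm.matrix.T
    x = np.linalg.solve(a, v.T).T
    scale = np.maximum(np.abs(v).max(axis=1, initial=1.0), 1.0)
    bad = np.flatnonzero((x < -_NNLS_TOL * scale[:, None]).any(axis=1))
    if bad.size:
        xb = x[bad]
        vb = v[bad]
        active = np.ones_like(xb, dtype=bool)
        tol = _NNLS_TOL * scale[bad, None]
        for _ in range(sm.n):
            neg = active & (xb < -tol)
            if not neg.any():
                break
            active &= ~neg
            redo = neg.any(axis=1)
            xb[redo] = _batch_restricted_lsq(a, vb[redo], active[redo])
        xb[xb < 0] = 0.0
        # KKT dual feasibility: gradient must be >= 0 on the zeroed variables
        grad = (xb @ a.T - vb) @ a
        viol = np.flatnonzero((~active & (grad < -1e-6 * scale[bad, None])).any(axis=1))
        for i in viol:
            xb[i], _ = nnls(a, vb[i])
        x[bad] = xb
    np.clip(x, 0.0, None, out=x)
    if single:
        return x[0]
    return x


def compensate_cell_table(table, sm: SpilloverMatrix, markers: list[str]):
    """Spillover-compensate per-cell mean intensities (table mode).

    ``markers`` gives, in spillover-matrix channel order, the marker whose
    ``mean_<marker>`` column corresponds to each matrix row.  This is the
    default compensation mode when working from an existing cell table: the
    per-cell mean is a linear functional of the pixels, so compensating the
    means equals averaging per-pixel compensated values whenever the
    non-negativity constraint is inactive.
    """
    if len(markers) != sm.n:
        raise ValueError("marker list length must equal spillover matrix dimension")
    cols = [f"mean_{m}" for m in markers]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing intensity columns: {missing}")
    out = table.copy()
    if len(out):
        out[cols] = compensate_spillover(out[cols].to_numpy(dtype=float), sm)
    return out


def compensate_image(stack: ImageStack, sm: SpilloverMatrix) -> ImageStack:
    """Per-pixel spillover compensation of a full image stack."""
    c, h, w = stack.pixels.shape
    flat = stack.pixels.reshape(c, h * w).T.astype(float)
    corrected = compensate_spillover(flat, sm)
    out = corrected.T.reshape(c, h, w)
    return ImageStack(
        pixels=out,
        panel=stack.panel,
        roi_id=stack.roi_id,
        pixel_size_um=stack.pixel_size_um,
        tissue_region=stack.tissue_region,
    )


_NEIGHBOR_FOOTPRINT = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)


def filter_hot_pixels(
    img: ImageStack | np.ndarray, threshold: float = DEFAULT_HOT_PIXEL_THRESHOLD
):
    """Suppress isolated hot pixels with the neighborhood-maximum rule.

    For each pixel and channel, let ``m`` be the maximum over the pixel's
    eight neighbors (edge pixels use the available neighbors).  A pixel
    whose value exceeds ``m`` by more than ``threshold`` is replaced by
    ``m``.  A single pass over the pre-filter image; the operation is
    idempotent and never increases a pixel value.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")

    def _filter(arr: np.ndarray) -> np.ndarray:
        # mode="constant" with cval=0 never *creates* replacements above the
        # true neighbor max at edges because image values are >= 0
        if arr.ndim == 2:
            m = ndi.maximum_filter(arr, footprint=_NEIGHBOR_FOOTPRINT, mode="constant", cval=0)
        else:  # one pass over all channels; footprint confined to each plane
            m = ndi.maximum_filter(
                arr, footprint=_NEIGHBOR_FOOTPRINT[None, :, :], mode="constant", cval=0
            )
        if np.issubdtype(arr.dtype, np.unsignedinteger):
            # unsigned subtraction would wrap; compare via a signed widening
            hot = (arr.astype(np.int32) - m.astype(np.int32)) > threshold
        else:
            hot = (arr - m) > threshold
        return np.where(hot, m, arr)

    if isinstance(img, ImageStack):
        return ImageStack(
            pixels=_filter(img.pixels),
            panel=img.panel,
            roi_id=img.roi_id,
            pixel_size_um=img.pixel_size_um,
            tissue_region=img.tissue_region,
        )
    arr = np.asarray(img)
    if arr.ndim not in (2, 3):
        raise ValueError("expected a 2-D or 3-D array or an ImageStack")
    return _filter(arr)


@dataclass(frozen=True)
class ChannelNormalization:
    """Per-channel percentile scaling parameters.

    ``low_percentile`` / ``high_percentile`` are taken over the channel's
    *nonzero* values (IMC images are mostly empty background; percentiles
    over all pixels would collapse to zero).  After scaling into [0, 1],
    values below ``background_threshold`` are set to 0.
    """

    low_percentile: float = 0.0
    high_percentile: float = 99.5
    background_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValueError("require 0 <= low_percentile < high_percentile <= 100")
        if not (0 <= self.background_threshold < 1):
            raise ValueError("background_threshold must lie in [0, 1)")


@dataclass(frozen=True)
class NormalizationSpec:
    """Normalization parameters, per channel with a shared default.

    Real IMC studies tune percentiles and background thresholds per channel
    on sample images; here they are configuration, with a sensible shared
    default for the synthetic panel.
    """

    default: ChannelNormalization = field(default_factory=ChannelNormalization)
    per_channel: dict = field(default_factory=dict)

    def for_marker(self, marker: str) -> ChannelNormalization:
        return self.per_channel.get(marker, self.default)


def percentile_scale(
    values_pooled, spec: ChannelNormalization | None = None, *, marker: str = ""
) -> tuple[float, float] | None:
    """(P_low, P_high) over the pooled *nonzero* values of one channel.

    ``values_pooled`` may be one array or a list of arrays (e.g. the same
    channel across several ROIs, so one scale applies consistently to all).
    Returns None for a degenerate channel (no nonzero values, or equal
    percentiles), with a warning.
    """
    if spec is None:
        spec = ChannelNormalization()
    arrays = values_pooled if isinstance(values_pooled, (list, tuple)) else [values_pooled]
    nz = [np.asarray(a)[np.asarray(a) > 0] for a in arrays]
    nz = np.concatenate(nz) if nz else np.empty(0)
    if nz.size == 0:
        warnings.warn(f"degenerate channel {marker or '<unnamed>'}: no nonzero values")
        return None
    p_low, p_high = np.percentile(nz, [spec.low_percentile, spec.high_percentile])
    if p_high == p_low:
        warnings.warn(
            f"degenerate channel {marker or '<unnamed>'}: "
            f"P{spec.low_percentile} == P{spec.high_percentile} == {p_low}"
        )
        return None
    return float(p_low), float(p_high)


def apply_percentile_scale(
    values: np.ndarray,
    scale: tuple[float, float] | None,
    spec: ChannelNormalization | None = None,
) -> np.ndarray:
    """Scale values into [0, 1] with a precomputed (P_low, P_high) pair.

    ``scale=None`` marks a degenerate channel: the output is all zeros.
    Values below the background threshold after scaling are set to 0.
    """
    if spec is None:
        spec = ChannelNormalization()
    v = np.asarray(values, dtype=np.float32)
    if scale is None:
        return np.zeros_like(v)
    p_low, p_high = scale
    out = (v - p_low) / (p_high - p_low)
    np.clip(out, 0.0, 1.0, out=out)
    out[out < spec.background_threshold] = 0.0
    return out


def normalize_percentile(
    values: np.ndarray, spec: ChannelNormalization | None = None, *, marker: str = ""
) -> np.ndarray:
    """Scale one channel's intensities into [0, 1] with background suppression.

    ``v' = clip((v - P_low) / (P_high - P_low), 0, 1)``, percentiles over the
    nonzero values (linear interpolation); then ``v' < background_threshold``
    is zeroed.  A channel with no nonzero values, or with equal low and high
    percentiles, is degenerate: the output is all zeros and a warning is
    emitted.
    """
    if spec is None:
        spec = ChannelNormalization()
    scale = percentile_scale(values, spec, marker=marker)
    return apply_percentile_scale(values, scale, spec)


def normalize_stack(
    stack: ImageStack,
    spec: NormalizationSpec | None = None,
    scales: dict | None = None,
) -> ImageStack:
    """Apply percentile normalization channel-wise to a full image stack.

    With ``scales`` (marker → (P_low, P_high) or None), precomputed — e.g.
    pooled across all ROIs of a sample — scales are applied instead of
    estimating from this stack alone.
    """
    if spec is None:
        spec = NormalizationSpec()
    out = np.empty(stack.pixels.shape, dtype=np.float32)
    for entry in stack.panel:
        ch_spec = spec.for_marker(entry.marker_name)
        ch = stack.pixels[entry.channel_index]
        if scales is not None:
            out[entry.channel_index] = apply_percentile_scale(ch, scales[entry.marker_name], ch_spec)
        else:
            out[entry.channel_index] = normalize_percentile(
                ch, ch_spec, marker=entry.marker_name
            )
    return ImageStack(
        pixels=out,
        panel=stack.panel,
        roi_id=stack.roi_id,
        pixel_size_um=stack.pixel_size_um,
        tissue_region=stack.tissue_region,
    )
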