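"""Count and classify hematopoietic cells in dual-channel stacks.

Circulating cells move faster than the acquisition and appear as
single-plane artifacts; non-moving cells span 15-20 z-sections.  A rolling
median over ~20 planes (approximately one cell depth) removes the
single-plane transients, a top-hat + threshold + 3D distance-watershed
chain segments the remaining objects, intensities are measured on the raw
(unfiltered) data, and per-channel thresholds split double-positive
hemogenic cells from single-positive hematopoietic (HSPC) ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import ball, h_maxima
from skimage.segmentation import watershed

from ehtkit.exceptions import ConfigurationError, WindowError
from ehtkit.volume import VolumeStack

__all__ = [
    "PreprocessConfig",
    "SegmentConfig",
    "temporal_median",
    "preprocess",
    "segment_objects",
    "measure_objects",
    "classify_objects",
    "suggest_threshold",
]


def _as_zyx(stack) -> np.ndarray:
    if isinstance(stack, VolumeStack):
        raise ConfigurationError("pass a single-channel (z, y, x) array; use stack.channel(i)")
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ConfigurationError(f"expected a (z, y, x) array, got ndim={arr.ndim}")
    return arr


# ---------------------------------------------------------------------------
# rolling median over planes
# ---------------------------------------------------------------------------

def temporal_median(stack, window: int = 20, mode: str = "replace") -> np.ndarray:
    """Rolling median over ~one cell depth of planes; removes 2D outliers.

    ``replace`` (default): each plane becomes the median of its centered,
    edge-truncated window — objects present in most of the window survive,
    single-plane transients vanish.  ``subtract``: the rolling median is
    subtracted and negatives clipped, which instead removes the persistent
    component (kept for fidelity with pipelines that subtract).

    The window runs over the plane axis (z here: the stated window
    approximates the cell depth in z-sections); for a time axis pass the
    (t, y, x) array the same way.
    """
    arr = _as_zyx(stack)
    if mode not in ("replace", "subtract"):
        raise ConfigurationError(f"mode must be 'replace' or 'subtract', got {mode!r}")
    nz = arr.shape[0]
    if window > nz:
        raise WindowError(f"median window {window} exceeds plane count {nz}")
    med = np.empty_like(arr)
    half = window // 2
    for i in range(nz):
        lo = max(0, i - half)
        hi = min(nz, lo + window)
        lo = max(0, hi - window)
        med[i] = np.median(arr[lo:hi], axis=0)
    if mode == "replace":
        return med
    return np.clip(arr - med, 0, None)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    """Signal-filter chain ahead of segmentation.

    Percentile contrast stretch, per-plane rolling-ball background
    subtraction, then 3D Gaussian blur, in that order.
    """

    stretch_percentiles: tuple[float, float] = (1.0, 99.8)
    rolling_ball_radius_px: int = 15
    gaussian_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        lo, hi = self.stretch_percentiles
        if not (0 <= lo < hi <= 100):
            raise ConfigurationError("invalid stretch percentiles")
        if self.rolling_ball_radius_px <= 0:
            raise ConfigurationError("rolling-ball radius must be positive")
        if any(s < 0 for s in self.gaussian_sigma):
            raise ConfigurationError("gaussian sigma must be >= 0")


def preprocess(stack, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast stretch, background subtraction, 3D Gaussian blur."""
    from skimage.restoration import rolling_ball

    cfg = cfg or PreprocessConfig()
    arr = _as_zyx(stack)
    lo, hi = np.percentile(arr, cfg.stretch_percentiles)
    if hi > lo:
        arr = np.clip((arr - lo) / (hi - lo), 0, 1)
    else:
        arr = np.zeros_like(arr)
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        bg = rolling_ball(arr[i], radius=cfg.rolling_ball_radius_px)
        out[i] = arr[i] - bg
    np.clip(out, 0, None, out=out)
    if any(s > 0 for s in cfg.gaussian_sigma):
        out = ndi.gaussian_filter(out, sigma=cfg.gaussian_sigma)
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentConfig:
    """Top-hat + threshold + distance-watershed segmentation parameters."""

    tophat_radius_px: int = 6
    threshold: float | None = None  # None: Otsu on the top-hat image
    min_size_voxels: int = 50
    #: marker suppression depth, in intensity units of the top-hat image:
    #: local maxima shallower than this are merged before seeding
    h_maxima_depth: float = 5.0

    def __post_init__(self):
        if self.tophat_radius_px <= 0:
            raise ConfigurationError("top-hat radius must be positive")
        if self.min_size_voxels < 1:
            raise ConfigurationError("min_size_voxels must be >= 1")


def segment_objects(
    stack, cfg: SegmentConfig | None = None, spacing_um=(1.0, 1.0, 1.0)
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment bright objects; returns (labels, object table skeleton).

    White top-hat with a spherical structuring element flattens the
    background, a global threshold binarizes, and touching objects are
    split by a watershed on the Euclidean distance transform seeded from
    h-maxima (shallow maxima suppressed to avoid oversplitting); objects
    below the minimum size are dropped.
    """
    cfg = cfg or SegmentConfig()
    arr = _as_zyx(stack)
    if any(2 * cfg.tophat_radius_px + 1 > s for s in arr.shape):
        raise ConfigurationError("structuring element larger than the image")
    selem = ball(cfg.tophat_radius_px)
    tophat = ndi.white_tophat(arr, footprint=selem)
    if cfg.threshold is None:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(tophat))
    else:
        thr = float(cfg.threshold)
    binary = tophat > thr
    if not binary.any():
        return np.zeros(arr.shape, dtype=np.int32), pd.DataFrame(
            columns=["id", "voxel_count", "centroid_z_um", "centroid_y_um", "centroid_x_um"]
        )
    distance = ndi.distance_transform_edt(binary, sampling=spacing_um)
    # markers from intensity maxima (smoothed top-hat) so deeply overlapping
    # blobs still seed separately; flooding runs on the distance transform
    smoothed = ndi.gaussian_filter(tophat, sigma=1.0)
    maxima = h_maxima(smoothed, cfg.h_maxima_depth) & binary
    markers, _ = ndi.label(maxima)
    if markers.max() == 0:
        labels, _ = ndi.label(binary)
    else:
        labels = watershed(-distance, markers=markers, mask=binary)
        unseeded, n_un = ndi.label(binary & (labels == 0))
        if n_un:  # components without any marker keep plain labels
            labels = np.where(unseeded > 0, unseeded + labels.max(), labels)
    # minimum-size filter, relabel consecutively
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= cfg.min_size_voxels)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[labels]

    rows = []
    sz, sy, sx = spacing_um
    for new_id in range(1, keep.size + 1):
        voxels = np.argwhere(labels == new_id)
        cz, cy, cx = voxels.mean(axis=0) + 0.5
        rows.append(
            {
                "id": new_id,
                "voxel_count": len(voxels),
                "centroid_z_um": cz * sz,
                "centroid_y_um": cy * sy,
                "centroid_x_um": cx * sx,
            }
        )
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# measurement and classification
# ---------------------------------------------------------------------------

def measure_objects(
    labels: np.ndarray,
    raw_stack: VolumeStack | np.ndarray,
    background_roi: np.ndarray | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-object per-channel totals from the raw (unfiltered) data.

    ``raw_stack`` is a (c, z, y, x) array or VolumeStack; ``background_roi``
    a boolean mask over (z, y, x) sampling background voxels.  Corrected
    total = raw total - mean(background) * voxel count; without a
    background ROI totals are flagged uncorrected.
    """
    raw = raw_stack.data if isinstance(raw_stack, VolumeStack) else np.asarray(raw_stack, float)
    if raw.ndim != 4:
        raise ConfigurationError("raw stack must be (c, z, y, x)")
    if raw.shape[1:] != labels.shape:
        raise ConfigurationError("labels and raw stack shapes differ")
    if channel_names is None:
        if isinstance(raw_stack, VolumeStack) and raw_stack.channel_names:
            channel_names = raw_stack.channel_names
        else:
            channel_names = tuple(f"ch{i}" for i in range(raw.shape[0]))
    ids = np.unique(labels)
    ids = ids[ids > 0]
    counts = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    empty = counts == 0
    if empty.any():
        warnings.warn(f"skipping empty objects: {list(ids[empty])}")
        ids, counts = ids[~empty], counts[~empty]
    table = pd.DataFrame({"id": ids, "voxel_count": counts.astype(int)})
    corrected = background_roi is not None
    for c, name in enumerate(channel_names):
        totals = ndi.sum_labels(raw[c], labels, ids)
        table[f"total_{name}"] = totals
        if corrected:
            bg_mean = float(raw[c][background_roi].mean())
            table[f"corrected_{name}"] = totals - bg_mean * counts
    table.attrs["background_corrected"] = corrected
    if not corrected:
        warnings.warn("no background ROI given; totals are uncorrected")
    return table


def classify_objects(
    table: pd.DataFrame,
    thresholds: dict[str, float],
    green: str = "green",
    red: str = "red",
) -> pd.DataFrame:
    """Split objects into hemogenic / hspc / other by channel positivity.

    Double-positive (green and red above threshold) objects are hemogenic
    cells; green-positive red-negative objects are hematopoietic (HSPC);
    everything else ``other``.  Thresholds apply to the background-corrected
    totals when present, otherwise to the raw totals.
    """
    for name in (green, red):
        if name not in thresholds:
            raise ConfigurationError(f"missing threshold for channel {name!r}")
        if f"corrected_{name}" not in table.columns and f"total_{name}" not in table.columns:
            raise ConfigurationError(f"channel {name!r} not measured in the table")

    def values(name):
        col = f"corrected_{name}" if f"corrected_{name}" in table.columns else f"total_{name}"
        return table[col].to_numpy(dtype=float)

    g_pos = values(green) > thresholds[green]
    r_pos = values(red) > thresholds[red]
    out = table.copy()
    out["object_class"] = np.where(
        g_pos & r_pos, "hemogenic", np.where(g_pos & ~r_pos, "hspc", "other")
    )
    return out


def suggest_threshold(values) -> float:
    """Two-component intensity split (Otsu on 1D values) as a starting point."""
    from skimage.filters import threshold_otsu

    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        raise ConfigurationError("need at least two distinct values")
    return float(threshold_otsu(values))
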