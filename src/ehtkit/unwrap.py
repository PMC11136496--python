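"""Unwrap a tubular vessel wall into a 2D cartography.

For each axial (x) slice a closed ring contour is fitted to the bright wall
signal in the (z, y) cross-section; intensity sampled along the ring at
fixed arc-length steps fills one cartography column.  The cartography's X
axis is the axial position and its Y axis the perimeter arc length from the
ventral reference angle, so distances along Y are distances along the wall.
Every cartography pixel can be mapped back to its 3D wall location.

Ring refinement is a discrete energy-minimizing closed snake: radial rays
from the current center locate the wall-intensity peak (with parabolic
sub-step refinement), a circular moving average regularizes curvature, and
the center is updated to the contour centroid; the fit propagates slice to
slice from the previous ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ehtkit.exceptions import ConfigurationError, GeometryError, NoRingFound
from ehtkit.volume import VolumeStack

__all__ = [
    "RingSet",
    "Cartography",
    "fit_rings",
    "unwrap",
    "back_map",
    "measure_perimeter",
]


@dataclass
class RingSet:
    """Per-slice fitted ring contours in physical (z, y) µm coordinates.

    ``contours[i]`` is an (n_angles, 2) array of (z, y) points ordered by
    angle from the ventral reference direction (+z), not closed (the last
    point connects back to the first).  ``slice_indices`` are the x-slice
    indices the rings belong to.
    """

    slice_indices: np.ndarray
    centers: np.ndarray  # (n, 2) (z, y) µm
    contours: list[np.ndarray]
    spacing_um: tuple[float, float, float]  # (z, y, x) of the source stack
    reference_angle_deg: float = 0.0

    def __post_init__(self):
        if len(self.contours) != len(self.slice_indices):
            raise ConfigurationError("one contour per included slice required")
        for c in self.contours:
            if len(c) < 3:
                raise GeometryError("ring contour needs at least 3 points")

    def __len__(self) -> int:
        return len(self.contours)

    def arc_lengths(self, i: int) -> np.ndarray:
        """Cumulative arc length at each contour point of ring ``i`` (µm)."""
        c = self.contours[i]
        seg = np.hypot(*(np.diff(np.vstack([c, c[:1]]), axis=0).T))
        return np.concatenate([[0.0], np.cumsum(seg)])  # length n+1, last = perimeter

    def perimeter(self, i: int) -> float:
        return float(self.arc_lengths(i)[-1])


@dataclass
class Cartography:
    """Unwrapped wall-intensity map: rows = arc length, columns = axial.

    ``image[j, i]`` is the wall intensity at arc position ``j * arc_step_um``
    (from the reference angle) on slice ``rings.slice_indices[i]``; rows
    beyond a column's perimeter are NaN (columns are padded to the maximum
    perimeter).  ``valid_arc_fraction`` marks the reliably segmentable part
    of the circumference (in real acquisitions roughly the floor-centred
    two-thirds); it is carried as a mask so counts can restrict to it.
    """

    image: np.ndarray
    arc_step_um: float
    rings: RingSet
    reference_angle_deg: float = 0.0
    band_halfwidth_um: float = 1.5
    mode: str = "max"
    valid_arc_fraction: float = 1.0

    @property
    def pixel_size_um(self) -> tuple[float, float]:
        """(dy, dx): arc step and axial step, µm."""
        return (self.arc_step_um, self.rings.spacing_um[2])

    def valid_mask(self) -> np.ndarray:
        """Boolean rows mask centred on the reference angle (floor)."""
        n_rows = self.image.shape[0]
        mask = np.zeros(n_rows, dtype=bool)
        half = int(round(0.5 * self.valid_arc_fraction * n_rows))
        mask[:half] = True
        mask[n_rows - half :] = True
        return mask


# ---------------------------------------------------------------------------
# ring fitting
# ---------------------------------------------------------------------------

def _slice_image(stack: VolumeStack, channel: int, ix: int) -> np.ndarray:
    """Cross-section (z, y) image at axial slice ix."""
    return stack.channel(channel)[:, :, ix]


def _sample_bilinear(img: np.ndarray, z_um, y_um, spacing) -> np.ndarray:
    sz, sy = spacing
    coords = np.vstack([np.asarray(z_um) / sz - 0.5, np.asarray(y_um) / sy - 0.5])
    return ndi.map_coordinates(img.astype(float), coords, order=1, mode="constant", cval=0.0)


def _refine_ring(
    img: np.ndarray,
    spacing_zy: tuple[float, float],
    center: np.ndarray,
    radii: np.ndarray,
    angles: np.ndarray,
    search_halfwidth_um: float,
    n_iter: int = 10,
    smooth_window: int = 7,
    min_peak: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One slice's snake refinement; returns (center, radii) or raises."""
    step = min(spacing_zy) / 2.0
    offsets = np.arange(-search_halfwidth_um, search_halfwidth_um + step / 2, step)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])  # (z, y) unit vectors

    for _ in range(n_iter):
        # radial profiles: (n_angles, n_offsets)
        rr = radii[:, None] + offsets[None, :]
        pz = center[0] + rr * dirs[:, 0:1]
        py = center[1] + rr * dirs[:, 1:2]
        prof = _sample_bilinear(img, pz.ravel(), py.ravel(), spacing_zy).reshape(rr.shape)
        peak_idx = np.argmax(prof, axis=1)
        peak_val = prof[np.arange(len(angles)), peak_idx]
        # auto detectability: a ray must reach a decent fraction of the slice's
        # brightest signal; a blank slice has max 0 and fails every ray
        thresh = min_peak if min_peak is not None else 0.1 * float(img.max())
        valid = peak_val > max(thresh, 1e-12)
        if valid.sum() < 0.3 * len(angles):
            raise NoRingFound("wall signal below detectability on this slice")
        # parabolic sub-step refinement of the peak position
        pi = peak_idx.copy()
        inner = (pi > 0) & (pi < len(offsets) - 1)
        delta = np.zeros(len(angles))
        f0 = prof[np.arange(len(angles)), np.clip(pi - 1, 0, None)]
        f1 = peak_val
        f2 = prof[np.arange(len(angles)), np.clip(pi + 1, None, len(offsets) - 1)]
        denom = f0 - 2 * f1 + f2
        with np.errstate(divide="ignore", invalid="ignore"):
            d = 0.5 * (f0 - f2) / denom
        delta[inner] = np.clip(np.nan_to_num(d[inner]), -0.5, 0.5)
        new_radii = radii + offsets[peak_idx] + delta * step
        # fill invalid angles by periodic interpolation over valid ones
        if not valid.all():
            idx = np.flatnonzero(valid)
            ang_ext = np.concatenate([angles[idx] - 2 * np.pi, angles[idx], angles[idx] + 2 * np.pi])
            rad_ext = np.tile(new_radii[idx], 3)
            new_radii[~valid] = np.interp(angles[~valid], ang_ext, rad_ext)
        # curvature regularization: circular moving average
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        ext = np.concatenate([new_radii[-pad:], new_radii, new_radii[:pad]])
        radii = np.convolve(ext, kernel, mode="valid")
        # re-center on the contour centroid
        contour = center + radii[:, None] * dirs
        new_center = contour.mean(axis=0)
        center = center + 0.8 * (new_center - center)
    contour = center + radii[:, None] * dirs
    return np.asarray(center, dtype=float), contour


def fit_rings(
    stack: VolumeStack,
    channel: int,
    init_center_zy_um: tuple[float, float],
    init_radius_um: float,
    n_angles: int = 360,
    search_halfwidth_um: float = 6.0,
    reference_angle_deg: float = 0.0,
    min_peak: float | None = None,
    slice_range: tuple[int, int] | None = None,
) -> RingSet:
    """Fit one wall ring per axial slice, propagating slice to slice.

    The circle (``init_center_zy_um``, ``init_radius_um``) initializes the
    first slice, as a user would draw it on the first plane; each subsequent
    slice starts from the previous fit.  Angle 0 points along +z (the
    ventral floor line) and increases toward +y.

    Raises :class:`NoRingFound` if the first slice has no detectable wall;
    on later slices propagation stops with a partial RingSet and a warning.
    """
    sz, sy, sx = stack.spacing_um
    nz, ny, nx = stack.shape_zyx
    cz, cy = init_center_zy_um
    if not (0 <= cz <= nz * sz and 0 <= cy <= ny * sy):
        raise ConfigurationError("initial circle center outside the image")
    lo, hi = slice_range if slice_range is not None else (0, nx)

    angles = (np.arange(n_angles) / n_angles) * 2 * np.pi + np.deg2rad(reference_angle_deg)
    center = np.array([cz, cy], dtype=float)
    radii = np.full(n_angles, float(init_radius_um))

    indices, centers, contours = [], [], []
    for ix in range(lo, hi):
        img = _slice_image(stack, channel, ix)
        try:
            # the first slice starts from the user's circle and needs the
            # full relaxation; propagated slices start near-converged
            center, contour = _refine_ring(
                img,
                (sz, sy),
                center.copy(),
                radii.copy(),
                angles,
                search_halfwidth_um,
                n_iter=12 if ix == lo else 3,
                min_peak=min_peak,
            )
        except NoRingFound:
            if not indices:
                raise
            warnings.warn(f"ring propagation stopped at slice {ix}: wall signal lost")
            break
        radii = np.hypot(*(contour - center).T)
        indices.append(ix)
        centers.append(center.copy())
        contours.append(contour)

    return RingSet(
        slice_indices=np.asarray(indices, dtype=int),
        centers=np.asarray(centers, dtype=float),
        contours=contours,
        spacing_um=stack.spacing_um,
        reference_angle_deg=reference_angle_deg,
    )


# ---------------------------------------------------------------------------
# unwrapping and back-mapping
# ---------------------------------------------------------------------------

def unwrap(
    stack: VolumeStack,
    rings: RingSet,
    channel: int,
    band_halfwidth_um: float = 1.5,
    mode: str = "max",
    arc_step_um: float | None = None,
    valid_arc_fraction: float = 1.0,
) -> Cartography:
    """Project wall intensity along each ring into a cartography column.

    For every arc position the intensity is reduced over a radial band of
    ``+-band_halfwidth_um`` around the contour — maximum by default (the
    junction signal is a thin bright sheet), mean selectable.  Columns are
    padded with NaN to the largest perimeter so the image is rectangular.
    """
    if mode not in ("max", "mean"):
        raise ConfigurationError(f"mode must be 'max' or 'mean', got {mode!r}")
    if len(rings) == 0:
        raise ConfigurationError("empty RingSet")
    nx = stack.shape_zyx[2]
    if rings.slice_indices.max() >= nx:
        raise ConfigurationError("ring slice indices exceed stack axial extent")
    sz, sy, _ = stack.spacing_um
    if arc_step_um is None:
        arc_step_um = min(sy, stack.spacing_um[0])

    perims = [rings.perimeter(i) for i in range(len(rings))]
    n_rows = int(np.ceil(max(perims) / arc_step_um))
    image = np.full((n_rows, len(rings)), np.nan, dtype=np.float32)

    step = min(sz, sy) / 2.0
    offsets = np.arange(-band_halfwidth_um, band_halfwidth_um + step / 2, step)
    for i in range(len(rings)):
        ix = rings.slice_indices[i]
        img = _slice_image(stack, channel, ix)
        contour = rings.contours[i]
        center = rings.centers[i]
        arcs = rings.arc_lengths(i)
        perim = arcs[-1]
        n_valid = int(np.floor(perim / arc_step_um)) + 1
        n_valid = min(n_valid, n_rows)
        targets = np.arange(n_valid) * arc_step_um
        closed = np.vstack([contour, contour[:1]])
        pz = np.interp(targets, arcs, closed[:, 0])
        py = np.interp(targets, arcs, closed[:, 1])
        radial = np.column_stack([pz, py]) - center
        norm = np.linalg.norm(radial, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        radial /= norm
        zz = pz[:, None] + offsets[None, :] * radial[:, 0:1]
        yy = py[:, None] + offsets[None, :] * radial[:, 1:2]
        vals = _sample_bilinear(img, zz.ravel(), yy.ravel(), (sz, sy)).reshape(zz.shape)
        column = vals.max(axis=1) if mode == "max" else vals.mean(axis=1)
        image[:n_valid, i] = column

    return Cartography(
        image=image,
        arc_step_um=float(arc_step_um),
        rings=rings,
        reference_angle_deg=rings.reference_angle_deg,
        band_halfwidth_um=band_halfwidth_um,
        mode=mode,
        valid_arc_fraction=valid_arc_fraction,
    )


def back_map(carto: Cartography, points_xy_um) -> np.ndarray:
    """3D wall coordinates (x, y, z) µm for cartography positions (X, Y) µm.

    X is the axial position, Y the arc length from the reference angle.  Y
    wraps modulo the slice perimeter (Y = perimeter maps to the ventral
    point, same as Y = 0); X outside the unwrapped range is a range error.
    """
    rings = carto.rings
    sx = rings.spacing_um[2]
    points = np.atleast_2d(np.asarray(points_xy_um, dtype=float))
    out = np.empty((len(points), 3))
    x_slices = rings.slice_indices
    x_lo = x_slices.min() * sx
    x_hi = (x_slices.max() + 1) * sx
    for k, (x_um, y_um) in enumerate(points):
        if not (x_lo - 0.5 * sx <= x_um <= x_hi + 0.5 * sx):
            raise ConfigurationError(f"X = {x_um} µm outside the unwrapped axial range")
        ix = int(round(x_um / sx - 0.5))
        i = int(np.argmin(np.abs(x_slices - ix)))
        arcs = rings.arc_lengths(i)
        perim = arcs[-1]
        if y_um > perim + carto.arc_step_um or y_um < -carto.arc_step_um:
            raise ConfigurationError(f"Y = {y_um} µm beyond the ring perimeter {perim:.2f} µm")
        s = y_um % perim
        contour = rings.contours[i]
        closed = np.vstack([contour, contour[:1]])
        z = np.interp(s, arcs, closed[:, 0])
        y = np.interp(s, arcs, closed[:, 1])
        out[k] = ((x_slices[i] + 0.5) * sx, y, z)
    return out


def measure_perimeter(rings: RingSet) -> tuple[pd.DataFrame, dict]:
    """Per-slice ring perimeters (µm) and summary statistics."""
    if len(rings) == 0:
        raise ConfigurationError("empty RingSet")
    perims = np.array([rings.perimeter(i) for i in range(len(rings))])
    table = pd.DataFrame({"slice": rings.slice_indices, "perimeter_um": perims})
    summary = {
        "mean_um": float(perims.mean()),
        "median_um": float(np.median(perims)),
        "sd_um": float(perims.std(ddof=1)) if len(perims) > 1 else 0.0,
        "n_slices": int(len(perims)),
    }
    return table, summary
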