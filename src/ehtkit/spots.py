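"""Spatial statistics of smFISH spots relative to labeled cell surfaces.

Spots are point coordinates (µm); cells are labeled 3D masks classified as
roof endothelial, hemogenic/EHT or sub-aortic, inside an aorta mask.  The
headline statistic is the attraction distance: the smallest distance from
hemogenic/EHT cells within which 50% (d50) or 75% (d75) of the spots lie.
Distances are surface distances (0 inside a target cell), computed with a
Euclidean distance transform at voxel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ehtkit import stats as stats_core
from ehtkit.exceptions import ConfigurationError

__all__ = [
    "CellSurfaceSet",
    "DistanceProfile",
    "classify_spots",
    "count_spots_per_cell",
    "distance_profile",
    "summarize_scene",
]

CELL_CLASSES = ("roof_endothelial", "hemogenic_EHT", "sub_aortic")
COMPARTMENTS = ("aortic_cell", "extra_aortic", "unassigned")


@dataclass
class CellSurfaceSet:
    """Labeled 3D cell masks with per-cell class labels and an aorta mask.

    ``labels`` is a (z, y, x) integer array (0 = background); ``classes``
    maps each positive label to one of ``CELL_CLASSES``; ``aorta_mask`` is
    the boolean vessel volume; ``spacing_um`` the voxel size (z, y, x).
    """

    labels: np.ndarray
    classes: dict[int, str]
    aorta_mask: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.aorta_mask = np.asarray(self.aorta_mask, dtype=bool)
        if self.labels.shape != self.aorta_mask.shape:
            raise ConfigurationError("labels and aorta_mask shapes differ")
        bad = set(self.classes.values()) - set(CELL_CLASSES)
        if bad:
            raise ConfigurationError(f"unknown cell classes: {sorted(bad)}")

    @classmethod
    def from_masks(cls, masks: dict[int, np.ndarray], classes, aorta_mask, spacing_um=(1, 1, 1)):
        """Build from per-cell boolean masks; masks must be disjoint."""
        labels = None
        overlap_ids = []
        for cid, m in masks.items():
            m = np.asarray(m, dtype=bool)
            if labels is None:
                labels = np.zeros(m.shape, dtype=np.int32)
            if (labels[m] != 0).any():
                overlap_ids.append(cid)
            labels[m] = cid
        if overlap_ids:
            raise ConfigurationError(f"overlapping cell masks: {overlap_ids}")
        return cls(labels=labels, classes=dict(classes), aorta_mask=aorta_mask, spacing_um=spacing_um)

    def class_mask(self, cell_class: str) -> np.ndarray:
        ids = [cid for cid, c in self.classes.items() if c == cell_class]
        return np.isin(self.labels, ids)


@dataclass
class DistanceProfile:
    """Per-spot distances to the nearest target cell with cumulative curve."""

    distances_um: np.ndarray
    grid_um: np.ndarray
    cumulative: np.ndarray  # F(d) on grid, nondecreasing, ends at 1
    d50: float
    d75: float


def _spot_voxels(spots: pd.DataFrame, spacing, shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sz, sy, sx = spacing
    iz = np.clip(np.floor(spots["z"].to_numpy() / sz).astype(int), 0, shape[0] - 1)
    iy = np.clip(np.floor(spots["y"].to_numpy() / sy).astype(int), 0, shape[1] - 1)
    ix = np.clip(np.floor(spots["x"].to_numpy() / sx).astype(int), 0, shape[2] - 1)
    return iz, iy, ix


def classify_spots(spots: pd.DataFrame, cells: CellSurfaceSet) -> pd.DataFrame:
    """Label each spot by tissue compartment.

    A spot whose center falls inside any cell mask is ``aortic_cell`` (its
    ``parent_cell`` is that label); otherwise ``extra_aortic`` when outside
    the aorta mask, else ``unassigned`` (inside the vessel but in no cell).
    A spot exactly on a mask border counts as inside (the mask voxel rule is
    inclusive).
    """
    out = spots.copy()
    iz, iy, ix = _spot_voxels(spots, cells.spacing_um, cells.labels.shape)
    lab = cells.labels[iz, iy, ix]
    in_aorta = cells.aorta_mask[iz, iy, ix]
    compartment = np.where(lab > 0, "aortic_cell", np.where(in_aorta, "unassigned", "extra_aortic"))
    out["compartment"] = compartment
    out["parent_cell"] = np.where(lab > 0, lab, 0)
    return out


def count_spots_per_cell(
    spots: pd.DataFrame,
    cells: CellSurfaceSet,
    cell_class: str | None = "hemogenic_EHT",
) -> tuple[pd.Series, pd.Series]:
    """Spots per cell and the histogram of cells by spot count (bins 0..4+).

    ``spots`` must be classified (have ``parent_cell``); counts cover every
    cell of ``cell_class`` (all cells when None), including zero-spot cells.
    """
    if "parent_cell" not in spots.columns:
        raise ConfigurationError("spots must be classified first (missing parent_cell)")
    ids = [
        cid
        for cid, c in cells.classes.items()
        if cell_class is None or c == cell_class
    ]
    counts = pd.Series(0, index=pd.Index(ids, name="cell_id"), name="n_spots")
    observed = spots.loc[spots["parent_cell"].isin(ids), "parent_cell"].value_counts()
    counts.loc[observed.index] = observed
    binned = pd.cut(
        counts,
        bins=[-0.5, 0.5, 1.5, 2.5, 3.5, np.inf],
        labels=["0", "1", "2", "3", "4+"],
    )
    hist = binned.value_counts().reindex(["0", "1", "2", "3", "4+"]).fillna(0).astype(int)
    hist.name = "n_cells"
    return counts, hist


def distance_profile(
    spots: pd.DataFrame,
    cells: CellSurfaceSet,
    target_class: str = "hemogenic_EHT",
    include_compartments: tuple[str, ...] = ("aortic_cell", "unassigned"),
    grid_um: np.ndarray | None = None,
) -> DistanceProfile:
    """Distances from spots to the nearest target-cell surface, with d50/d75.

    Distance is the Euclidean distance transform of the complement of the
    target mask (0 inside a target cell), sampled at each spot's voxel.
    d50/d75 are the lower empirical quantiles: the smallest observed
    distance d with F(d) >= 0.5 / 0.75 (no interpolation).  By default,
    extra-aortic spots are excluded, matching curated aortic-tissue spots.
    """
    target = cells.class_mask(target_class)
    if not target.any():
        raise ConfigurationError(f"no cells of class {target_class!r}")
    sel = spots
    if include_compartments is not None and "compartment" in spots.columns:
        sel = spots[spots["compartment"].isin(include_compartments)]
    if len(sel) == 0:
        raise ConfigurationError("no spots to profile")
    edt = ndi.distance_transform_edt(~target, sampling=cells.spacing_um)
    iz, iy, ix = _spot_voxels(sel, cells.spacing_um, target.shape)
    d = edt[iz, iy, ix]

    d_sorted = np.sort(d)
    n = d_sorted.size
    d50 = float(d_sorted[int(np.ceil(0.5 * n)) - 1])
    d75 = float(d_sorted[int(np.ceil(0.75 * n)) - 1])

    if grid_um is None:
        grid_um = np.arange(0.0, 50.0 + 1e-9, 0.5)
    cumulative = np.searchsorted(d_sorted, grid_um, side="right") / n
    return DistanceProfile(
        distances_um=d,
        grid_um=np.asarray(grid_um, dtype=float),
        cumulative=cumulative,
        d50=d50,
        d75=d75,
    )


def summarize_scene(segments: pd.DataFrame) -> dict:
    """Cross-segment correlations of cell count against spot statistics.

    ``segments`` has one row per aortic segment with columns ``n_cells``
    (hemogenic/EHT cell count) and any of ``n_spots``, ``d50``, ``d75``.
    Returns Pearson R with its t-test p and the regression line per
    covariate; constant covariates are reported as not-applicable.
    """
    if "n_cells" not in segments.columns:
        raise ConfigurationError("segments table needs an n_cells column")
    if len(segments) < 3:
        raise ConfigurationError("need >= 3 segments for correlation")
    out = {}
    x = segments["n_cells"].to_numpy(dtype=float)
    for cov in ("n_spots", "d50", "d75"):
        if cov not in segments.columns:
            continue
        y = segments[cov].to_numpy(dtype=float)
        res = stats_core.pearson(x, y)
        entry = {"r": res.r, "pvalue": res.pvalue, "n": res.n, "applicable": res.applicable}
        if res.applicable:
            slope, intercept = np.polyfit(x, y, 1)
            entry["slope"] = float(slope)
            entry["intercept"] = float(intercept)
        out[cov] = entry
    return out
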