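"""Cell morphometry and rule-based typing on 2D wall cartographies.

Cells arrive as closed polygons in cartography coordinates (X = axial
position along the blood-flow axis, Y = perimeter arc length, both µm).
Descriptors follow the best-fitting-ellipse convention: the equivalent
ellipse sharing the polygon's second central moments; elongation is the
ratio of its major to minor diameter (1 for a non-elongated object) and
orientation the angle of the major axis to the flow axis, folded into
[0, 180).  Typing mirrors the morphological vocabulary of aortic-floor
hematopoiesis: elongated floor cells with a thick nucleus are hemogenic,
floor cells with luminal-membrane inward bending are EHT pol+, rounded
floor cells with a short antero-posterior axis are EHT pol-, roof cells
(or cells with a flat nucleus) are endothelial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.validation import explain_validity
from skimage.segmentation import watershed

from ehtkit.exceptions import ConfigurationError, GeometryError, PavingError

__all__ = [
    "CellROI",
    "Morphometrics",
    "SectorConfig",
    "ClassifierConfig",
    "compute_morphometrics",
    "refine_paving",
    "count_neighbors",
    "classify_cell_type",
    "summarize_segment",
]

CELL_TYPES = ("endothelial", "hemogenic", "EHT_pol_plus", "EHT_pol_minus", "uncharacterized")
REGIONS = ("floor", "lateral", "roof")


@dataclass
class CellROI:
    """A cell outline on the cartography with its labels."""

    polygon: Polygon
    id: int
    cell_type: str = "uncharacterized"
    region: str = "floor"
    nucleus_thick: bool | None = None
    flags: dict = field(default_factory=dict)
    low_confidence: bool = False

    def __post_init__(self):
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if self.cell_type not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell type {self.cell_type!r}")
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class Morphometrics:
    area_um2: float
    elongation: float  # major/minor equivalent-ellipse diameter ratio, >= 1
    orientation_deg: float  # major-axis angle to the flow (X) axis, [0, 180)
    major_length_um: float  # extent along the major axis
    neighbor_count: int | None = None


@dataclass(frozen=True)
class SectorConfig:
    """Angular sectors assigning regions from the arc position of the center.

    Angle 0 is the ventral-most (floor) line; floor spans +- floor_halfwidth
    degrees around it, roof +- roof_halfwidth around 180, lateral the rest.
    """

    floor_halfwidth_deg: float = 60.0
    roof_halfwidth_deg: float = 60.0

    def region_of_angle(self, angle_deg: float) -> str:
        a = angle_deg % 360.0
        dist_floor = min(a, 360.0 - a)
        if dist_floor <= self.floor_halfwidth_deg:
            return "floor"
        if abs(a - 180.0) <= self.roof_halfwidth_deg:
            return "roof"
        return "lateral"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the rule cascade (the source study classifies by eye)."""

    elongation_min: float = 2.0  # "elongated" along the flow axis
    short_axial_um: float = 10.0  # "clear shortening of the antero-posterior axis"
    sectors: SectorConfig = field(default_factory=SectorConfig)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def _polygon_second_moments(poly: Polygon) -> tuple[float, np.ndarray]:
    """Area and central second-moment (covariance) matrix of a filled polygon.

    Closed-form Green's-theorem sums over the exterior ring; exact, no
    rasterization.  Holes are not supported (cell outlines are simple).
    """
    x, y = np.asarray(poly.exterior.coords.xy)
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    cross = x0 * y1 - x1 * y0
    area = float(cross.sum() / 2.0)
    if area == 0:
        raise GeometryError("degenerate polygon with zero area")
    cx = float(((x0 + x1) * cross).sum() / (6.0 * area))
    cy = float(((y0 + y1) * cross).sum() / (6.0 * area))
    # second moments about origin
    ixx = float(((x0**2 + x0 * x1 + x1**2) * cross).sum() / 12.0)
    iyy = float(((y0**2 + y0 * y1 + y1**2) * cross).sum() / 12.0)
    ixy = float(((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / 24.0)
    # central, normalized by area -> covariance of the uniform lamina
    cov = np.array(
        [
            [ixx / area - cx**2, ixy / area - cx * cy],
            [ixy / area - cx * cy, iyy / area - cy**2],
        ]
    )
    if area < 0:  # ring orientation; covariance is orientation-independent
        area = -area
    return area, cov


def compute_morphometrics(roi: CellROI | Polygon) -> Morphometrics:
    """Area, equivalent-ellipse elongation/orientation and major-axis length.

    The equivalent ellipse shares the polygon's exact second central
    moments; its diameters are 4 sqrt(eigenvalue).  ``major_length_um`` is
    the extent of the polygon projected onto the major-axis direction
    (length "in the longest axis").
    """
    if isinstance(roi, CellROI):
        poly = roi.polygon
    elif isinstance(roi, Polygon):
        poly = roi
    else:
        poly = Polygon(roi)
    if poly.is_empty or poly.area == 0:
        raise GeometryError("degenerate polygon with zero area")
    if not poly.is_valid:
        raise GeometryError(f"invalid polygon: {explain_validity(poly)}")
    area, cov = _polygon_second_moments(poly)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    if lam_minor <= 0:
        raise GeometryError("degenerate polygon: zero minor axis")
    elongation = float(np.sqrt(lam_major / lam_minor))
    major_dir = evecs[:, 1]  # (x, y) components
    orientation = float(np.degrees(np.arctan2(major_dir[1], major_dir[0])) % 180.0)
    coords = np.asarray(poly.exterior.coords)
    proj = coords @ major_dir
    major_length = float(proj.max() - proj.min())
    return Morphometrics(
        area_um2=area,
        elongation=elongation,
        orientation_deg=orientation,
        major_length_um=major_length,
    )


# ---------------------------------------------------------------------------
# paving refinement
# ---------------------------------------------------------------------------

def _carto_image_and_spacing(carto):
    """Accept a Cartography object or an (image, (dy, dx)) pair."""
    if hasattr(carto, "image") and hasattr(carto, "pixel_size_um"):
        return np.asarray(carto.image, dtype=float), carto.pixel_size_um
    image, spacing = carto
    return np.asarray(image, dtype=float), tuple(spacing)


def refine_paving(
    carto,
    seeds: list[Polygon],
    overlap_tolerance: float = 0.05,
    dilate_um: float = 4.0,
) -> list[CellROI]:
    """Refine seed polygons toward the junction signal into a joint paving.

    Seeds are rasterized as markers and expanded by a marker-based watershed
    on the junction-intensity image (boundaries are bright, so ridges of the
    flooding land on cell borders), restricted to the union of the seeds
    dilated by ``dilate_um``.  The result covers the seeded area jointly:
    refined ROIs touch without overlapping.

    ``carto`` is a Cartography or an ``(image, (dy_um, dx_um))`` pair with Y
    (rows) the arc axis and X (columns) the axial axis.

    Raises
    ------
    PavingError
        If two seeds overlap by more than ``overlap_tolerance`` of the
        smaller seed's area.
    GeometryError
        If a seed lies outside the cartography extent.
    """
    image, (dy, dx) = _carto_image_and_spacing(carto)
    ny, nx = image.shape
    extent_y, extent_x = ny * dy, nx * dx

    for i, a in enumerate(seeds):
        minx, miny, maxx, maxy = a.bounds
        if minx < -dx or miny < -dy or maxx > extent_x + dx or maxy > extent_y + dy:
            raise GeometryError(f"seed {i} outside cartography extent")
    offenders = []
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            inter = seeds[i].intersection(seeds[j]).area
            if inter > overlap_tolerance * min(seeds[i].area, seeds[j].area):
                offenders.append((i, j))
    if offenders:
        raise PavingError(f"seeds overlap beyond tolerance: {offenders}", offending_ids=offenders)

    # rasterize seeds as markers (row = Y/dy, col = X/dx)
    from skimage.draw import polygon as draw_polygon

    markers = np.zeros((ny, nx), dtype=np.int32)
    for i, s in enumerate(seeds, start=1):
        xs, ys = np.asarray(s.exterior.coords.xy)
        rr, cc = draw_polygon(ys / dy, xs / dx, shape=(ny, nx))
        markers[rr, cc] = i

    if len(seeds) == 1:
        labels = markers
    else:
        from scipy import ndimage as ndi

        mask = markers > 0
        n_dil = max(1, int(round(dilate_um / min(dy, dx))))
        mask = ndi.binary_dilation(mask, iterations=n_dil)
        # junctions are bright: flooding from the seeds meets at intensity
        # crests, which is exactly the cell-border signal
        labels = watershed(image, markers=markers, mask=mask)

    from scipy import ndimage as ndi

    rois = []
    for i, seed in enumerate(seeds, start=1):
        mask = labels == i
        # drop 1-px ridge strips the flooding may have grabbed along borders
        opened = ndi.binary_opening(mask)
        if opened.any():
            comps, n = ndi.label(opened)
            if n > 1:
                sizes = np.bincount(comps.ravel())
                opened = comps == (1 + np.argmax(sizes[1:]))
            mask = opened
        poly = _label_to_polygon(mask, dy, dx)
        if poly is None:
            poly = seed
        rois.append(CellROI(polygon=poly, id=i - 1))
    return rois


def _label_to_polygon(mask: np.ndarray, dy: float, dx: float) -> Polygon | None:
    """Largest outer contour of a binary mask as a polygon in µm coordinates."""
    from skimage.measure import find_contours

    if not mask.any():
        return None
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    # contour is (row, col) on the padded grid; pixel r sits at r * d
    ys = (contour[:, 0] - 1) * dy
    xs = (contour[:, 1] - 1) * dx
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def count_neighbors(rois: list[CellROI], eps_um: float = 1e-9) -> dict[int, int]:
    """Neighbor counts: pairs sharing boundary of positive length.

    Vertex-only contact does not count.  If the input is not a strict paving
    (polygons overlap), a warning is emitted and adjacency falls back to a
    distance-eps test on the boundaries with the same positive-shared-length
    rule.
    """
    n = len(rois)
    counts = {r.id: 0 for r in rois}
    polys = [r.polygon for r in rois]
    overlapping = False
    for i in range(n):
        for j in range(i + 1, n):
            inter = polys[i].intersection(polys[j])
            if inter.is_empty:
                continue
            if inter.area > max(eps_um, 1e-9):
                overlapping = True
            if _shared_length(inter) > eps_um or inter.area > eps_um:
                counts[rois[i].id] += 1
                counts[rois[j].id] += 1
    if overlapping:
        warnings.warn("input is not a strict paving; overlap-based adjacency used")
    return counts


def _shared_length(geom) -> float:
    if geom.is_empty:
        return 0.0
    if geom.geom_type in ("LineString", "MultiLineString", "LinearRing"):
        return geom.length
    if geom.geom_type == "GeometryCollection":
        return sum(_shared_length(g) for g in geom.geoms)
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom.length  # degenerate overlap: boundary length as proxy
    return 0.0  # points


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_cell_type(
    roi: CellROI,
    morph: Morphometrics,
    perimeter_um: float,
    flags: dict | None = None,
    config: ClassifierConfig | None = None,
) -> CellROI:
    """Assign region (from the geometric center's arc position) and type.

    Rule cascade: floor + inward bending -> EHT pol+; floor + outward round
    + short antero-posterior length -> EHT pol-; floor/lateral + elongation
    >= threshold + thick nucleus -> hemogenic; roof, or a flat nucleus ->
    endothelial; anything else -> uncharacterized.  Shape flags
    (``inward_bending``, ``outward_round``) come from 3D morphology and are
    inputs, not inferred from the 2D outline; with flags missing the cell is
    classified from the remaining rules and marked low-confidence.

    Returns a new CellROI with type/region set (pure function of its inputs).
    """
    config = config or ClassifierConfig()
    flags = dict(roi.flags or {}) | dict(flags or {})
    center_y = roi.polygon.centroid.y
    angle = (center_y / perimeter_um) * 360.0
    region = config.sectors.region_of_angle(angle)

    nucleus_thick = flags.get("nucleus_thick", roi.nucleus_thick)
    inward = flags.get("inward_bending")
    outward = flags.get("outward_round")
    low_confidence = inward is None or outward is None or nucleus_thick is None

    if region == "roof":
        cell_type = "endothelial"
    elif region == "floor" and inward:
        cell_type = "EHT_pol_plus"
    elif region == "floor" and outward and morph.major_length_um < config.short_axial_um:
        cell_type = "EHT_pol_minus"
    elif (
        region in ("floor", "lateral")
        and morph.elongation >= config.elongation_min
        and bool(nucleus_thick)
    ):
        cell_type = "hemogenic"
    elif nucleus_thick is False:
        cell_type = "endothelial"
    else:
        cell_type = "uncharacterized"

    return CellROI(
        polygon=roi.polygon,
        id=roi.id,
        cell_type=cell_type,
        region=region,
        nucleus_thick=nucleus_thick,
        flags=flags,
        low_confidence=low_confidence,
    )


def summarize_segment(rois: list[CellROI], uncharacterized_as_hemogenic: bool = False):
    """Counts per (type, region) plus the per-cell descriptor table.

    With ``uncharacterized_as_hemogenic`` the uncharacterized emerging cells
    are folded into the hemogenic count, as done in whole-aorta numerations.
    Totals are conserved either way.
    """
    import pandas as pd

    records = []
    for r in rois:
        m = compute_morphometrics(r)
        ct = r.cell_type
        if uncharacterized_as_hemogenic and ct == "uncharacterized":
            ct = "hemogenic"
        records.append(
            {
                "id": r.id,
                "cell_type": ct,
                "region": r.region,
                "area_um2": m.area_um2,
                "elongation": m.elongation,
                "orientation_deg": m.orientation_deg,
                "major_length_um": m.major_length_um,
            }
        )
    cells = pd.DataFrame(records)
    if cells.empty:
        counts = pd.DataFrame(0, index=list(CELL_TYPES), columns=list(REGIONS))
    else:
        counts = (
            cells.pivot_table(index="cell_type", columns="region", values="id", aggfunc="count")
            .reindex(index=list(CELL_TYPES), columns=list(REGIONS))
            .fillna(0)
            .astype(int)
        )
    return counts, cells
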