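"""Morphometric descriptors, paving refinement, adjacency, classification."""

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Polygon

from ehtkit import morphometry as mm
from ehtkit import unwrap as uw
from ehtkit.exceptions import GeometryError, PavingError
from ehtkit.synthetic import TubePhantomConfig, make_tube_phantom


def _disk(r=10.0, n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([r * np.cos(t), r * np.sin(t)]))


def _rect(lx=40.0, ly=10.0):
    return Polygon([(0, 0), (lx, 0), (lx, ly), (0, ly)])


class TestComputeMorphometrics:
    def test_disk_is_round(self):
        m = mm.compute_morphometrics(_disk(10.0))
        assert m.elongation == pytest.approx(1.0, abs=0.02)
        assert m.area_um2 == pytest.approx(100 * np.pi, rel=0.02)

    def test_rectangle_moment_ellipse(self):
        m = mm.compute_morphometrics(_rect(40, 10))
        assert m.elongation == pytest.approx(4.0, rel=0.02)
        assert m.orientation_deg == pytest.approx(0.0, abs=1.0)
        assert m.major_length_um == pytest.approx(40.0, rel=0.02)

    @pytest.mark.parametrize("angle", [10, 30, 75, 120, 179])
    def test_rotation_equivariance_of_orientation(self, angle):
        rot = affinity.rotate(_rect(40, 10), angle, origin="centroid")
        m = mm.compute_morphometrics(rot)
        assert m.orientation_deg == pytest.approx(angle % 180, abs=1.0)
        assert m.elongation == pytest.approx(4.0, rel=0.02)

    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_scale_invariance_of_elongation(self, scale):
        base = mm.compute_morphometrics(_rect(25, 8)).elongation
        scaled = affinity.scale(_rect(25, 8), scale, scale)
        assert mm.compute_morphometrics(scaled).elongation == pytest.approx(base, rel=1e-9)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises((GeometryError, Exception)):
            mm.compute_morphometrics(Polygon([(0, 0), (1, 0), (2, 0)]))


class TestCountNeighbors:
    def test_three_mutually_adjacent(self):
        # three sectors around a common center: each touches the other two
        rois = [
            mm.CellROI(Polygon([(0, 0), (2, 0), (1, 1)]), id=0),
            mm.CellROI(Polygon([(2, 0), (2, 2), (1, 1)]), id=1),
            mm.CellROI(Polygon([(0, 0), (1, 1), (2, 2), (0, 2)]), id=2),
        ]
        counts = mm.count_neighbors(rois)
        assert counts == {0: 2, 1: 2, 2: 2}

    def test_grid_corner_contact_excluded(self):
        sq = lambda x, y: Polygon([(x, y), (x + 1, y), (x + 1, y + 1), (x, y + 1)])
        rois = [mm.CellROI(sq(i, j), id=2 * i + j) for i in (0, 1) for j in (0, 1)]
        counts = mm.count_neighbors(rois)
        assert all(c == 2 for c in counts.values())  # diagonals do not count

    def test_matches_buffered_overlap_oracle_on_voronoi(self):
        from scipy.spatial import Voronoi

        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 10, size=(15, 2))
        mirrored = np.concatenate(
            [pts]
            + [pts * [1, -1], pts * [-1, 1], pts * [1, -1] + [0, 20], pts * [-1, 1] + [20, 0]]
        )
        vor = Voronoi(mirrored)
        polys = []
        for i in range(15):
            region = vor.regions[vor.point_region[i]]
            polys.append(Polygon(vor.vertices[region]))
        rois = [mm.CellROI(p, id=i) for i, p in enumerate(polys)]
        counts = mm.count_neighbors(rois)
        # a shared edge of length L yields buffered overlap ~ 2 eps L; a
        # vertex-only contact yields ~ pi eps^2 -- the threshold separates them
        eps = 1e-6
        for i in range(15):
            oracle = sum(
                1
                for j in range(15)
                if j != i
                and polys[i].buffer(eps).intersection(polys[j].buffer(eps)).area > 100 * eps**2
            )
            assert counts[i] == oracle


class TestRefinePaving:
    def test_phantom_seeds_recover_truth(self, small_tube, small_tube_carto):
        _, truth = small_tube
        carto = small_tube_carto
        pairs = [(i, truth.polygons[i].buffer(-1.0)) for i in truth.cells["id"]]
        pairs = [(i, s) for i, s in pairs if not s.is_empty and s.geom_type == "Polygon"]
        img = np.nan_to_num(carto.image, nan=0.0)
        rois = mm.refine_paving((img, carto.pixel_size_um), [s for _, s in pairs])
        jacc = [
            rois[k].polygon.intersection(truth.polygons[i]).area
            / rois[k].polygon.union(truth.polygons[i]).area
            for k, (i, _) in enumerate(pairs)
        ]
        assert min(jacc) >= 0.9

    def test_single_seed_roughly_unchanged(self):
        img = np.zeros((50, 50), dtype=float)
        seed = Polygon([(5, 5), (15, 5), (15, 15), (5, 15)])
        rois = mm.refine_paving((img, (1.0, 1.0)), [seed])
        inter = rois[0].polygon.intersection(seed).area
        assert inter / seed.area > 0.85

    def test_overlapping_seeds_rejected(self):
        img = np.zeros((40, 40), dtype=float)
        a = Polygon([(5, 5), (20, 5), (20, 20), (5, 20)])
        b = Polygon([(10, 10), (25, 10), (25, 25), (10, 25)])
        with pytest.raises(PavingError):
            mm.refine_paving((img, (1.0, 1.0)), [a, b])

    def test_seed_outside_extent_rejected(self):
        img = np.zeros((20, 20), dtype=float)
        with pytest.raises(GeometryError):
            mm.refine_paving((img, (1.0, 1.0)), [Polygon([(30, 30), (40, 30), (40, 40)])])

    def test_refined_rois_form_a_paving(self, small_tube, small_tube_carto):
        _, truth = small_tube
        carto = small_tube_carto
        pairs = [(i, truth.polygons[i].buffer(-1.0)) for i in truth.cells["id"]]
        pairs = [(i, s) for i, s in pairs if not s.is_empty and s.geom_type == "Polygon"]
        img = np.nan_to_num(carto.image, nan=0.0)
        rois = mm.refine_paving((img, carto.pixel_size_um), [s for _, s in pairs])
        total_seed = sum(s.area for _, s in pairs)
        total_refined = sum(r.polygon.area for r in rois)
        assert total_refined >= total_seed  # dilation never shrinks coverage
        overlap = sum(
            rois[i].polygon.intersection(rois[j].polygon).area
            for i in range(len(rois))
            for j in range(i + 1, len(rois))
        )
        assert overlap < 0.02 * total_refined


class TestClassification:
    def _roi(self, centroid_s, perimeter, lx=20.0, ly=6.0):
        poly = Polygon(
            [
                (0, centroid_s - ly / 2),
                (lx, centroid_s - ly / 2),
                (lx, centroid_s + ly / 2),
                (0, centroid_s + ly / 2),
            ]
        )
        return mm.CellROI(poly, id=0)

    def test_roof_center_is_endothelial_regardless_of_elongation(self):
        perimeter = 100.0
        roi = self._roi(50.0, perimeter)  # 180 degrees = roof
        morph = mm.compute_morphometrics(roi)
        out = mm.classify_cell_type(
            roi, morph, perimeter,
            flags={"inward_bending": False, "outward_round": False, "nucleus_thick": True},
        )
        assert out.region == "roof" and out.cell_type == "endothelial"

    def test_floor_inward_bending_is_pol_plus(self):
        roi = self._roi(2.0, 100.0)
        morph = mm.compute_morphometrics(roi)
        out = mm.classify_cell_type(
            roi, morph, 100.0,
            flags={"inward_bending": True, "outward_round": False, "nucleus_thick": True},
        )
        assert out.cell_type == "EHT_pol_plus" and out.region == "floor"

    def test_floor_round_short_is_pol_minus(self):
        roi = self._roi(2.0, 100.0, lx=7.0, ly=6.0)
        morph = mm.compute_morphometrics(roi)
        out = mm.classify_cell_type(
            roi, morph, 100.0,
            flags={"inward_bending": False, "outward_round": True, "nucleus_thick": True},
        )
        assert out.cell_type == "EHT_pol_minus"

    def test_missing_flags_low_confidence(self):
        roi = self._roi(2.0, 100.0)
        morph = mm.compute_morphometrics(roi)
        out = mm.classify_cell_type(roi, morph, 100.0, flags={"nucleus_thick": True})
        assert out.low_confidence

    def test_pure_function_of_inputs(self):
        roi = self._roi(2.0, 100.0)
        morph = mm.compute_morphometrics(roi)
        flags = {"inward_bending": False, "outward_round": False, "nucleus_thick": True}
        a = mm.classify_cell_type(roi, morph, 100.0, flags=flags)
        b = mm.classify_cell_type(roi, morph, 100.0, flags=flags)
        assert (a.cell_type, a.region) == (b.cell_type, b.region)

    def test_phantom_ledger_agreement(self, small_tube, small_tube_carto):
        """Full chain: refine noisy seeds, measure, classify, compare to truth."""
        _, truth = small_tube
        carto = small_tube_carto
        perimeter = truth.perimeter_um
        cells = truth.cells.set_index("id")
        agree = total = 0
        for cid, poly in truth.polygons.items():
            row = cells.loc[cid]
            roi = mm.CellROI(poly, id=cid)
            morph = mm.compute_morphometrics(roi)
            out = mm.classify_cell_type(
                roi, morph, perimeter,
                flags={
                    "inward_bending": bool(row["inward_bending"]),
                    "outward_round": bool(row["outward_round"]),
                    "nucleus_thick": bool(row["nucleus_thick"]),
                },
            )
            total += 1
            agree += out.cell_type == row["cell_type"]
        assert agree / total >= 0.95


class TestSummarize:
    def test_totals_conserved(self, small_tube):
        _, truth = small_tube
        rois = [
            mm.CellROI(truth.polygons[i], id=i, cell_type=t, region=r)
            for i, t, r in zip(truth.cells["id"], truth.cells["cell_type"], truth.cells["region"])
        ]
        counts, cells = mm.summarize_segment(rois)
        assert counts.to_numpy().sum() == len(rois)
        hemo_truth = (truth.cells["cell_type"] == "hemogenic").sum()
        assert counts.loc["hemogenic"].sum() == hemo_truth

    def test_empty_input_all_zero(self):
        counts, cells = mm.summarize_segment([])
        assert (counts.to_numpy() == 0).all()

    def test_uncharacterized_fold_into_hemogenic(self):
        p = Polygon([(0, 0), (10, 0), (10, 5), (0, 5)])
        rois = [mm.CellROI(p, id=0, cell_type="uncharacterized", region="floor")]
        counts, _ = mm.summarize_segment(rois, uncharacterized_as_hemogenic=True)
        assert counts.loc["hemogenic", "floor"] == 1
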