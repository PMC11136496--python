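"""Rolling-median transient removal, preprocessing, segmentation, counting."""

import numpy as np
import pytest

from ehtkit import counter as cnt
from ehtkit.exceptions import ConfigurationError, WindowError
from ehtkit.synthetic import FlowTimelapseConfig, make_flow_timelapse


def _blob_stack(shape=(48, 40, 40)):
    zg, yg, xg = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")

    def add(img, c, sigma=2.0, amp=100.0, zspan=None):
        disk = amp * np.exp(-(((yg[0] - c[1]) ** 2 + (xg[0] - c[2]) ** 2)) / (2 * sigma**2))
        if zspan is None:
            img[int(c[0])] += disk
        else:
            img[int(c[0]) : int(c[0]) + zspan] += disk
        return img

    return np.zeros(shape), add


class TestTemporalMedian:
    def test_single_plane_transient_suppressed(self):
        img, add = _blob_stack()
        img = add(img, (24, 20, 20))  # one plane only
        out = cnt.temporal_median(img, 20, "replace")
        assert out[24, 20, 20] < 0.10 * img[24, 20, 20]

    def test_full_window_object_retained(self):
        img, add = _blob_stack()
        img = add(img, (14, 20, 20), zspan=20)
        out = cnt.temporal_median(img, 20, "replace")
        core = 14 + 10
        assert out[core, 20, 20] >= 0.95 * img[core, 20, 20]

    def test_ledger_phantom_transients_removed_persistents_kept(self):
        cfg = FlowTimelapseConfig(n_transient=5, n_persistent_double=5, seed=31)
        stack, ledger = make_flow_timelapse(cfg)
        green = stack.channel(0)
        out = cnt.temporal_median(green, cfg.median_window, "replace")
        for _, r in ledger.iterrows():
            y, x = int(r["centroid_y_um"]), int(r["centroid_x_um"])
            if r["object_class"] == "transient":
                z = int(r["z0"])
                assert out[z, y, x] < 0.10 * green[z, y, x]
            else:
                z = int(r["z0"] + r["z_span"] // 2)
                assert out[z, y, x] > 0.5 * green[z, y, x]

    def test_replace_idempotent_on_thick_objects(self):
        # odd window: the median is a single order statistic, so a flat
        # object spanning more than the window is reproduced exactly
        img, add = _blob_stack()
        img = add(img, (10, 14, 14), zspan=24)
        img = add(img, (20, 28, 28), zspan=22)
        once = cnt.temporal_median(img, 21, "replace")
        twice = cnt.temporal_median(once, 21, "replace")
        assert np.allclose(once, twice, atol=1e-6)

    def test_subtract_mode_removes_persistent_component(self):
        img, add = _blob_stack()
        img = add(img, (0, 20, 20), zspan=48)  # spans the whole stack
        out = cnt.temporal_median(img, 20, "subtract")
        assert out.max() == pytest.approx(0.0, abs=1e-9)

    def test_window_larger_than_depth_rejected(self):
        with pytest.raises(WindowError):
            cnt.temporal_median(np.zeros((10, 5, 5)), 20)


class TestPreprocess:
    def test_all_zero_passthrough(self):
        out = cnt.preprocess(np.zeros((4, 32, 32)))
        assert np.allclose(out, 0.0)

    def test_constant_stack_zero_after_background(self):
        out = cnt.preprocess(np.full((4, 32, 32), 7.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_snr_improves_on_blob(self):
        rng = np.random.default_rng(5)
        img, add = _blob_stack((8, 48, 48))
        img = add(img, (2, 24, 24), sigma=2.0, zspan=5)
        noisy = np.clip(img + 20.0 + rng.normal(0, 5, img.shape), 0, None)
        out = cnt.preprocess(noisy, cnt.PreprocessConfig(gaussian_sigma=(1, 1, 1)))
        snr_before = noisy[4, 24, 24] / noisy[:, :8, :8].mean()
        snr_after = out[4, 24, 24] / max(out[:, :8, :8].mean(), 1e-9)
        assert snr_after > snr_before


class TestSegmentObjects:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        img, add = _blob_stack((40, 40, 40))
        img = add(img, (18, 10, 20), sigma=2.0, zspan=6)
        img = add(img, (18, 30, 20), sigma=2.0, zspan=6)
        noisy = np.clip(img + rng.normal(0, 10, img.shape), 0, None)
        labels, tab = cnt.segment_objects(
            noisy, cnt.SegmentConfig(tophat_radius_px=6, threshold=20.0)
        )
        assert len(tab) == 2
        ys = sorted(tab["centroid_y_um"])
        assert abs(ys[0] - 10.0) < 1.0 and abs(ys[1] - 30.0) < 1.0

    def test_pure_noise_no_objects(self):
        rng = np.random.default_rng(2)
        noise = np.clip(rng.normal(0, 10, (40, 40, 40)), 0, None)
        _, tab = cnt.segment_objects(noise, cnt.SegmentConfig(tophat_radius_px=6, threshold=30.0))
        assert len(tab) == 0

    def test_touching_blobs_split_by_watershed(self):
        rng = np.random.default_rng(3)
        shape = (40, 40, 40)
        zg, yg, xg = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")

        def ball3(c):
            return 100 * np.exp(
                -((zg - c[0]) ** 2 + (yg - c[1]) ** 2 + (xg - c[2]) ** 2) / (2 * 3.0**2)
            )

        img = np.clip(ball3((20, 16, 20)) + ball3((20, 24, 20)) + rng.normal(0, 10, shape), 0, None)
        _, tab = cnt.segment_objects(img, cnt.SegmentConfig(tophat_radius_px=6, threshold=20.0))
        assert len(tab) == 2

    def test_structuring_element_too_large(self):
        with pytest.raises(ConfigurationError):
            cnt.segment_objects(np.zeros((5, 5, 5)), cnt.SegmentConfig(tophat_radius_px=10))


class TestMeasureAndClassify:
    def _measured(self, seed=41):
        cfg = FlowTimelapseConfig(
            n_transient=3, n_persistent_double=4, n_persistent_single=6, snr=10, seed=seed
        )
        stack, ledger = make_flow_timelapse(cfg)
        green = cnt.temporal_median(stack.channel(0), cfg.median_window, "replace")
        labels, _ = cnt.segment_objects(
            green, cnt.SegmentConfig(tophat_radius_px=5, threshold=20.0)
        )
        bg = np.zeros(green.shape, bool)
        bg[:, :6, :6] = True
        table = cnt.measure_objects(labels, stack, background_roi=bg)
        return table, ledger

    def test_painted_totals_recovered(self):
        from scipy import ndimage as ndi

        cfg = FlowTimelapseConfig(n_transient=0, n_persistent_double=4, seed=43)
        stack, ledger = make_flow_timelapse(cfg)
        labels, _ = ndi.label(stack.channel(0) > 2.0)
        bg = np.zeros(stack.shape_zyx, bool)
        bg[:, :6, :6] = True
        table = cnt.measure_objects(labels, stack, background_roi=bg)
        # noise-free: captured total within a few percent of painted total
        # (only the faint Gaussian skirt below threshold is lost)
        got = np.sort(table["corrected_green"].to_numpy())
        want = np.sort(ledger["total_green"].to_numpy())
        assert len(got) == len(want)
        assert np.all(np.abs(got - want) / want < 0.05)

    def test_uniform_background_correction_algebra(self):
        labels = np.zeros((4, 8, 8), dtype=np.int32)
        labels[1:3, 2:5, 2:5] = 1
        raw = np.full((1, 4, 8, 8), 3.0)
        raw[0, 1:3, 2:5, 2:5] += 10.0
        bg = labels == 0
        table = cnt.measure_objects(labels, raw, background_roi=bg)
        v = labels.sum()
        assert table["corrected_ch0"].iloc[0] == pytest.approx(10.0 * v)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            cnt.measure_objects(np.zeros((3, 4, 4), dtype=int), np.zeros((1, 3, 5, 5)))

    def test_classification_rules_and_ledger(self):
        table, ledger = self._measured()
        out = cnt.classify_objects(table, {"green": 5000.0, "red": 5000.0})
        counts = out["object_class"].value_counts()
        assert counts.get("hemogenic", 0) == 4
        assert counts.get("hspc", 0) == 6

    def test_threshold_monotonicity(self):
        table, _ = self._measured()
        pos = []
        for thr in (1000.0, 5000.0, 50000.0):
            out = cnt.classify_objects(table, {"green": thr, "red": 5000.0})
            pos.append((out["object_class"] != "other").sum())
        assert pos[0] >= pos[1] >= pos[2]

    def test_missing_channel_threshold_rejected(self):
        table, _ = self._measured()
        with pytest.raises(ConfigurationError):
            cnt.classify_objects(table, {"green": 1.0})
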