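"""Image pipeline: registration, masking, pixel OxD, segmentation, measurement."""

import numpy as np
import pytest

from redoxtrace.imaging import (
    FilterCriteria,
    ImageStack,
    analyze_stack,
    auto_background_roi,
    expression_mask,
    filter_objects,
    measure_cells,
    normalize_bit_depth,
    pixel_oxd_map,
    register_stack,
    segment_cells,
    subtract_background,
    threshold_mask,
)
from redoxtrace.redox import OxDFlag, oxd_to_ratio


def one_channel_stack(frames, name="chlorophyll"):
    pix = np.stack([f[None] for f in frames])
    return ImageStack(pixels=pix, channel_names=(name,), frame_times=np.arange(len(frames)) * 20.0)


def textured_scene(seed=0, size=96):
    rng = np.random.default_rng(seed)
    img = rng.random((size, size)) * 0.1
    img[30:42, 40:50] += 4.0
    img[60:70, 20:28] += 3.0
    return img


class TestRegistration:
    def test_identical_frames_give_zero_offsets(self):
        img = textured_scene()
        _, offsets = register_stack(one_channel_stack([img, img, img]))
        np.testing.assert_allclose(offsets, 0.0)

    def test_integer_drift_recovered_exactly(self):
        img = textured_scene()
        drift = (3, -2)
        frames = [np.roll(np.roll(img, drift[0] * f, 0), drift[1] * f, 1) for f in range(5)]
        reg, offsets = register_stack(one_channel_stack(frames))
        expected = np.array([[-drift[0] * f, -drift[1] * f] for f in range(5)], dtype=float)
        np.testing.assert_array_equal(offsets, expected)
        # interior pixels restored exactly
        np.testing.assert_allclose(reg.pixels[-1, 0, 20:76, 20:76], img[20:76, 20:76])
        assert reg.valid_mask[40, 45] and not reg.valid_mask[0, 0]

    def test_subpixel_drift_within_half_pixel(self):
        from scipy import ndimage as ndi
        img = textured_scene(seed=1)
        frames = [img] + [ndi.shift(img, (0.4 * f, -0.4 * f), order=3, mode="wrap") for f in range(1, 5)]
        _, offsets = register_stack(one_channel_stack(frames), upsample_factor=20)
        for f in range(5):
            assert abs(offsets[f][0] + 0.4 * f) < 0.5
            assert abs(offsets[f][1] - 0.4 * f) < 0.5

    def test_boundary_warning(self):
        img = textured_scene()
        frames = [img, np.roll(img, 12, axis=0)]
        with pytest.warns(UserWarning, match="boundary"):
            register_stack(one_channel_stack(frames), max_shift=10)


class TestNormalization:
    @pytest.mark.parametrize(
        "value,depth,expected", [(65535, 16, 1.0), (51, 8, 0.2), (0, 12, 0.0)]
    )
    def test_scaling(self, value, depth, expected):
        out, _ = normalize_bit_depth(np.array([[value]], dtype=float), depth)
        assert out[0, 0] == pytest.approx(expected)

    def test_saturation_flag_and_guard(self):
        out, sat = normalize_bit_depth(np.array([[4095.0, 100.0]]), 12)
        assert sat[0, 0] and not sat[0, 1]
        with pytest.raises(ValueError):
            normalize_bit_depth(np.array([[4096.0]]), 12)
        with pytest.raises(ValueError):
            normalize_bit_depth(np.array([[1.0]]), 10)


class TestBackground:
    def test_constant_image_goes_to_zero(self):
        img = np.full((40, 40), 0.3)
        out, bg = subtract_background(img, (0, 10, 0, 10))
        assert bg == pytest.approx(0.3)
        np.testing.assert_allclose(out, 0.0)

    def test_cell_peak_reduced_by_exact_background(self):
        img = np.full((40, 40), 0.1)
        img[20:25, 20:25] += 0.7
        out, _ = subtract_background(img, (0, 10, 0, 10))
        assert out[22, 22] == pytest.approx(0.7)
        assert out[0, 30] == pytest.approx(0.0)

    def test_roi_overlapping_cells_warns(self):
        img = np.full((40, 40), 0.1)
        mask = np.zeros((40, 40), bool)
        mask[2:6, 2:6] = True
        with pytest.warns(UserWarning, match="overlaps"):
            subtract_background(img, (0, 10, 0, 10), cell_mask=mask)

    def test_invalid_roi_errors(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError):
            subtract_background(img, (0, 0, 0, 10))  # empty
        with pytest.raises(ValueError):
            subtract_background(img, (0, 30, 0, 10))  # out of bounds

    def test_auto_roi_finds_darkest_tile(self):
        img = np.full((64, 64), 0.5)
        img[32:, 32:] = 0.01
        r0, r1, c0, c1 = auto_background_roi(img, tile=32)
        assert (r0, c0) == (32, 32)


class TestMasks:
    def test_threshold_mask_extremes_and_counts(self):
        img = np.zeros((10, 10))
        img[:5] = 0.9
        assert threshold_mask(img + 1e-6, 0.95).sum() == 0
        assert threshold_mask(np.full((4, 4), 0.9), 0.5).all()
        assert threshold_mask(img, 0.5).sum() == 50
        with pytest.raises(ValueError):
            threshold_mask(img, 1.5)

    def test_expression_mask_requires_colocalization(self):
        i405 = np.array([[0.5, 0.5], [0.0, 0.5]])
        i488 = np.array([[0.5, 0.0], [0.5, 0.5]])
        m405, m488 = i405 > 0.1, i488 > 0.1
        mask = expression_mask(i405, i488, 0.1, m405, m488)
        assert mask[0, 0] and not mask[0, 1] and not mask[1, 0]

    def test_expression_mask_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        i405, i488 = rng.random((30, 30)), rng.random((30, 30))
        m405, m488 = i405 > 0.3, i488 > 0.3
        t = 0.25
        mask = expression_mask(i405, i488, t, m405, m488)
        brute = np.zeros_like(mask)
        for r in range(30):
            for c in range(30):
                brute[r, c] = m405[r, c] and m488[r, c] and i405[r, c] * i488[r, c] > t
        np.testing.assert_array_equal(mask, brute)


class TestPixelOxD:
    def test_noise_free_cell_recovers_generating_oxd(self, calib):
        true_oxd = 0.35
        r = oxd_to_ratio(true_oxd, calib)
        i488 = np.zeros((20, 20))
        i488[5:15, 5:15] = 0.4
        i405 = i488 * r
        mask = i488 > 0
        oxd, flags = pixel_oxd_map(i405, i488, calib, mask)
        assert np.nanmax(np.abs(oxd[mask] - true_oxd)) < 1e-6
        assert np.isnan(oxd[~mask]).all()
        assert (flags[~mask] == OxDFlag.INVALID).all()

    def test_leakage_inflated_pixel_excluded(self, calib):
        r_bad = oxd_to_ratio(1.0, calib) * 1.5
        i488 = np.full((4, 4), 0.5)
        i405 = i488 * r_bad
        oxd, flags = pixel_oxd_map(i405, i488, calib, np.ones((4, 4), bool))
        assert (flags == OxDFlag.EXCLUDED).all()

    def test_empty_mask_warns(self, calib):
        with pytest.warns(UserWarning, match="empty"):
            oxd, _ = pixel_oxd_map(np.ones((4, 4)), np.ones((4, 4)), calib, np.zeros((4, 4), bool))
        assert np.isnan(oxd).all()

    def test_oxd_invariant_to_common_rescaling(self, calib):
        rng = np.random.default_rng(3)
        i488 = rng.uniform(0.2, 0.6, (16, 16))
        i405 = i488 * oxd_to_ratio(0.6, calib)
        mask = np.ones((16, 16), bool)
        oxd1, _ = pixel_oxd_map(i405, i488, calib, mask)
        oxd2, _ = pixel_oxd_map(i405 * 3.7, i488 * 3.7, calib, mask)
        np.testing.assert_allclose(oxd1, oxd2, atol=1e-12)


class TestSegmentation:
    @staticmethod
    def blob(center, sigma, size=64, amp=1.0):
        yy, xx = np.mgrid[:size, :size]
        return amp * np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)))

    def test_two_separated_blobs(self):
        img = self.blob((16, 16), 4) + self.blob((48, 48), 4)
        labels = segment_cells(img, img > 0.1)
        assert labels.max() == 2

    def test_touching_blobs_split_at_saddle(self):
        img = self.blob((32, 22), 5) + self.blob((32, 42), 5)
        labels = segment_cells(img, img > 0.1, min_distance=5)
        assert labels.max() == 2
        # labels nest inside the mask
        assert not labels[~(img > 0.1)].any()

    def test_empty_mask_zero_labels(self):
        assert segment_cells(np.zeros((32, 32)), np.zeros((32, 32), bool)).max() == 0


class TestFiltering:
    def test_bounds_enforced_with_reasons(self):
        labels = np.zeros((40, 60), dtype=np.int32)
        labels[2:4, 2:4] = 1            # area 4 -> too small
        labels[10:20, 10:20] = 2        # 100 px, round -> kept
        labels[30:32, 0:59] = 3         # long thin doublet -> eccentric, too long
        crit = FilterCriteria(area_min=20, area_max=500, major_axis_max=30,
                              minor_axis_min=1.5, eccentricity_max=0.95)
        out, log = filter_objects(labels, crit)
        assert set(np.unique(out)) == {0, 2}
        assert "area_min" in log[1]
        assert "major_axis_max" in log[3] or "eccentricity_max" in log[3]

    def test_all_within_bounds_is_identity(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:15, 5:15] = 1
        labels[25:35, 25:35] = 2
        out, log = filter_objects(labels, FilterCriteria(area_min=10, area_max=200,
                                                         major_axis_max=50,
                                                         minor_axis_min=1.0,
                                                         eccentricity_max=0.99))
        np.testing.assert_array_equal(out, labels)
        assert log == {}


class TestMeasurement:
    def test_uniform_cell(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        oxd = np.full((20, 20), np.nan)
        oxd[5:15, 5:15] = 0.5
        flags = np.full((20, 20), int(OxDFlag.INVALID), dtype=np.int8)
        flags[5:15, 5:15] = int(OxDFlag.IN_RANGE)
        rec = measure_cells(labels, oxd, flags).iloc[0]
        assert rec.mean_oxd == pytest.approx(0.5)
        assert rec.n_oxd_pixels == 100
        assert rec.x == pytest.approx(9.5) and rec.y == pytest.approx(9.5)

    def test_half_and_half_mean_and_median_tie_rule(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:8, 2:8] = 1
        oxd = np.full((10, 10), np.nan)
        oxd[2:8, 2:5] = 0.2
        oxd[2:8, 5:8] = 0.8
        flags = np.where(labels > 0, int(OxDFlag.IN_RANGE), int(OxDFlag.INVALID)).astype(np.int8)
        rec = measure_cells(labels, oxd, flags).iloc[0]
        assert rec.mean_oxd == pytest.approx(0.5)
        assert rec.median_oxd in (0.2, 0.8)  # tie breaks to an observed value

    def test_excluded_pixels_do_not_contribute(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:6, 2:6] = 1
        oxd = np.full((8, 8), np.nan)
        oxd[2:6, 2:6] = 0.4
        flags = np.where(labels > 0, int(OxDFlag.IN_RANGE), int(OxDFlag.INVALID)).astype(np.int8)
        oxd[3, 3] = 1.5
        flags[3, 3] = int(OxDFlag.EXCLUDED)
        rec = measure_cells(labels, oxd, flags).iloc[0]
        assert rec.n_oxd_pixels == 15
        assert rec.mean_oxd == pytest.approx(0.4)

    def test_cell_with_no_oxd_pixels(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:6, 2:6] = 1
        oxd = np.full((8, 8), np.nan)
        flags = np.full((8, 8), int(OxDFlag.INVALID), dtype=np.int8)
        rec = measure_cells(labels, oxd, flags).iloc[0]
        assert rec.n_oxd_pixels == 0
        assert np.isnan(rec.mean_oxd)


class TestPipelineOnSimulatedStack:
    def test_detection_and_oxd_recovery(self, small_stack, default_calib):
        cfg, stack, truth = small_stack
        cells, qc = analyze_stack(stack, default_calib)
        from scipy.spatial import cKDTree
        # registration aligns all frames to frame 0, so detections are
        # compared against the frame-0 truth positions
        tr0 = truth[truth.frame == 0]
        n_matched, n_true = 0, 0
        for f in range(stack.n_frames):
            det = cells[cells.frame == f]
            n_true += len(tr0)
            if det.empty:
                continue
            tree = cKDTree(det[["x", "y"]].to_numpy())
            d, idx = tree.query(tr0[["x", "y"]].to_numpy())
            n_matched += int(np.sum(d < 2.0))
        assert n_matched / n_true >= 0.95
        # per-cell OxD close to generating OxD (frame 0)
        det0 = cells[cells.frame == 0]
        tr0 = truth[truth.frame == 0]
        tree = cKDTree(tr0[["x", "y"]].to_numpy())
        d, idx = tree.query(det0[["x", "y"]].to_numpy())
        err = np.abs(det0.median_oxd.to_numpy() - tr0.true_oxd.to_numpy()[idx])
        assert np.median(err) < 0.03

    def test_cell_free_frames_have_zero_detections(self, default_calib):
        rng = np.random.default_rng(0)
        maxv = 2**16 - 1
        pix = (np.clip(0.05 + rng.normal(0, 0.005, (3, 3, 128, 128)), 0, 1) * maxv).astype(np.uint16)
        stack = ImageStack(pixels=pix, channel_names=("i405", "i488", "chlorophyll"),
                           frame_times=np.arange(3) * 20.0)
        cells, _ = analyze_stack(stack, default_calib, register=False)
        assert len(cells) == 0


class TestStackIO:
    def test_round_trip(self, tmp_path, small_stack):
        _, stack, _ = small_stack
        stack.write(tmp_path / "s.tif")
        back = ImageStack.read(tmp_path / "s.tif")
        np.testing.assert_array_equal(back.pixels, stack.pixels)
        assert back.channel_names == stack.channel_names
        np.testing.assert_allclose(back.frame_times, stack.frame_times)

    def test_page_count_mismatch_raises(self, tmp_path, small_stack):
        import json
        _, stack, _ = small_stack
        stack.write(tmp_path / "s.tif")
        meta = json.loads((tmp_path / "s.json").read_text())
        meta["n_frames"] += 1
        (tmp_path / "s.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="page count"):
            ImageStack.read(tmp_path / "s.tif")

    def test_single_frame_shape(self, tmp_path):
        pix = np.zeros((1, 2, 16, 16), dtype=np.uint16)
        stack = ImageStack(pixels=pix, channel_names=("i405", "i488"), frame_times=[0.0])
        stack.write(tmp_path / "one.tif")
        back = ImageStack.read(tmp_path / "one.tif")
        assert back.pixels.shape == (1, 2, 16, 16)
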