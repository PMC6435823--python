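"""Detection chain: preprocessing, maxima, segmentation, measurement, mask transfer."""

import numpy as np
import pytest

from azquant import puncta as pk
from azquant import synthetic as syn
from azquant.validation import detection_metrics

CONST_BG = {"method": "constant"}


def _one_spot(level=1000.0, x=20.0, y=30.0, field=(64, 64), sigma=1.5):
    m = syn.AZMap(
        az_id=np.array([0]), x=np.array([x]), y=np.array([y]),
        true_level=np.array([level]), second_level=np.array([level]),
        true_pr=np.array([0.1]), field=field,
    )
    return syn.render_puncta_image(m, psf_sigma=sigma, background=0.0).pixels


class TestPreprocess:
    def test_constant_image_constant_background_is_zero(self):
        img = np.full((32, 32), 13.0)
        out = pk.preprocess(img, gaussian_sigma=0.0, background={"method": "constant", "value": 13.0})
        assert np.all(out == 0.0)

    def test_identity_path(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        np.testing.assert_array_equal(pk.preprocess(img, gaussian_sigma=0.0), img)

    def test_impulse_matches_direct_convolution(self):
        # oracle: direct convolution of the impulse with a sampled 2-D kernel
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = pk.preprocess(img, gaussian_sigma=0.75)
        r = np.arange(33) - 16.0
        g = np.exp(-(r**2) / (2 * 0.75**2))
        kernel = np.outer(g, g)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out, kernel, atol=1e-6)

    def test_nonfinite_pixels_rejected(self):
        img = np.zeros((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            pk.preprocess(img, 0.75)


class TestFindMaxima:
    def test_constant_image_has_no_maxima(self):
        assert pk.find_maxima(np.full((32, 32), 5.0), noise_tolerance=1.0) == []

    def test_single_gaussian_peak_found_exactly(self):
        img = _one_spot()
        assert pk.find_maxima(img, noise_tolerance=1.0, min_intensity=0.5) == [(20, 30)]

    def test_two_peaks_resolved_when_tolerance_below_dip(self):
        # oracle: 1-D profile of two unit-sum Gaussians 12 px apart (sigma 1.5)
        # dips essentially to zero between them, so any modest tolerance resolves both
        img = _one_spot(x=20.0, y=20.0) + _one_spot(x=32.0, y=20.0)
        found = pk.find_maxima(img, noise_tolerance=5.0, min_intensity=0.5)
        assert sorted(found) == [(20, 20), (32, 20)]

    def test_two_peaks_merge_when_tolerance_above_dip(self):
        # two sigma-3 spots 8 px apart: dip prominence ~3.6; tolerance 5 merges
        img = _one_spot(x=20.0, y=20.0, sigma=3.0) + _one_spot(x=28.0, y=20.0, sigma=3.0)
        found = pk.find_maxima(img, noise_tolerance=5.0, min_intensity=0.0)
        assert len(found) == 1
        # below the dip depth both peaks are resolved again
        assert len(pk.find_maxima(img, noise_tolerance=2.0, min_intensity=0.0)) == 2

    def test_plateau_reports_lexicographically_smallest(self):
        img = np.zeros((16, 16))
        img[5:8, 5:8] = 2.0
        found = pk.find_maxima(img, noise_tolerance=0.5, min_intensity=0.0)
        assert found == [(5, 5)]


class TestSegmentation:
    def test_single_maximum_single_connected_label(self):
        img = _one_spot()
        labels = pk.segment_puncta(img, [(20, 30)], min_intensity=0.5)
        assert labels.max() == 1
        assert labels[30, 20] == 1
        from skimage.measure import label as cc_label

        assert cc_label(labels > 0).max() == 1

    def test_partition_of_thresholded_pixels(self):
        img = _one_spot(x=20.0, y=20.0) + _one_spot(x=40.0, y=40.0)
        thr = 0.3
        labels = pk.segment_puncta(img, [(20, 20), (40, 40)], min_intensity=thr)
        assert set(np.unique(labels)) == {0, 1, 2}
        np.testing.assert_array_equal(labels > 0, img >= thr)
        # well-separated spots: agrees with nearest-maximum assignment
        yy, xx = np.nonzero(labels)
        d1 = (xx - 20.0) ** 2 + (yy - 20.0) ** 2
        d2 = (xx - 40.0) ** 2 + (yy - 40.0) ** 2
        assert np.all(labels[yy, xx] == np.where(d1 < d2, 1, 2))

    def test_empty_maxima_gives_background(self):
        labels = pk.segment_puncta(np.ones((8, 8)), [], min_intensity=0.5)
        assert labels.max() == 0

    def test_maximum_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            pk.segment_puncta(np.zeros((8, 8)), [(3, 3)], min_intensity=1.0)


class TestMeasurement:
    def test_uniform_region(self):
        img = np.zeros((16, 16))
        img[4:8, 4:9] = 7.0
        labels = (img > 0).astype(np.int32)
        t = pk.measure_puncta(img, labels).table
        assert len(t) == 1
        assert t.loc[0, "area_px"] == 20
        assert t.loc[0, "mean_intensity"] == pytest.approx(7.0)
        assert t.loc[0, "sum_intensity"] == pytest.approx(140.0)

    def test_gaussian_sum_recovered(self):
        # oracle: truncated Gaussian integral — thresholding at 1 % of peak
        # keeps > 95 % of the flux
        level = 900.0
        img = _one_spot(level=level, x=32.0, y=32.0)
        thr = 0.01 * img.max()
        labels = (img >= thr).astype(np.int32)
        t = pk.measure_puncta(img, labels).table
        assert t.loc[0, "sum_intensity"] == pytest.approx(level, rel=0.05)

    def test_two_labels_unique_ids(self):
        img = np.zeros((16, 16))
        img[2:4, 2:4] = 1.0
        img[10:12, 10:12] = 2.0
        labels = np.zeros_like(img, dtype=np.int32)
        labels[2:4, 2:4] = 1
        labels[10:12, 10:12] = 2
        t = pk.measure_puncta(img, labels).table
        assert list(t["punctum_id"]) == [1, 2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pk.measure_puncta(np.zeros((8, 8)), np.zeros((9, 9), dtype=np.int32))

    def test_sum_equals_mean_times_area(self, noisy_image):
        t, _ = pk.detect_puncta(noisy_image.pixels, pk.DetectionParams(background=CONST_BG))
        np.testing.assert_allclose(
            t.table["sum_intensity"], t.table["mean_intensity"] * t.table["area_px"], rtol=1e-12
        )


class TestMaskTransfer:
    def test_target_equals_source_gives_identical_table(self, noisy_image):
        params = pk.DetectionParams(background=CONST_BG)
        tables, _ = pk.mask_transfer_measure(
            noisy_image.pixels, {"a": noisy_image.pixels}, params
        )
        direct, _ = pk.detect_puncta(noisy_image.pixels, params)
        np.testing.assert_allclose(tables["a"].table.to_numpy(), direct.table.to_numpy())

    def test_doubled_target_doubles_sums(self):
        src = _one_spot(x=20.0, y=20.0) + _one_spot(x=40.0, y=40.0) + 10.0
        params = pk.DetectionParams(background={"method": "constant", "value": 10.0})
        tables, _ = pk.mask_transfer_measure(src, {"t": 2.0 * src - 10.0}, params)
        base, _ = pk.mask_transfer_measure(src, {"t": src}, params)
        np.testing.assert_allclose(
            tables["t"].table["sum_intensity"], 2.0 * base["t"].table["sum_intensity"], rtol=1e-9
        )

    def test_dimmed_middle_spot_measured_dimmer(self):
        # oracle: the forward model plants the dimming factor
        xs = [12.0, 32.0, 52.0]
        src = sum(_one_spot(x=x, y=32.0) for x in xs)
        dim = _one_spot(x=12.0, y=32.0) + 0.4 * _one_spot(x=32.0, y=32.0) + _one_spot(x=52.0, y=32.0)
        params = pk.DetectionParams(background={"method": "none"}, min_intensity=0.5, noise_tolerance=1.0)
        tables, _ = pk.mask_transfer_measure(src, {"src": src, "dim": dim}, params)
        assert len(tables["dim"]) == 3
        s = tables["src"].table.sort_values("x", ignore_index=True)
        d = tables["dim"].table.sort_values("x", ignore_index=True)
        ratio = d["sum_intensity"] / s["sum_intensity"]
        np.testing.assert_allclose(ratio, [1.0, 0.4, 1.0], rtol=0.02)

    def test_shape_mismatch_rejected(self, noisy_image):
        with pytest.raises(ValueError):
            pk.mask_transfer_measure(noisy_image.pixels, {"bad": np.zeros((8, 8))})


class TestDetectionQuality:
    def test_noiseless_centroids_within_half_pixel(self, default_map, clean_image):
        t, _ = pk.detect_puncta(clean_image.pixels, pk.DetectionParams(background=CONST_BG))
        met = detection_metrics(t.centroids, default_map.centers, radius=2.0)
        assert met["recall"] == 1.0 and met["precision"] == 1.0
        assert met["max_localization_error"] <= 0.5

    def test_exclusion_mask_removes_region(self, default_map, noisy_image):
        mask = np.zeros(noisy_image.pixels.shape, dtype=bool)
        mask[:, :128] = True
        t, _ = pk.detect_puncta(
            noisy_image.pixels, pk.DetectionParams(background=CONST_BG), exclusion_mask=mask
        )
        assert (t.table["x"] >= 127).all()
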