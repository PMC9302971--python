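"""Calibration, ROI sampling, line profiles, and background correction."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant.imaging import (
    BackgroundSubtractConfig,
    CalibratedImage,
    CalibrationError,
    CircleROI,
    PointROI,
    TimeLapse,
    background_subtracted_mean,
    blur_background_subtract,
    read_image_stack,
    roi_mean_intensity,
    sample_line_profile,
    write_image_stack,
)


class TestCalibratedImage:
    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(CalibrationError):
            CalibratedImage(np.zeros((4, 4)), pixel_size_um=0.0)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            CalibratedImage(np.zeros((2, 2, 2)), pixel_size_um=0.1)

    def test_um_px_conversion_is_exact(self):
        img = CalibratedImage(np.zeros((4, 4)), pixel_size_um=0.25)
        assert img.to_um(8.0) == 2.0
        assert img.to_px(2.0) == 8.0


class TestTimeLapse:
    def test_rejects_non_monotone_timestamps(self):
        frames = [CalibratedImage(np.zeros((4, 4)), 0.1) for _ in range(3)]
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeLapse({"ch": frames}, timestamps=[0.0, 2.0, 1.0])

    def test_rejects_mixed_dimensions(self):
        frames = [CalibratedImage(np.zeros((4, 4)), 0.1), CalibratedImage(np.zeros((5, 4)), 0.1)]
        with pytest.raises(ValueError, match="dimensions"):
            TimeLapse({"ch": frames}, timestamps=[0.0, 1.0])


class TestReadImageStack:
    def test_round_trips_generator_output(self, tmp_path, rng):
        stack = rng.uniform(0, 100, size=(5, 16, 16)).astype(np.float32)
        path = tmp_path / "m.tif"
        tifffile.imwrite(path, stack)
        movie = read_image_stack(path, pixel_size_um=0.1)
        assert movie.n_frames == 5
        assert movie.pixel_size_um == 0.1
        for k in range(5):
            np.testing.assert_array_equal(movie.frames[k].pixels, stack[k])

    def test_single_page_tiff(self, tmp_path):
        path = tmp_path / "s.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.float32))
        assert read_image_stack(path, pixel_size_um=0.2).n_frames == 1

    def test_missing_calibration_raises(self, tmp_path):
        path = tmp_path / "u.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.float32))
        with pytest.raises(CalibrationError):
            read_image_stack(path)

    def test_metadata_calibration_round_trip(self, tmp_path):
        frames = [CalibratedImage(np.ones((8, 8)) * k, 0.25) for k in range(3)]
        movie = TimeLapse({"ch0": frames}, [0.0, 1.0, 2.0])
        path = tmp_path / "cal.tif"
        write_image_stack(movie, path)
        back = read_image_stack(path)  # no override: must come from metadata
        assert back.pixel_size_um == pytest.approx(0.25)

    def test_explicit_calibration_overrides_metadata(self, tmp_path):
        frames = [CalibratedImage(np.ones((8, 8)), 0.25)]
        write_image_stack(TimeLapse({"ch0": frames}, [0.0]), tmp_path / "c.tif")
        assert read_image_stack(tmp_path / "c.tif", pixel_size_um=0.5).pixel_size_um == 0.5


class TestRoiMeanIntensity:
    def test_constant_image(self, constant_image):
        roi = CircleROI(PointROI(32, 32), radius_um=1.0)
        assert roi_mean_intensity(constant_image, roi) == 7.0

    def test_half_plane_boundary_circle(self):
        # 0 on the left half, 10 on the right; circle centered on the boundary
        img = np.zeros((101, 101))
        img[:, 51:] = 10.0
        image = CalibratedImage(img, 0.1)
        # center between the two halves: x = 50.5
        val = roi_mean_intensity(image, CircleROI(PointROI(50.5, 50.0), radius_um=3.0))
        brute = _brute_circle_mean(img, 50.5, 50.0, 30.0)
        assert val == pytest.approx(brute)
        assert val == pytest.approx(5.0, abs=0.3)

    def test_too_small_circle_raises(self, constant_image):
        with pytest.raises(ValueError, match="no pixel centers"):
            roi_mean_intensity(constant_image, CircleROI(PointROI(10.5, 10.5), radius_um=0.04))

    def test_off_image_circle_raises(self, constant_image):
        with pytest.raises(ValueError, match="bounds"):
            roi_mean_intensity(constant_image, CircleROI(PointROI(2, 2), radius_um=1.0))

    def test_offset_linearity(self, rng):
        """roi mean of (I + c) equals roi mean of I plus c."""
        base = rng.uniform(0, 50, (40, 40))
        roi = CircleROI(PointROI(20, 20), radius_um=1.0)
        m0 = roi_mean_intensity(CalibratedImage(base, 0.1), roi)
        m1 = roi_mean_intensity(CalibratedImage(base + 13.5, 0.1), roi)
        assert m1 == pytest.approx(m0 + 13.5)


def _brute_circle_mean(img, cx, cy, r_px):
    total, n = 0.0, 0
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r_px**2:
                total += img[y, x]
                n += 1
    return total / n


class TestSampleLineProfile:
    def test_horizontal_ramp(self):
        h, w = 8, 32
        img = CalibratedImage(np.tile(np.arange(w, dtype=float), (h, 1)), 0.1)
        pos, vals = sample_line_profile(img, PointROI(2, 4), PointROI(29, 4))
        np.testing.assert_allclose(vals, np.linspace(2, 29, len(vals)))
        assert pos[0] == 0.0
        assert pos[-1] == pytest.approx(2.7)  # 27 px * 0.1 um

    def test_reversal_symmetry(self, rng):
        img = CalibratedImage(rng.uniform(0, 100, (40, 40)), 0.1)
        p1, p2 = PointROI(3.2, 5.7), PointROI(35.1, 30.4)
        _, fwd = sample_line_profile(img, p1, p2)
        _, rev = sample_line_profile(img, p2, p1)
        np.testing.assert_allclose(fwd, rev[::-1], rtol=1e-12)

    def test_diagonal_through_gaussian_matches_analytic(self):
        """Bilinear samples along a diagonal track the analytic 2-D Gaussian."""
        n, sigma = 81, 6.0
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        img = CalibratedImage(np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * sigma**2)), 0.1)
        p1, p2 = PointROI(10, 10), PointROI(70, 70)
        pos, vals = sample_line_profile(img, p1, p2)
        t = np.linspace(0, 1, len(vals))
        xs, ys = 10 + 60 * t, 10 + 60 * t
        analytic = np.exp(-((xs - c) ** 2 + (ys - c) ** 2) / (2 * sigma**2))
        # bilinear error bound ~ h^2 |f''| / 8 with h = sqrt(2) px diagonal spacing
        np.testing.assert_allclose(vals, analytic, atol=0.01)

    def test_degenerate_segment_raises(self, constant_image):
        with pytest.raises(ValueError, match="degenerate"):
            sample_line_profile(constant_image, PointROI(5, 5), PointROI(5, 5))

    def test_out_of_bounds_raises(self, constant_image):
        with pytest.raises(ValueError, match="outside"):
            sample_line_profile(constant_image, PointROI(5, 5), PointROI(100, 5))


class TestBlurBackgroundSubtract:
    def test_constant_image_becomes_zero(self, constant_image):
        out = blur_background_subtract(constant_image)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)

    def test_impulse_survives_large_sigma(self):
        img = np.zeros((201, 201))
        img[100, 100] = 1000.0
        out = blur_background_subtract(CalibratedImage(img, 0.1), BackgroundSubtractConfig(30.0))
        # blur of an impulse spreads it over ~sigma^2 pixels; the peak keeps >99%
        assert out.pixels[100, 100] > 0.99 * 1000.0

    def test_gradient_flattened_spot_kept(self):
        n = 301
        yy, xx = np.mgrid[0:n, 0:n]
        gradient = xx * 0.5
        spot = 500.0 * np.exp(-((xx - 150) ** 2 + (yy - 150) ** 2) / (2 * 2.0**2))
        out = blur_background_subtract(
            CalibratedImage(gradient + spot, 0.1), BackgroundSubtractConfig(30.0)
        )
        interior = out.pixels[100:-100, 100:-100]  # away from blur edge effects
        spotless = interior.copy()
        spotless[30:75, 30:75] = 0.0  # spot neighbourhood, local coords
        # gradient amplitude (ptp away from the spot) reduced > 10x
        assert np.ptp(spotless) < np.ptp(gradient[100:-100, 100:-100]) / 10
        # spot peak reduced < 5%
        assert out.pixels[150, 150] > 0.95 * 500.0


class TestBackgroundSubtractedMean:
    def test_algebraic_identity_on_random_image(self, rng):
        img = CalibratedImage(rng.uniform(0, 200, (30, 30)), 0.1)
        sig = np.zeros((30, 30), bool)
        sig[5:15, 5:15] = True
        bg = np.zeros((30, 30), bool)
        bg[20:28, 20:28] = True
        val = background_subtracted_mean(img, sig, bg)
        assert val == pytest.approx(img.pixels[sig].mean() - img.pixels[bg].mean(), rel=1e-12)

    @given(offset=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_global_offset(self, offset):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 100, (20, 20))
        sig = np.zeros((20, 20), bool)
        sig[2:8, 2:8] = True
        bg = np.zeros((20, 20), bool)
        bg[12:18, 12:18] = True
        v0 = background_subtracted_mean(CalibratedImage(base, 0.1), sig, bg)
        v1 = background_subtracted_mean(CalibratedImage(base + offset, 0.1), sig, bg)
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_empty_mask_raises(self, constant_image):
        empty = np.zeros((64, 64), bool)
        bg = np.ones((64, 64), bool)
        with pytest.raises(ValueError, match="empty signal"):
            background_subtracted_mean(constant_image, empty, bg)

    def test_overlapping_regions_raise(self, constant_image):
        m = np.ones((64, 64), bool)
        with pytest.raises(ValueError, match="overlap"):
            background_subtracted_mean(constant_image, m, m)
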