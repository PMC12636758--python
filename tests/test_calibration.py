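"""Frame calibration: rectification, axis solve, response correction, extraction."""

import numpy as np
import pytest

from sorsbone import (
    BundleLayout,
    CCDFrame,
    DetectorSpec,
    WavenumberAxis,
    apply_rectification,
    apply_response,
    calibrate_axis,
    dark_subtract,
    extract_bundle_spectra,
    fit_rectification,
    fit_response,
    generate_calibration_set,
)
from sorsbone.calibration import CROP_LENGTH, CalibrationError, peak_centroid


@pytest.fixture(scope="module")
def calib(detector):
    return generate_calibration_set(detector, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="module")
def rect(calib):
    return fit_rectification(calib)


def rectified(frame, calib, rect):
    return apply_rectification(dark_subtract(frame, calib.dark), rect)


class TestDarkSubtract:
    def test_frame_equal_to_dark_becomes_zero(self):
        f = CCDFrame(np.full((8, 16), 120.0))
        assert np.array_equal(dark_subtract(f, f).data, np.zeros((8, 16)))

    def test_constant_offset_survives(self):
        dark = CCDFrame(np.full((8, 16), 120.0), role="dark")
        f = CCDFrame(dark.data + 100.0)
        assert np.allclose(dark_subtract(f, dark).data, 100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dark_subtract(CCDFrame(np.zeros((4, 8))), CCDFrame(np.zeros((4, 9))))


class TestFitRectification:
    def test_zero_smile_fits_near_zero_coefficients(self):
        det = DetectorSpec(smile_coeffs=(0.0, 0.0, 0.0), gain_sigma=1e-12)
        r = fit_rectification(generate_calibration_set(det))
        rows = np.arange(det.n_rows)
        assert np.abs(r.shift(rows)).max() < 1e-3

    def test_recovers_quadratic_smile_within_one_percent(self, detector, rect):
        c2 = detector.smile_coeffs[2]
        assert rect.shift_coeffs[1] == pytest.approx(c2, rel=0.01)
        assert rect.shift_coeffs[0] == pytest.approx(detector.smile_coeffs[1], rel=0.01)

    def test_crop_window_spans_499_pixels(self, rect):
        assert rect.crop[1] - rect.crop[0] == CROP_LENGTH


class TestApplyRectification:
    def test_zero_map_is_identity_up_to_crop(self, rect, calib):
        from dataclasses import replace

        zero = replace(rect, shift_coeffs=(0.0, 0.0))
        out = apply_rectification(calib.white, zero)
        assert np.allclose(out.data, calib.white.data[:, rect.crop[0] : rect.crop[1]])

    def test_line_centroids_align_across_rows_after_rectification(self, detector, calib, rect):
        frame = rectified(calib.neon, calib, rect)
        approx = int(calib.truth["neon_cols"][7]) - rect.crop[0]
        cents = [peak_centroid(frame.data[r], approx) for r in range(0, detector.n_rows, 16)]
        assert np.ptp(cents) < 0.1

    def test_row_intensity_conserved_for_interior_peaks(self, calib, rect):
        before = dark_subtract(calib.neon, calib.dark)
        after = apply_rectification(before, rect)
        # compare the flux of one interior line, row by row
        lo = int(calib.truth["neon_cols"][7]) - 15
        sl_before = before.data[:, lo : lo + 31].sum(axis=1)
        # post-rectification the line sits at its row-0 position in all rows;
        # shifts are < 3 px, so the 31-px window has ample margin either way
        sl_after = after.data[:, lo - rect.crop[0] : lo - rect.crop[0] + 31].sum(axis=1)
        assert np.all(np.abs(sl_after - sl_before) / sl_before < 1e-3)

    def test_shift_exceeding_margin_rejected(self, rect, calib):
        from dataclasses import replace

        wild = replace(rect, shift_coeffs=(2.0, 0.0))
        with pytest.raises(CalibrationError):
            apply_rectification(calib.white, wild)


@pytest.fixture(scope="module")
def axis(calib, rect):
    return calibrate_axis(
        rectified(calib.neon, calib, rect), calib.neon_lines_nm,
        rectified(calib.acetaminophen, calib, rect), calib.acet_shifts_cm,
    )


class TestCalibrateAxis:
    def test_effective_laser_wavelength_recovered(self, axis, detector):
        assert abs(axis.lambda0_nm - detector.laser_wavelength_nm) < 0.01

    def test_axis_is_monotone_and_obeys_shift_identity(self, axis):
        assert np.all(np.diff(axis.shifts) > 0)
        lam = axis.wavelength(np.arange(CROP_LENGTH))
        expected = 1e7 * (1.0 / axis.lambda0_nm - 1.0 / lam)
        assert np.allclose(axis.shifts, expected, atol=1e-9)

    def test_acetaminophen_lines_land_within_2_inverse_cm(self, axis, calib, rect):
        frame = rectified(calib.acetaminophen, calib, rect)
        prof = frame.data.sum(axis=0)
        for shift_true, col_true in zip(calib.acet_shifts_cm, calib.truth["acet_cols"]):
            cent = peak_centroid(prof, int(col_true) - rect.crop[0])
            got = np.interp(cent, np.arange(CROP_LENGTH), axis.shifts)
            assert abs(got - shift_true) < 2.0

    def test_perfect_axis_reproduces_known_line_exactly(self):
        from numpy.polynomial import Polynomial

        lam0 = 830.0
        poly = Polynomial([880.0, 0.2])  # exact linear map
        axis = WavenumberAxis(
            shifts=1e7 * (1 / lam0 - 1 / poly(np.arange(499.0))),
            lambda_poly=poly, lambda0_nm=lam0,
        )
        # a line whose wavelength matches pixel 100 must land at shift(100)
        lam_line = poly(100.0)
        assert 1e7 * (1 / lam0 - 1 / lam_line) == pytest.approx(axis.shifts[100])

    def test_too_few_lines_rejected(self, calib, rect):
        neon = rectified(calib.neon, calib, rect)
        with pytest.raises(CalibrationError):
            calibrate_axis(neon, calib.neon_lines_nm[:2], neon, calib.acet_shifts_cm)


class TestResponseCorrection:
    def test_flat_instrument_correction_is_identity(self):
        det = DetectorSpec(
            smile_coeffs=(0.0, 0.0, 0.0), gain_map=np.ones((64, 1024)),
            broadband_response=np.ones(1024), n_rows=64,
        )
        calib = generate_calibration_set(det)
        rect = fit_rectification(calib)
        axis = calibrate_axis(
            rectified(calib.neon, calib, rect), calib.neon_lines_nm,
            rectified(calib.acetaminophen, calib, rect), calib.acet_shifts_cm,
        )
        model = fit_response(
            rectified(calib.white, calib, rect), rectified(calib.glass, calib, rect),
            calib.glass_certified, axis,
        )
        assert np.allclose(model.fixed_pattern, 1.0, atol=1e-6)
        assert np.allclose(model.broadband, 1.0, atol=0.02)

    def test_known_gain_and_response_recovered(self, detector, calib, rect):
        axis = calibrate_axis(
            rectified(calib.neon, calib, rect), calib.neon_lines_nm,
            rectified(calib.acetaminophen, calib, rect), calib.acet_shifts_cm,
        )
        model = fit_response(
            rectified(calib.white, calib, rect), rectified(calib.glass, calib, rect),
            calib.glass_certified, axis,
        )
        # fixed pattern ~ rectified gain map: compare away from the crop edges
        cols = slice(rect.crop[0] + 5, rect.crop[1] - 5)
        gain = apply_rectification(CCDFrame(detector.gain_map), rect).data[:, 5:-5]
        rel = model.fixed_pattern[:, 5:-5] / gain - 1.0
        assert np.sqrt(np.mean(rel**2)) < 0.02
        true_bb = detector.broadband_response[cols]
        est = model.broadband[5:-5]
        rel_bb = est / est.mean() - true_bb / true_bb.mean()
        assert np.sqrt(np.mean(rel_bb**2)) < 0.02

    def test_fixed_pattern_division_equalizes_two_gain_fields(self):
        """Same signal seen through two different gain fields agrees after step (i)."""
        from scipy.ndimage import median_filter

        rng = np.random.default_rng(0)
        cols = np.arange(CROP_LENGTH)
        signal = 1000.0 + 400.0 * np.exp(-0.5 * ((cols - 250) / 40.0) ** 2)
        signal = np.tile(signal, (32, 1))
        corrected = []
        for seed in (1, 2):
            gain = np.clip(np.random.default_rng(seed).normal(1.0, 0.03, signal.shape), 0.5, None)
            white = 1000.0 * gain
            pattern = white / median_filter(white, size=(1, 31), mode="nearest")
            corrected.append(signal * gain / pattern)
        rel = corrected[0] / corrected[1] - 1.0
        assert np.sqrt(np.mean(rel**2)) < 0.02


class TestExtractBundleSpectra:
    def test_ones_frame_counts_bundle_rows(self, instrument):
        frame = CCDFrame(np.ones((256, CROP_LENGTH)))
        for spec in extract_bundle_spectra(frame, instrument.layout, instrument.axis):
            n_rows = len(instrument.layout.rows[spec.offset_mm])
            assert np.allclose(spec.intensity, n_rows)
            assert n_rows == {0: 4, 3: 12, 6: 26}[spec.offset_mm]

    def test_bundle_sums_are_additive(self, instrument):
        rng = np.random.default_rng(1)
        frame = CCDFrame(rng.uniform(0, 10, (256, CROP_LENGTH)))
        spectra = extract_bundle_spectra(frame, instrument.layout, instrument.axis)
        total = sum(s.intensity for s in spectra)
        manual = sum(
            frame.data[r.start : r.stop].sum(axis=0)
            for r in instrument.layout.rows.values()
        )
        assert np.allclose(total, manual)

    def test_overlapping_layout_rejected(self):
        with pytest.raises(ValueError):
            BundleLayout({0: range(0, 10), 3: range(5, 20)})
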