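"""Cohort generator and instrument model: ground truth the analysis must recover."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from sorsbone import (
    BundleLayout,
    CohortSpec,
    DetectorSpec,
    WHOClass,
    classify_who,
    generate_calibration_set,
    generate_cohort,
    render_clean_spectrum,
    render_frame_stack,
)
from sorsbone.calibration import peak_centroid
from sorsbone.synthetic import MATRIX_BANDS, ConfigurationError

from conftest import make_specimen


class TestGenerateCohort:
    def test_default_composition_is_8_6_11(self):
        cohort = generate_cohort(CohortSpec(seed=1))
        counts = {c: sum(1 for s in cohort if s.who_class == c) for c in WHOClass}
        assert len(cohort) == 25
        assert counts[WHOClass.NORMAL] == 8
        assert counts[WHOClass.OSTEOPENIA] == 6
        assert counts[WHOClass.OSTEOPOROSIS] == 11

    def test_seed_determinism_bitwise(self):
        a = generate_cohort(CohortSpec(seed=7))
        b = generate_cohort(CohortSpec(seed=7))
        for s, t in zip(a, b):
            assert s.tscore == t.tscore and s.chem_score == t.chem_score
            for layer in ("surface", "subsurface"):
                assert s.layer_amplitudes[layer] == t.layer_amplitudes[layer]
            assert np.array_equal(s.fluorescence_coeffs, t.fluorescence_coeffs)

    def test_every_specimen_class_matches_its_tscore(self):
        for s in generate_cohort(CohortSpec(seed=3)):
            assert classify_who(s.tscore) == s.who_class

    def test_zero_noise_zero_link_gives_identical_amplitudes(self, quiet_cohort_spec):
        spec = replace(
            quiet_cohort_spec,
            link_slope=dict.fromkeys(["PO4", "CO3", "AmideIII", "CH2", "AmideI"], 0.0),
        )
        cohort = generate_cohort(spec)
        ref = cohort[0].layer_amplitudes
        for s in cohort[1:]:
            for layer in ref:
                for band, amp in ref[layer].items():
                    assert s.layer_amplitudes[layer][band] == pytest.approx(amp)

    def test_truncated_tscore_sampler_matches_analytic_means(self):
        # Monte-Carlo check against the closed-form truncated-normal moments
        spec = CohortSpec(
            n_per_class={c: 1000 for c in WHOClass}, seed=5
        )
        cohort = generate_cohort(spec)
        bounds = {
            WHOClass.NORMAL: (-1.0, np.inf),
            WHOClass.OSTEOPENIA: (-2.5, -1.0),
            WHOClass.OSTEOPOROSIS: (-np.inf, -2.5),
        }
        for cls in WHOClass:
            t = np.array([s.tscore for s in cohort if s.who_class == cls])
            lo, hi = bounds[cls]
            mu, sd = spec.tscore_mean[cls], spec.tscore_sd[cls]
            a, b = (lo - mu) / sd, (hi - mu) / sd
            mean = stats.truncnorm.mean(a, b, loc=mu, scale=sd)
            se = stats.truncnorm.std(a, b, loc=mu, scale=sd) / np.sqrt(t.size)
            assert abs(t.mean() - mean) < 4 * se
            assert np.all((t > lo) & (t <= hi) | np.isinf([lo] * t.size))
        # and the osteoporosis sample mean stays near its configured (untruncated) mean
        t_op = np.array([s.tscore for s in cohort if s.who_class == WHOClass.OSTEOPOROSIS])
        assert abs(t_op.mean() - (-4.19)) < 3 * t_op.std(ddof=1) / np.sqrt(t_op.size)

    def test_unknown_class_label_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_per_class={"Brittle": 3})

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortSpec(noise_sigma=-1.0))


class TestRenderCleanSpectrum:
    axis = np.linspace(700.0, 1800.0, 551)  # 2 cm^-1 grid containing 1200 exactly

    def test_single_band_peak_height_equals_amplitude(self):
        s = make_specimen({"X": 1.0}, centers={"X": 1200.0})
        for offset in (0, 3, 6):
            spec = render_clean_spectrum(s, offset, self.axis)
            assert spec.intensity.max() == pytest.approx(1.0, abs=1e-6)

    def test_equal_layers_make_offset_irrelevant(self):
        s = make_specimen({"X": 2.0, "Y": 0.7}, centers={"X": 1000.0, "Y": 1500.0})
        ref = render_clean_spectrum(s, 0, self.axis).intensity
        for offset in (3, 6):
            assert np.allclose(render_clean_spectrum(s, offset, self.axis).intensity, ref)

    def test_mixture_weights_blend_layer_amplitudes_pointwise(self):
        surf = {"X": 1.0, "Y": 3.0}
        sub = {"X": 2.0, "Y": 1.0}
        s = make_specimen(surf, sub, centers={"X": 1000.0, "Y": 1500.0},
                          subsurface_weight={0: 0.2, 3: 0.5, 6: 0.6})
        for offset, w in ((0, 0.2), (3, 0.5), (6, 0.6)):
            got = render_clean_spectrum(s, offset, self.axis).intensity
            expected = np.zeros_like(self.axis)
            for band in surf:
                amp = (1 - w) * surf[band] + w * sub[band]
                expected += amp * np.exp(
                    -0.5 * ((self.axis - s.band_centers[band]) / s.band_sigma[band]) ** 2
                )
            assert np.allclose(got, expected)

    def test_layer_weights_sum_to_one_conserves_band_energy(self):
        surf = {"X": 1.0}
        sub = {"X": 4.0}
        s = make_specimen(surf, sub, centers={"X": 1200.0})
        for offset, w in ((0, 0.2), (3, 0.5), (6, 0.6)):
            mixed = s.mixed_amplitudes(offset)["X"]
            assert mixed == pytest.approx((1 - w) * 1.0 + w * 4.0)

    def test_unknown_offset_rejected(self):
        s = make_specimen({"X": 1.0})
        with pytest.raises(ConfigurationError):
            render_clean_spectrum(s, 4, self.axis)

    def test_mineral_to_matrix_ordering_tracks_tscore(self, quiet_cohort_spec):
        """In the noise-free limit PO4/matrix ratios fall as the T-score falls."""
        cohort = generate_cohort(quiet_cohort_spec)
        order = np.argsort([s.tscore for s in cohort])
        for band in MATRIX_BANDS:
            ratios = np.array([
                s.mixed_amplitudes(3)["PO4"] / s.mixed_amplitudes(3)[band]
                for s in cohort
            ])[order]
            assert np.all(np.diff(ratios) > 0)  # increasing with increasing T


class TestRenderFrameStack:
    def test_identity_instrument_reproduces_spectrum_exactly(self):
        det = DetectorSpec(
            smile_coeffs=(0.0, 0.0, 0.0), gain_map=np.ones((64, 1024)),
            broadband_response=np.ones(1024), dark_level=0.0, n_rows=64,
        )
        layout = BundleLayout.default(64)
        s = make_specimen({"X": 5.0}, centers={"X": 1200.0})
        truth = render_clean_spectrum(s, 3, det.true_axis())
        frames, spikes = render_frame_stack(
            truth, s, det, n_frames=1, seed=0, noise_sigma=0.0, cosmic_rate=0.0,
            layout=layout,
        )
        assert spikes == []
        rows = layout.rows[3]
        c0 = (det.n_cols - 499) // 2
        block = frames[0].data[rows.start : rows.stop, c0 : c0 + 499]
        assert np.allclose(block.sum(axis=0), truth.intensity, atol=1e-9)

    def test_seeded_spike_log_is_reproducible(self):
        det = DetectorSpec(n_rows=64)
        s = make_specimen({"X": 5.0})
        truth = render_clean_spectrum(s, 3, det.true_axis())
        logs = []
        for _ in range(2):
            frames, spikes = render_frame_stack(
                truth, s, det, n_frames=5, seed=42, noise_sigma=2.0, cosmic_rate=3.0,
                layout=BundleLayout.default(64),
            )
            logs.append(spikes)
        assert logs[0] == logs[1]
        assert len(logs[0]) > 0

    def test_recorded_spikes_really_are_in_the_frames(self):
        det = DetectorSpec(n_rows=64)
        s = make_specimen({"X": 5.0})
        truth = render_clean_spectrum(s, 3, det.true_axis())
        frames, spikes = render_frame_stack(
            truth, s, det, n_frames=3, seed=9, noise_sigma=0.0, cosmic_rate=4.0,
            layout=BundleLayout.default(64),
        )
        quiet, _ = render_frame_stack(
            truth, s, det, n_frames=3, seed=9, noise_sigma=0.0, cosmic_rate=0.0,
            layout=BundleLayout.default(64),
        )
        for k, r, c, amp in spikes:
            assert frames[k].data[r, c] - quiet[k].data[r, c] == pytest.approx(amp)

    def test_smile_shifts_line_centroid_by_c2_r_squared(self):
        c2 = 5e-5
        det = DetectorSpec(smile_coeffs=(0.0, 0.0, c2), gain_sigma=1e-12,
                           broadband_response=np.ones(1024))
        calib = generate_calibration_set(det, neon_lines_nm=np.array([920.0]))
        frame = calib.neon.data - det.dark_level
        col0 = peak_centroid(frame[0], int(calib.truth["neon_cols"][0]))
        for r in range(32, 256, 32):
            shift = peak_centroid(frame[r], int(round(col0 + c2 * r * r))) - col0
            assert shift == pytest.approx(c2 * r * r, abs=0.05)


class TestGenerateCalibrationSet:
    def test_ground_truth_lists_exactly_15_neon_lines(self, detector):
        calib = generate_calibration_set(detector)
        assert len(calib.neon_lines_nm) == 15
        assert len(calib.truth["neon_cols"]) == 15
        assert len(calib.acet_shifts_cm) == 13

    def test_zero_smile_gives_row_independent_centroids(self):
        det = DetectorSpec(smile_coeffs=(0.0, 0.0, 0.0), gain_sigma=1e-12)
        calib = generate_calibration_set(det)
        frame = calib.neon.data - det.dark_level
        approx = int(calib.truth["neon_cols"][3])
        cents = [peak_centroid(frame[r], approx) for r in range(0, 256, 16)]
        assert np.ptp(cents) < 0.02

    def test_white_frame_ratio_recovers_gain_map(self, detector):
        calib = generate_calibration_set(detector)
        white = calib.white.data - detector.dark_level
        # dividing out the column mean spectrum leaves the fixed pattern
        ratio = white / white.mean(axis=0, keepdims=True)
        gain_norm = detector.gain_map / detector.gain_map.mean(axis=0, keepdims=True)
        assert np.sqrt(np.mean((ratio - gain_norm) ** 2)) < 0.01
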