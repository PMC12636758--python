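"""Calibrate the spectrograph from its standard frames and invert one measurement.

The chain: dark subtraction; smile rectification fitted to 15 neon + 13
acetaminophen line centroids (one shared quadratic row-shift law); a
quadratic pixel->wavelength fit to the neon lamp; the effective laser
wavelength solved against the known acetaminophen Raman shifts; and a
two-step response correction (white-lamp fixed pattern, green-glass
broadband).  With a noise-free synthetic instrument the chain should give
back exactly what went in.
"""

import numpy as np

from sorsbone import (
    CohortSpec,
    DetectorSpec,
    apply_rectification,
    apply_response,
    calibrate_instrument,
    dark_subtract,
    extract_bundle_spectra,
    generate_cohort,
    render_clean_spectrum,
    render_frame_stack,
)

detector = DetectorSpec()  # 1024x256 CCD, 830 nm laser, known smile/gain/response
instrument = calibrate_instrument(detector, noise_sigma=0.0, seed=1)

b1, b2 = instrument.rectification.shift_coeffs
print(f"smile law:   fitted {b1:+.5f} r {b2:+.2e} r^2   (true {detector.smile_coeffs[1]:+.5f} r {detector.smile_coeffs[2]:+.2e} r^2)")
print(f"laser line:  recovered {instrument.axis.lambda0_nm:.5f} nm (true {detector.laser_wavelength_nm} nm)")
print(f"axis:        {instrument.axis.shifts[0]:.0f} .. {instrument.axis.shifts[-1]:.0f} cm^-1 over 499 pixels")

# render one noise-free bone measurement and push it through the chain
spec = CohortSpec(noise_sigma=0.0, cosmic_rate=0.0, scale_sigma=0.0,
                  fluorescence_amp=0.0, seed=3)
specimen = generate_cohort(spec)[0]
truth_axis = detector.true_axis(instrument.rectification.crop[0])
clean = render_clean_spectrum(specimen, 3, truth_axis)
frames, _ = render_frame_stack(clean, specimen, detector, n_frames=1, seed=2,
                               noise_sigma=0.0, cosmic_rate=0.0,
                               layout=instrument.layout)
f = dark_subtract(frames[0], instrument.calibration.dark)
f = apply_rectification(f, instrument.rectification)
f = apply_response(f, instrument.response)
measured = next(s for s in extract_bundle_spectra(f, instrument.layout, instrument.axis)
                if s.offset_mm == 3)

truth = render_clean_spectrum(specimen, 3, instrument.axis)
scale = measured.intensity @ truth.intensity / (measured.intensity @ measured.intensity)
rms = np.sqrt(np.mean((scale * measured.intensity - truth.intensity) ** 2)
              / np.mean(truth.intensity ** 2))
print(f"round trip:  {100 * rms:.2f}% relative RMS between recovered and true spectrum")
print("\nSub-2% round-trip error means band ratios taken from calibrated spectra")
print("reflect the specimen, not the instrument.")
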