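import numpy as np
import pytest

from sorsbone import (
    CohortSpec,
    DetectorSpec,
    GroundTruthSpecimen,
    WHOClass,
    calibrate_instrument,
)


@pytest.fixture(scope="session")
def detector():
    return DetectorSpec()


@pytest.fixture(scope="session")
def instrument(detector):
    """Noise-free calibration fit of the default instrument, shared per session."""
    return calibrate_instrument(detector, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def quiet_cohort_spec():
    """Deterministic composition: no detector noise, no nuisance variability."""
    return CohortSpec(
        noise_sigma=0.0, cosmic_rate=0.0, scale_sigma=0.0, fluorescence_amp=0.0,
        link_noise_sd=0.0, axis_jitter_sd=0.0,
        residual_sd=dict.fromkeys(["PO4", "CO3", "AmideIII", "CH2", "AmideI"], 0.0),
        seed=11,
    )


def make_specimen(
    band_amplitudes_surface: dict,
    band_amplitudes_subsurface: dict | None = None,
    centers: dict | None = None,
    sigmas: dict | None = None,
    subsurface_weight: dict | None = None,
) -> GroundTruthSpecimen:
    """Hand-built specimen for single-band / known-amplitude scenarios."""
    surface = dict(band_amplitudes_surface)
    sub = dict(band_amplitudes_subsurface or band_amplitudes_surface)
    centers = centers or {b: 1200.0 for b in surface}
    sigmas = sigmas or {b: 8.0 for b in surface}
    return GroundTruthSpecimen(
        specimen_id="TEST",
        who_class=WHOClass.NORMAL,
        tscore=0.0,
        chem_score=0.0,
        layer_amplitudes={"surface": surface, "subsurface": sub},
        band_centers=centers,
        band_sigma=sigmas,
        subsurface_weight=subsurface_weight or {0: 0.2, 3: 0.5, 6: 0.6},
        fluorescence_coeffs=np.zeros(1),
    )


def gaussian_spectrum(shifts, center, amplitude=1.0, sigma=6.0, background=None):
    y = amplitude * np.exp(-0.5 * ((shifts - center) / sigma) ** 2)
    if background is not None:
        y = y + background
    return y
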