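"""Synthetic cadaver cohorts and raw CCD frame stacks with known ground truth.

No public dataset accompanies the bone study this package analyses, so this
module generates cohorts that emulate its statistical structure: 25 female
donors in three WHO classes (8 normal / 6 osteopenic / 11 osteoporotic),
class-specific distal-radius T-score distributions, and spectra whose
matrix-band amplitudes (carbonate, Amide III, CH2, Amide I) grow as the
T-score falls — the direction observed in osteoporotic bone, where the
mineral-to-matrix ratio drops.

Depth sensitivity is phenomenological: each specimen has a surface-cortex and
a subcortical band-amplitude set, mixed with an offset-dependent subsurface
weight (larger lateral offsets sample deeper).  No photon-transport is
simulated.  The instrument model applies spectrograph smile, per-pixel gain,
a broadband spectral response, dark level, shot-like Gaussian noise, and
single-pixel cosmic-ray spikes, so the full calibration chain can be
exercised and inverted against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats

from .calibration import (
    CROP_LENGTH,
    BundleLayout,
    BundleSpectrum,
    CCDFrame,
    WavenumberAxis,
)
from .chemometrics import T_OSTEOPENIA, T_OSTEOPOROSIS, WHOClass, classify_who

# --- bone Raman band model -------------------------------------------------

#: band centers (cm^-1): the phosphate nu1 position is the value the study
#: normalizes to; the matrix-band centers are literature-standard.
BAND_CENTERS = {"PO4": 960.0, "CO3": 1070.0, "AmideIII": 1250.0, "CH2": 1450.0, "AmideI": 1660.0}
BAND_FWHM = {"PO4": 12.0, "CO3": 16.0, "AmideIII": 22.0, "CH2": 18.0, "AmideI": 24.0}
MATRIX_BANDS = ("CO3", "AmideIII", "CH2", "AmideI")
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: 13 acetaminophen Raman shifts (cm^-1) from the standard relative-intensity
#: calibration list that fall inside the cropped axis; the 834.5 line is
#: omitted because it is unresolvable from 857.9 at this dispersion.
ACETAMINOPHEN_SHIFTS_CM = (
    710.8, 797.2, 857.9, 968.7, 1105.5, 1168.5, 1236.8,
    1278.5, 1323.9, 1371.5, 1515.1, 1561.5, 1648.4,
)

CLASS_ORDER = (WHOClass.NORMAL, WHOClass.OSTEOPENIA, WHOClass.OSTEOPOROSIS)
_CLASS_BOUNDS = {
    WHOClass.NORMAL: (T_OSTEOPENIA, np.inf),
    WHOClass.OSTEOPENIA: (T_OSTEOPOROSIS, T_OSTEOPENIA),
    WHOClass.OSTEOPOROSIS: (-np.inf, T_OSTEOPOROSIS),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class DetectorSpec:
    """Geometry and response of the synthetic CCD spectrograph.

    The pixel->wavelength map is quadratic (near-linear dispersion with a
    small bow), spanning ``shift_span`` cm^-1 of Raman shift at the nominal
    830 nm laser line.  ``smile_coeffs`` give the column shift of a
    monochromatic line versus row, (c0, c1, c2) -> c0 + c1*r + c2*r^2.
    """

    n_cols: int = 1024
    n_rows: int = 256
    smile_coeffs: tuple[float, float, float] = (0.0, -0.004, 5.0e-5)
    gain_sigma: float = 0.03
    gain_seed: int = 901_234
    dark_level: float = 100.0
    laser_wavelength_nm: float = 830.0
    shift_span: tuple[float, float] = (-100.0, 2350.0)
    dispersion_bow_nm: float = 0.8
    calib_sigma_px: float = 1.5
    gain_map: np.ndarray | None = None
    broadband_response: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gain_map is None:
            rng = np.random.default_rng(self.gain_seed)
            self.gain_map = np.clip(
                rng.normal(1.0, self.gain_sigma, (self.n_rows, self.n_cols)), 0.2, None
            )
        if np.any(self.gain_map <= 0):
            raise ConfigurationError("gain map must be strictly positive")
        if self.broadband_response is None:
            u = np.linspace(0.0, 1.0, self.n_cols)
            resp = 0.55 + 0.45 * np.sin(np.pi * (0.12 + 0.80 * u))
            self.broadband_response = resp / resp.mean()
        if np.any(self.broadband_response <= 0):
            raise ConfigurationError("broadband response must be strictly positive")
        smax = np.abs(self.smile(np.arange(self.n_rows))).max()
        if smax >= (self.n_cols - CROP_LENGTH) // 2:
            raise ConfigurationError("smile shift exceeds the crop margin")

    # wavelength map ---------------------------------------------------
    def _lambda_endpoints(self) -> tuple[float, float]:
        inv0 = 1.0 / self.laser_wavelength_nm
        lo, hi = self.shift_span
        return 1.0 / (inv0 - lo * 1e-7), 1.0 / (inv0 - hi * 1e-7)

    @property
    def wavelength_poly(self) -> Polynomial:
        lam_s, lam_e = self._lambda_endpoints()
        span, bow, m = lam_e - lam_s, self.dispersion_bow_nm, self.n_cols - 1
        # quadratic through the endpoints with mid-column excess `bow` nm
        return Polynomial([lam_s, (span + 4 * bow) / m, -4 * bow / m**2])

    def wavelength(self, cols) -> np.ndarray:
        return self.wavelength_poly(np.asarray(cols, dtype=float))

    def shift_true(self, cols) -> np.ndarray:
        """True Raman shift (cm^-1) seen by each detector column."""
        return 1e7 * (1.0 / self.laser_wavelength_nm - 1.0 / self.wavelength(cols))

    def column_of_wavelength(self, lam_nm) -> np.ndarray:
        cols = np.arange(self.n_cols, dtype=float)
        return np.interp(np.asarray(lam_nm, dtype=float), self.wavelength(cols), cols)

    def column_of_shift(self, shift_cm) -> np.ndarray:
        inv = 1.0 / self.laser_wavelength_nm - np.asarray(shift_cm, dtype=float) * 1e-7
        return self.column_of_wavelength(1.0 / inv)

    def smile(self, rows) -> np.ndarray:
        r = np.asarray(rows, dtype=float)
        c0, c1, c2 = self.smile_coeffs
        return c0 + c1 * r + c2 * r * r

    def true_axis(self, crop_start: int | None = None) -> WavenumberAxis:
        """Ground-truth axis over the default central crop (for rendering truth)."""
        c0 = (self.n_cols - CROP_LENGTH) // 2 if crop_start is None else crop_start
        cols = np.arange(c0, c0 + CROP_LENGTH)
        poly = self.wavelength_poly
        # re-express in cropped column coordinates
        shifted = Polynomial([float(c0), 1.0])
        return WavenumberAxis(
            shifts=self.shift_true(cols),
            lambda_poly=(poly(shifted)).convert(),
            lambda0_nm=self.laser_wavelength_nm,
        )


@dataclass
class CohortSpec:
    """Statistical design of a synthetic cohort (defaults = study conditions).

    T-score means/SDs per class follow the donor demographics table of the
    study being emulated; band link slopes, layer residuals and the
    wrist-to-finger decoupling noise are sized so the cohort reproduces the
    study's reported fidelity scale (see docs/methods.md).
    """

    n_per_class: dict = field(default_factory=lambda: {
        WHOClass.NORMAL: 8, WHOClass.OSTEOPENIA: 6, WHOClass.OSTEOPOROSIS: 11})
    tscore_mean: dict = field(default_factory=lambda: {
        WHOClass.NORMAL: 0.05, WHOClass.OSTEOPENIA: -1.63, WHOClass.OSTEOPOROSIS: -4.19})
    tscore_sd: dict = field(default_factory=lambda: {
        WHOClass.NORMAL: 0.45, WHOClass.OSTEOPENIA: 0.38, WHOClass.OSTEOPOROSIS: 0.90})
    #: change in subsurface band amplitude per T-score unit below t_ref
    link_slope: dict = field(default_factory=lambda: {
        "PO4": 0.0, "CO3": 0.08, "AmideIII": 0.20, "CH2": 0.11, "AmideI": 0.14})
    surface_link_fraction: float = 0.25
    #: sd of the latent chemistry score around the wrist T-score (T units):
    #: finger-bone composition tracks the distal-radius DXA only imperfectly
    link_noise_sd: float = 0.8
    #: per-band residual sd as a fraction of the base amplitude (subsurface);
    #: phosphate nu1 is the strongest, most reproducible band and carries the
    #: smallest residual, which matters because every spectrum is normalized
    #: to it downstream
    residual_sd: dict = field(default_factory=lambda: {
        "PO4": 0.02, "CO3": 0.06, "AmideIII": 0.06, "CH2": 0.06, "AmideI": 0.06})
    surface_residual_multiplier: float = 2.0
    base_amplitude: dict = field(default_factory=lambda: {
        "PO4": 1.0, "CO3": 0.25, "AmideIII": 0.25, "CH2": 0.35, "AmideI": 0.45})
    subsurface_matrix_boost: float = 1.15
    subsurface_weight: dict = field(default_factory=lambda: {0: 0.2, 3: 0.5, 6: 0.6})
    t_ref: float = 0.0
    amplitude_scale: float = 1000.0     # detector counts of the phosphate peak
    scale_sigma: float = 0.15           # lognormal per-measurement coupling spread
    fluorescence_amp: float = 2.0       # background amplitude, x phosphate peak
    fluorescence_order: int = 4
    axis_jitter_sd: float = 0.5         # cm^-1, per-specimen band-center jitter
    noise_sigma: float = 5.0            # detector counts per pixel per frame
    cosmic_rate: float = 3.0            # expected spikes per frame
    spike_amp: tuple[float, float] = (300.0, 3000.0)
    n_frames: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        # accept plain class-name strings (e.g. from YAML) as dict keys
        for attr in ("n_per_class", "tscore_mean", "tscore_sd"):
            try:
                setattr(self, attr, {WHOClass(k): v for k, v in getattr(self, attr).items()})
            except ValueError as exc:
                raise ConfigurationError(str(exc)) from None
        self.subsurface_weight = {int(k): float(v) for k, v in self.subsurface_weight.items()}

    def validate(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in _CLASS_BOUNDS:
                raise ConfigurationError(f"unknown WHO class {cls!r}")
            if n < 1:
                raise ConfigurationError("each included class needs >= 1 specimen")
        for name, d in (("tscore_sd", self.tscore_sd), ("residual_sd", self.residual_sd)):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError(f"{name} entries must be >= 0")
        if self.noise_sigma < 0 or self.cosmic_rate < 0:
            raise ConfigurationError("noise_sigma and cosmic_rate must be >= 0")
        for off, w in self.subsurface_weight.items():
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError(f"subsurface weight at {off} mm outside [0, 1]")
        if not 0 <= self.fluorescence_order <= 5:
            raise ConfigurationError("fluorescence order must be in [0, 5]")


@dataclass
class GroundTruthSpecimen:
    """One synthetic donor: the recovery target for acceptance tests."""

    specimen_id: str
    who_class: WHOClass
    tscore: float
    chem_score: float
    layer_amplitudes: dict            # layer -> band -> amplitude (counts)
    band_centers: dict                # band -> jittered center (cm^-1)
    band_sigma: dict                  # band -> Gaussian sigma (cm^-1)
    subsurface_weight: dict           # offset mm -> weight in [0, 1]
    fluorescence_coeffs: np.ndarray   # polynomial over normalized shift (counts)
    axis_jitter_cm: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        for layer, amps in self.layer_amplitudes.items():
            if any(a <= 0 for a in amps.values()):
                raise ConfigurationError(f"non-positive band amplitude in layer {layer}")
        if classify_who(self.tscore) != self.who_class:
            raise ConfigurationError("who_class inconsistent with tscore")

    def mixed_amplitudes(self, offset_mm: int) -> dict:
        if offset_mm not in self.subsurface_weight:
            raise ConfigurationError(f"unknown offset {offset_mm} mm")
        w = self.subsurface_weight[offset_mm]
        surf, sub = self.layer_amplitudes["surface"], self.layer_amplitudes["subsurface"]
        return {b: (1.0 - w) * surf[b] + w * sub[b] for b in surf}


@dataclass
class CalibrationSet:
    """Calibration frames plus their ground truth (line positions, curves)."""

    dark: CCDFrame
    neon: CCDFrame
    acetaminophen: CCDFrame
    white: CCDFrame
    glass: CCDFrame
    neon_lines_nm: np.ndarray
    acet_shifts_cm: np.ndarray
    glass_certified: tuple[np.ndarray, np.ndarray]
    truth: dict = field(default_factory=dict)


# --- cohort generation -----------------------------------------------------


def _truncated_tscores(cls: WHOClass, n: int, spec: CohortSpec, rng) -> np.ndarray:
    lo, hi = _CLASS_BOUNDS[cls]
    mu, sd = spec.tscore_mean[cls], spec.tscore_sd[cls]
    if sd == 0:
        t = np.full(n, mu)
        if np.any((t < lo) | (t > hi)):
            raise ConfigurationError("degenerate T-score mean outside its class interval")
        return t
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def _fluorescence_poly(spec: CohortSpec, po4_counts: float, rng) -> np.ndarray:
    """Random smooth positive background, as coefficients over u in [0, 1]."""
    order = spec.fluorescence_order
    raw = Polynomial(rng.normal(0.0, 1.0, order + 1))
    u = np.linspace(0.0, 1.0, 201)
    v = raw(u)
    lo, span = v.min(), np.ptp(v) + 1e-9
    amp = spec.fluorescence_amp * po4_counts
    # affine-map the polynomial so values lie in [0.25, 1.0] * amp
    scaled = (raw - lo) * (0.75 * amp / span) + 0.25 * amp
    return scaled.coef


def generate_cohort(spec: CohortSpec) -> list[GroundTruthSpecimen]:
    """Draw a full cohort with class-truncated T-scores and linked amplitudes.

    Subsurface band amplitudes follow
    ``a0_b * (1 + beta_b * (t_ref - c)) + eps``,  ``c = t + eta``,
    with ``eta`` the wrist-to-finger decoupling noise shared by all bands of a
    specimen and ``eps`` a per-band residual.  Surface amplitudes use a
    reduced link slope and a larger residual, so shallow (0 mm) sampling
    carries a weaker, noisier version of the composition signal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    specimens: list[GroundTruthSpecimen] = []
    counter = 0
    for cls in CLASS_ORDER:
        n = spec.n_per_class.get(cls, 0)
        if n == 0:
            continue
        tscores = _truncated_tscores(cls, n, spec, rng)
        for t in tscores:
            counter += 1
            chem = float(t + rng.normal(0.0, spec.link_noise_sd))
            scale = float(np.exp(rng.normal(0.0, spec.scale_sigma)))
            counts = spec.amplitude_scale * scale
            layers = {}
            for layer in ("surface", "subsurface"):
                link_frac = 1.0 if layer == "subsurface" else spec.surface_link_fraction
                res_mult = 1.0 if layer == "subsurface" else spec.surface_residual_multiplier
                amps = {}
                for band, a0 in spec.base_amplitude.items():
                    base = a0
                    if layer == "subsurface" and band in MATRIX_BANDS:
                        base = a0 * spec.subsurface_matrix_boost
                    beta = spec.link_slope.get(band, 0.0) * link_frac
                    eps = rng.normal(0.0, res_mult * spec.residual_sd.get(band, 0.0) * base)
                    amps[band] = max(base * (1.0 + beta * (spec.t_ref - chem)) + eps,
                                     0.02 * base) * counts
                layers[layer] = amps
            jitter = float(rng.normal(0.0, spec.axis_jitter_sd))
            specimens.append(GroundTruthSpecimen(
                specimen_id=f"S{counter:02d}",
                who_class=cls,
                tscore=float(t),
                chem_score=chem,
                layer_amplitudes=layers,
                band_centers={b: c + jitter for b, c in BAND_CENTERS.items()},
                band_sigma={b: f * _FWHM_TO_SIGMA for b, f in BAND_FWHM.items()},
                subsurface_weight=dict(spec.subsurface_weight),
                fluorescence_coeffs=_fluorescence_poly(spec, counts, rng),
                axis_jitter_cm=jitter,
                scale=scale,
            ))
    return specimens


def cohort_table(specimens: list[GroundTruthSpecimen]):
    import pandas as pd

    return pd.DataFrame({
        "specimen_id": [s.specimen_id for s in specimens],
        "who_class": [s.who_class.value for s in specimens],
        "tscore": [s.tscore for s in specimens],
    })


# --- spectrum and frame rendering ------------------------------------------


def _band_profile(shifts: np.ndarray, amplitudes: dict, centers: dict, sigmas: dict) -> np.ndarray:
    out = np.zeros_like(shifts, dtype=float)
    for band, amp in amplitudes.items():
        s = sigmas[band]
        out += amp * np.exp(-0.5 * ((shifts - centers[band]) / s) ** 2)
    return out


def render_clean_spectrum(
    specimen: GroundTruthSpecimen, offset_mm: int, axis: WavenumberAxis | np.ndarray
) -> BundleSpectrum:
    """Noise- and baseline-free mixture spectrum at one lateral offset."""
    shifts = axis.shifts if isinstance(axis, WavenumberAxis) else np.asarray(axis, float)
    if np.any(np.diff(shifts) <= 0):
        raise ValueError("axis must be strictly increasing")
    intensity = _band_profile(
        shifts, specimen.mixed_amplitudes(offset_mm), specimen.band_centers, specimen.band_sigma
    )
    return BundleSpectrum(
        offset_mm=offset_mm, shifts=shifts, intensity=intensity,
        provenance={"specimen": specimen.specimen_id, "kind": "clean-truth"},
    )


def _fluorescence_counts(specimen: GroundTruthSpecimen, shifts: np.ndarray,
                         span: tuple[float, float]) -> np.ndarray:
    u = (shifts - span[0]) / (span[1] - span[0])
    return Polynomial(specimen.fluorescence_coeffs)(u)


def _render_raw(
    detector: DetectorSpec,
    ideal_cols: np.ndarray,
    rows: range | None,
    row_weight: float,
    rng,
    noise_sigma: float,
    cosmic_rate: float,
    spike_amp: tuple[float, float],
):
    """Place a 1-D ideal signal into rows, apply the instrument model."""
    from scipy.interpolate import CubicSpline

    nr, nc = detector.n_rows, detector.n_cols
    cols = np.arange(nc, dtype=float)
    data = np.zeros((nr, nc))
    target = range(nr) if rows is None else rows
    smile = detector.smile(np.arange(nr))
    pos = np.clip(cols[None, :] - smile[list(target), None], 0.0, nc - 1.0)
    # cubic evaluation: the generator's smile shift is applied without the
    # smoothing a linear resample would introduce
    shifted = CubicSpline(cols, ideal_cols)(pos)
    data[list(target), :] = shifted * row_weight
    data *= detector.gain_map * detector.broadband_response[None, :]
    data += detector.dark_level
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, data.shape)
    spikes = []
    if cosmic_rate > 0:
        for _ in range(rng.poisson(cosmic_rate)):
            r, c = int(rng.integers(nr)), int(rng.integers(nc))
            amp = float(rng.uniform(*spike_amp))
            data[r, c] += amp
            spikes.append((r, c, amp))
    return data, spikes


def render_frame_stack(
    spectrum: BundleSpectrum,
    specimen: GroundTruthSpecimen,
    detector: DetectorSpec,
    n_frames: int = 5,
    seed: int = 0,
    *,
    noise_sigma: float = 5.0,
    cosmic_rate: float = 3.0,
    spike_amp: tuple[float, float] = (300.0, 3000.0),
    layout: BundleLayout | None = None,
) -> tuple[list[CCDFrame], list[tuple[int, int, int, float]]]:
    """Render replicate raw frames for one specimen/offset measurement.

    The clean spectrum plus the specimen's polynomial fluorescence background
    is imaged into the bundle's row block (split evenly across its fibers),
    smile-shifted per row, multiplied by the gain map and broadband response,
    offset by the dark level, and degraded by Gaussian noise and single-pixel
    cosmic-ray spikes.  Spike locations ``(frame, row, col, amp)`` are
    returned for test oracles.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    layout = layout or BundleLayout.default(detector.n_rows)
    rows = layout.rows[spectrum.offset_mm]
    rng = np.random.default_rng(seed)
    col_shift = detector.shift_true(np.arange(detector.n_cols))
    ideal = np.interp(col_shift, spectrum.shifts, spectrum.intensity, left=0.0, right=0.0)
    ideal = ideal + _fluorescence_counts(specimen, col_shift, detector.shift_span)
    frames, spike_log = [], []
    for k in range(n_frames):
        data, spikes = _render_raw(
            detector, ideal, rows, 1.0 / len(rows), rng, noise_sigma, cosmic_rate, spike_amp
        )
        frames.append(CCDFrame(data=data, role="sample", index=k))
        spike_log.extend((k, r, c, a) for r, c, a in spikes)
    return frames, spike_log


def default_neon_lines(detector: DetectorSpec, n_lines: int = 15,
                       crop_start: int | None = None) -> np.ndarray:
    """Synthetic neon-lamp wavelengths: evenly spaced inside the cropped axis.

    (A stand-in line list, not the NIST Ne I spectrum; real lamp wavelengths
    can be passed to :func:`generate_calibration_set` instead.)
    """
    c0 = (detector.n_cols - CROP_LENGTH) // 2 if crop_start is None else crop_start
    cols = np.linspace(c0 + 18, c0 + CROP_LENGTH - 18, n_lines)
    return np.round(detector.wavelength(cols), 2)


def generate_calibration_set(
    detector: DetectorSpec,
    *,
    noise_sigma: float = 0.0,
    cosmic_rate: float = 0.0,
    seed: int = 0,
    neon_lines_nm: np.ndarray | None = None,
    acet_shifts_cm: np.ndarray | None = None,
) -> CalibrationSet:
    """Render dark/neon/acetaminophen/white/glass frames through the instrument.

    All calibration sources uniformly illuminate the slit (every detector
    row), so per-row centroids are available for the rectification fit.  The
    certified green-glass emission curve is returned alongside the measured
    glass frame.
    """
    rng = np.random.default_rng(seed)
    neon_lines_nm = np.asarray(
        default_neon_lines(detector) if neon_lines_nm is None else neon_lines_nm, float
    )
    acet_shifts_cm = np.asarray(
        ACETAMINOPHEN_SHIFTS_CM if acet_shifts_cm is None else acet_shifts_cm, float
    )
    cols = np.arange(detector.n_cols, dtype=float)
    sig = detector.calib_sigma_px

    def line_frame(line_cols, heights, role):
        ideal = np.zeros(detector.n_cols)
        for c, h in zip(line_cols, heights):
            ideal += h * np.exp(-0.5 * ((cols - c) / sig) ** 2)
        data, _ = _render_raw(detector, ideal, None, 1.0, rng,
                              noise_sigma, cosmic_rate, (300.0, 3000.0))
        return CCDFrame(data=data, role=role)

    neon_cols = detector.column_of_wavelength(neon_lines_nm)
    neon_heights = 800.0 * (1.0 + 0.1 * np.cos(np.arange(neon_lines_nm.size)))
    acet_cols = detector.column_of_shift(acet_shifts_cm)
    acet_heights = 700.0 * (1.0 + 0.15 * np.sin(np.arange(acet_shifts_cm.size)))

    dark_data = np.full((detector.n_rows, detector.n_cols), detector.dark_level)
    if noise_sigma > 0:
        dark_data = dark_data + rng.normal(0.0, noise_sigma, dark_data.shape)

    white_data, _ = _render_raw(detector, np.full(detector.n_cols, 1000.0), None, 1.0,
                                rng, noise_sigma, cosmic_rate, (300.0, 3000.0))

    wl_grid = np.linspace(detector.wavelength(0.0) - 5.0,
                          detector.wavelength(detector.n_cols - 1.0) + 5.0, 400)
    certified = 0.15 + np.exp(-0.5 * ((wl_grid - 928.0) / 55.0) ** 2)
    glass_ideal = 1200.0 * np.interp(detector.wavelength(cols), wl_grid, certified)
    glass_data, _ = _render_raw(detector, glass_ideal, None, 1.0, rng,
                                noise_sigma, cosmic_rate, (300.0, 3000.0))

    return CalibrationSet(
        dark=CCDFrame(data=dark_data, role="dark"),
        neon=line_frame(neon_cols, neon_heights, "neon"),
        acetaminophen=line_frame(acet_cols, acet_heights, "acetaminophen"),
        white=CCDFrame(data=white_data, role="white"),
        glass=CCDFrame(data=glass_data, role="glass"),
        neon_lines_nm=neon_lines_nm,
        acet_shifts_cm=acet_shifts_cm,
        glass_certified=(wl_grid, certified),
        truth={
            "neon_cols": neon_cols,
            "acet_cols": acet_cols,
            "smile_coeffs": detector.smile_coeffs,
            "lambda0_nm": detector.laser_wavelength_nm,
        },
    )
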