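"""Replicate-frame cosmic-ray rejection, averaging, baseline removal, clipping.

The stage order is fixed by the types: :func:`reject_cosmic_rays` operates on
a :class:`FrameStack` of replicate spectra and returns one,
:func:`average_frames` collapses a stack to a single spectrum, and the
baseline/clipping steps accept only single spectra — so rejection cannot be
run after averaging.

Cosmic rays are flagged per spectral pixel when a replicate exceeds the mean
of the four lowest of five values by more than 10 median absolute deviations
(MAD of those four lowest, unscaled, floored to avoid zero-MAD degeneracy);
flagged values are replaced by that reference mean so frame averaging stays
balanced.  Fluorescence is removed by an iterative modified polynomial fit
(order 7, at most 10 iterations, 0.05 % relative-change convergence), and
residual negative intensities below the noise floor are clipped at
-0.5 sigma_noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import BundleSpectrum


@dataclass
class CosmicRayConfig:
    """10-MAD spike rejection settings.

    ``mad_floor`` guards against the zero/near-zero-MAD degeneracy of a
    4-sample MAD (whose lower percentiles sit far below the true noise sd,
    which would make the threshold fire on ordinary noise).  ``None`` (the
    default) scales the floor to the stack itself: 1.4 x the median per-pixel
    MAD, about half the frame-to-frame noise sd; a number fixes it in counts.
    """

    k_mad: float = 10.0
    n_lowest: int = 4
    mad_floor: float | None = None

    def __post_init__(self) -> None:
        if self.k_mad <= 0 or self.n_lowest < 1:
            raise ValueError("invalid cosmic-ray configuration")
        if self.mad_floor is not None and self.mad_floor < 0:
            raise ValueError("mad_floor must be >= 0")


@dataclass
class FluorescenceConfig:
    poly_order: int = 7
    max_iter: int = 10
    tol: float = 5e-4  # relative L2 change of the fitted polynomial (0.05 %)

    def __post_init__(self) -> None:
        if self.poly_order < 0 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid fluorescence-removal configuration")


@dataclass
class FrameStack:
    """K replicate spectra for one specimen/offset on a shared axis."""

    spectra: np.ndarray  # (K, n_pixels)
    shifts: np.ndarray
    offset_mm: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.spectra.shape[1] != self.shifts.size:
            raise ValueError("spectra and axis lengths differ")

    @property
    def n_frames(self) -> int:
        return self.spectra.shape[0]

    @classmethod
    def from_spectra(cls, spectra: list[BundleSpectrum]) -> "FrameStack":
        if not spectra:
            raise ValueError("empty stack")
        offsets = {s.offset_mm for s in spectra}
        if len(offsets) != 1:
            raise ValueError("stack mixes lateral offsets")
        return cls(
            spectra=np.vstack([s.intensity for s in spectra]),
            shifts=spectra[0].shifts,
            offset_mm=offsets.pop(),
        )


@dataclass
class CleanSpectrum:
    """Baseline-subtracted spectrum with its cleanup bookkeeping."""

    shifts: np.ndarray
    intensity: np.ndarray
    baseline: np.ndarray | None = None
    sigma_noise: float = float("nan")
    cosmic_mask: np.ndarray | None = None
    clip_mask: np.ndarray | None = None
    n_iterations: int = 0
    offset_mm: int = 0
    provenance: dict = field(default_factory=dict)

    def scaled(self, factor: float) -> "CleanSpectrum":
        return replace(
            self,
            intensity=self.intensity * factor,
            baseline=None if self.baseline is None else self.baseline * factor,
            sigma_noise=self.sigma_noise * factor,
        )


def reject_cosmic_rays(
    stack: FrameStack, cfg: CosmicRayConfig | None = None
) -> tuple[FrameStack, np.ndarray]:
    """Flag and replace cosmic-ray spikes, pixel by pixel across replicates.

    For each spectral pixel the ``n_lowest`` smallest replicate values form
    the reference subset; any replicate above ``mean(ref) + k_mad *
    max(MAD(ref), floor)`` is replaced by ``mean(ref)``.  Returns the
    cleaned stack and the boolean flag mask (K, n_pixels).
    """
    cfg = cfg or CosmicRayConfig()
    if stack.n_frames <= cfg.n_lowest:
        raise ValueError(
            f"need more than n_lowest={cfg.n_lowest} replicates, got {stack.n_frames}"
        )
    vals = stack.spectra
    lowest = np.sort(vals, axis=0)[: cfg.n_lowest]
    mu = lowest.mean(axis=0)
    med = np.median(lowest, axis=0)
    mad = np.median(np.abs(lowest - med), axis=0)
    floor = resolve_mad_floor(mad, cfg)
    threshold = mu + cfg.k_mad * np.maximum(mad, floor)
    mask = vals > threshold
    cleaned = np.where(mask, mu, vals)
    return replace(stack, spectra=cleaned), mask


def resolve_mad_floor(per_pixel_mad: np.ndarray, cfg: CosmicRayConfig) -> float:
    """The MAD floor actually applied: configured value, or the auto scale."""
    if cfg.mad_floor is not None:
        return float(cfg.mad_floor)
    return 1.4 * float(np.median(per_pixel_mad))


def average_frames(stack: FrameStack) -> BundleSpectrum:
    """Per-pixel arithmetic mean of the (cosmic-ray-cleaned) replicates."""
    return BundleSpectrum(
        offset_mm=stack.offset_mm,
        shifts=stack.shifts,
        intensity=stack.spectra.mean(axis=0),
        provenance={**stack.provenance, "n_frames": stack.n_frames},
    )


def modified_polynomial_baseline(
    shifts: np.ndarray, intensity: np.ndarray, cfg: FluorescenceConfig
) -> tuple[np.ndarray, int]:
    """Iterative modified polynomial fit of a fluorescence baseline.

    Repeatedly fits an order-``poly_order`` polynomial to the working curve
    and clamps the curve to the pointwise minimum of itself and the fit, so
    Raman peaks are progressively excluded while the smooth background is
    kept.  Stops when the relative L2 change of the fitted polynomial drops
    below ``tol`` or after ``max_iter`` iterations.
    """
    if intensity.size < cfg.poly_order + 1:
        raise ValueError("fewer points than polynomial order + 1")
    x = np.linspace(-1.0, 1.0, intensity.size)  # conditioning
    work = intensity.astype(float).copy()
    prev = None
    fitted = work
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        coeffs = np.polynomial.polynomial.polyfit(x, work, cfg.poly_order)
        fitted = np.polynomial.polynomial.polyval(x, coeffs)
        if prev is not None:
            denom = np.linalg.norm(prev)
            if denom == 0 or np.linalg.norm(fitted - prev) / denom < cfg.tol:
                break
        prev = fitted
        work = np.minimum(work, fitted)
    return fitted, n_iter


def remove_fluorescence(
    spectrum: BundleSpectrum, cfg: FluorescenceConfig | None = None
) -> CleanSpectrum:
    """Subtract the modified-polynomial fluorescence baseline."""
    cfg = cfg or FluorescenceConfig()
    baseline, n_iter = modified_polynomial_baseline(spectrum.shifts, spectrum.intensity, cfg)
    return CleanSpectrum(
        shifts=spectrum.shifts,
        intensity=spectrum.intensity - baseline,
        baseline=baseline,
        n_iterations=n_iter,
        offset_mm=spectrum.offset_mm,
        provenance=dict(spectrum.provenance),
    )


def estimate_sigma_noise(
    spectrum: CleanSpectrum | BundleSpectrum, window: tuple[float, float] = (1750.0, 1800.0)
) -> float:
    """Noise sd from a signal-free axis window (linear trend removed)."""
    sel = (spectrum.shifts >= window[0]) & (spectrum.shifts <= window[1])
    if sel.sum() < 4:
        raise ValueError(f"noise window {window} covers too few pixels")
    x = spectrum.shifts[sel]
    y = spectrum.intensity[sel]
    trend = np.polynomial.polynomial.polyval(
        x, np.polynomial.polynomial.polyfit(x, y, 1)
    )
    return float(np.std(y - trend, ddof=2))


def clip_to_noise_floor(
    spectrum: CleanSpectrum,
    sigma_noise: float | None = None,
    window: tuple[float, float] = (1750.0, 1800.0),
) -> CleanSpectrum:
    """Saturate intensities below the noise floor at -0.5 sigma_noise."""
    if sigma_noise is None:
        sigma_noise = estimate_sigma_noise(spectrum, window)
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be >= 0")
    floor = -0.5 * sigma_noise
    mask = spectrum.intensity < floor
    return replace(
        spectrum,
        intensity=np.where(mask, floor, spectrum.intensity),
        sigma_noise=float(sigma_noise),
        clip_mask=mask,
    )


def clean_stack(
    stack: FrameStack,
    cosmic_cfg: CosmicRayConfig | None = None,
    fluor_cfg: FluorescenceConfig | None = None,
    noise_window: tuple[float, float] = (1750.0, 1800.0),
) -> CleanSpectrum:
    """Fixed-order cleanup: reject -> average -> baseline -> clip."""
    rejected, mask = reject_cosmic_rays(stack, cosmic_cfg)
    averaged = average_frames(rejected)
    clean = remove_fluorescence(averaged, fluor_cfg)
    clean = clip_to_noise_floor(clean, window=noise_window)
    clean.cosmic_mask = mask
    return clean
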