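"""CCD frame calibration: rectification, wavenumber axis, response correction.

Converts raw detector frames into response-corrected per-bundle spectra on a
calibrated Raman-shift axis. The processing chain is

    dark_subtract -> fit/apply_rectification -> calibrate_axis
                  -> correct_response -> extract_bundle_spectra

Rectification removes spectrograph "smile" (a row-dependent column shift of
monochromatic lines) by fitting a single shared quadratic shift law to the
per-row centroids of neon and acetaminophen calibration peaks, then resampling
each row and cropping to a fixed 499-column spectral window.  The wavenumber
axis comes from a two-step calibration: a quadratic pixel->wavelength fit to
neon lamp lines, then a least-squares solve of the effective laser wavelength
against known acetaminophen Raman shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

CROP_LENGTH = 499  # spectral pixels retained after rectification

#: default fiber count per lateral offset (mm); bundle sizes grow with offset
#: so net collected signal stays comparable across offsets.
FIBER_COUNTS = {0: 4, 3: 12, 6: 26}


class CalibrationError(ValueError):
    """Raised when calibration inputs are unusable (too few peaks, bad axis)."""


@dataclass
class CCDFrame:
    """One 2-D detector exposure (rows x columns, counts)."""

    data: np.ndarray
    role: str = "sample"
    exposure_s: float = 60.0
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2-D (rows x columns)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class BundleLayout:
    """Mapping lateral offset (mm) -> contiguous detector row block."""

    rows: dict[int, range]

    def __post_init__(self) -> None:
        blocks = sorted((r.start, r.stop) for r in self.rows.values())
        for (s0, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError("bundle row ranges overlap")

    @classmethod
    def default(cls, n_rows: int = 256) -> "BundleLayout":
        total = sum(FIBER_COUNTS.values())
        gap = (n_rows - total) // 4
        if gap < 1:
            raise ValueError(f"detector with {n_rows} rows too small for default layout")
        rows, start = {}, gap
        for offset in sorted(FIBER_COUNTS):
            rows[offset] = range(start, start + FIBER_COUNTS[offset])
            start += FIBER_COUNTS[offset] + gap
        return cls(rows)

    def offsets(self) -> list[int]:
        return sorted(self.rows)


@dataclass
class RectificationMap:
    """Quadratic row->column-shift law plus the spectral crop window.

    The shift is referenced to row 0 (``shift(0) == 0``); a constant shift of
    all rows is unobservable from centroids and is absorbed by the wavelength
    calibration.
    """

    shift_coeffs: tuple[float, float]  # (b1, b2): shift(r) = b1*r + b2*r^2
    crop: tuple[int, int]              # half-open column window, width 499
    residual_px: float = 0.0
    centroids: dict | None = None

    def __post_init__(self) -> None:
        if self.crop[1] - self.crop[0] != CROP_LENGTH:
            raise ValueError(f"crop window must span {CROP_LENGTH} columns")

    def shift(self, rows: np.ndarray) -> np.ndarray:
        r = np.asarray(rows, dtype=float)
        b1, b2 = self.shift_coeffs
        return b1 * r + b2 * r * r


@dataclass
class WavenumberAxis:
    """Calibrated Raman-shift axis over the cropped spectral window."""

    shifts: np.ndarray                 # cm^-1, strictly increasing, length 499
    lambda_poly: Polynomial            # cropped column index -> wavelength (nm)
    lambda0_nm: float                  # effective laser wavelength

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.size != CROP_LENGTH:
            raise ValueError(f"axis must have {CROP_LENGTH} points")
        if np.any(np.diff(self.shifts) <= 0):
            raise CalibrationError("Raman-shift axis must be strictly increasing")

    def wavelength(self, cols: np.ndarray) -> np.ndarray:
        return self.lambda_poly(np.asarray(cols, dtype=float))


@dataclass
class ResponseModel:
    """Two-part detector response: per-pixel fixed pattern and broadband curve."""

    fixed_pattern: np.ndarray   # (rows, 499), strictly positive
    broadband: np.ndarray       # (499,), smooth, unit mean
    masked: np.ndarray | None = None  # pixels where the white frame was ~0

    def __post_init__(self) -> None:
        if np.any(self.fixed_pattern <= 0) or np.any(self.broadband <= 0):
            raise ValueError("response factors must be strictly positive")


@dataclass
class BundleSpectrum:
    """1-D intensity vector on a Raman-shift axis, tagged with its offset."""

    offset_mm: int
    shifts: np.ndarray
    intensity: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shifts.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("spectrum contains non-finite values")

    def scaled(self, factor: float) -> "BundleSpectrum":
        return replace(self, intensity=self.intensity * factor)


# ---------------------------------------------------------------------------
# operations


def dark_subtract(frame: CCDFrame, dark: CCDFrame) -> CCDFrame:
    if frame.shape != dark.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {dark.shape}")
    return replace(frame, data=frame.data - dark.data)


def peak_centroid(profile: np.ndarray, approx_col: float, window: int = 11) -> float:
    """Intensity-weighted centroid in a fixed window around the local maximum.

    The window is centred on the maximum sample within ``window`` pixels of the
    approximate position; the window minimum is subtracted as a local baseline
    so nearby background does not bias the first moment.
    """
    n = profile.size
    half = window // 2
    a = int(round(approx_col))
    lo, hi = max(0, a - half), min(n, a + half + 1)
    peak = lo + int(np.argmax(profile[lo:hi]))
    lo, hi = max(0, peak - half), min(n, peak + half + 1)
    seg = profile[lo:hi] - profile[lo:hi].min()
    total = seg.sum()
    if total <= 0:
        raise CalibrationError("empty peak window")
    return float((np.arange(lo, hi) * seg).sum() / total)


def _locate_peaks(profile: np.ndarray, n_expected: int, window: int = 11) -> np.ndarray:
    """Approximate columns of the ``n_expected`` strongest peaks, sorted."""
    prominence = 0.05 * (profile.max() - profile.min())
    idx, props = find_peaks(profile, prominence=prominence, distance=window // 2 + 1)
    if idx.size < n_expected:
        raise CalibrationError(
            f"found only {idx.size} of {n_expected} expected calibration peaks"
        )
    strongest = idx[np.argsort(props["prominences"])[::-1][:n_expected]]
    return np.sort(strongest)


def fit_rectification(
    calib,
    *,
    window: int = 11,
    crop_start: int | None = None,
    snr_min: float = 0.1,
) -> RectificationMap:
    """Fit the shared-curvature smile model to neon + acetaminophen centroids.

    ``calib`` provides dark, neon and acetaminophen frames (see
    :class:`sorsbone.synthetic.CalibrationSet`).  For every calibration peak
    the per-row centroid is measured; a single least-squares model

        centroid(k, r) = mu_k + b1*r + b2*r^2

    with one intercept per peak and one shared quadratic shift law is solved.
    Rows where a peak falls below ``snr_min`` of its global maximum are
    excluded with a warning.
    """
    frames = [
        (dark_subtract(calib.neon, calib.dark), len(calib.neon_lines_nm)),
        (dark_subtract(calib.acetaminophen, calib.dark), len(calib.acet_shifts_cm)),
    ]
    rows_list, peak_ids, cents = [], [], []
    peak_counter = 0
    n_rows = frames[0][0].shape[0]
    excluded = 0
    for frame, n_expected in frames:
        approx = _locate_peaks(frame.data.sum(axis=0), n_expected, window)
        for a in approx:
            global_max = frame.data[:, max(0, a - window) : a + window + 1].max()
            for r in range(n_rows):
                seg = frame.data[r]
                lo = max(0, a - window)
                if seg[lo : a + window + 1].max() < snr_min * global_max:
                    excluded += 1
                    continue
                rows_list.append(r)
                peak_ids.append(peak_counter)
                cents.append(peak_centroid(seg, a, window))
            peak_counter += 1
    if excluded:
        warnings.warn(f"{excluded} low-SNR peak rows excluded from rectification fit")
    if peak_counter < 3:
        raise CalibrationError("need at least 3 usable calibration peaks")

    rows_arr = np.asarray(rows_list, dtype=float)
    cents_arr = np.asarray(cents, dtype=float)
    ids = np.asarray(peak_ids)
    # design matrix: per-peak intercepts + shared (r, r^2) columns; rows
    # rescaled to [0, 1] for conditioning
    r_s = rows_arr / max(n_rows - 1, 1)
    design = np.zeros((rows_arr.size, peak_counter + 2))
    design[np.arange(rows_arr.size), ids] = 1.0
    design[:, peak_counter] = r_s
    design[:, peak_counter + 1] = r_s * r_s
    sol, *_ = np.linalg.lstsq(design, cents_arr, rcond=None)
    b1 = sol[peak_counter] / max(n_rows - 1, 1)
    b2 = sol[peak_counter + 1] / max(n_rows - 1, 1) ** 2
    resid = cents_arr - design @ sol

    n_cols = frames[0][0].shape[1]
    rmax = np.abs(b1 * np.arange(n_rows) + b2 * np.arange(n_rows) ** 2.0).max()
    margin = int(np.ceil(rmax)) + 1
    c0 = (n_cols - CROP_LENGTH) // 2 if crop_start is None else crop_start
    if c0 < margin or c0 + CROP_LENGTH > n_cols - margin:
        raise CalibrationError("smile shift exceeds the crop margin")
    return RectificationMap(
        shift_coeffs=(float(b1), float(b2)),
        crop=(c0, c0 + CROP_LENGTH),
        residual_px=float(np.sqrt(np.mean(resid**2))) if resid.size else 0.0,
        centroids={"rows": rows_arr, "peak": ids, "centroid": cents_arr},
    )


def apply_rectification(frame: CCDFrame, rmap: RectificationMap) -> CCDFrame:
    """Resample each row by its modeled shift (linear interpolation) and crop."""
    n_rows, n_cols = frame.shape
    shifts = rmap.shift(np.arange(n_rows))
    margin = min(rmap.crop[0], n_cols - rmap.crop[1])
    if np.abs(shifts).max() > margin:
        raise CalibrationError("row shift exceeds crop margin")
    cols = np.arange(rmap.crop[0], rmap.crop[1], dtype=float)
    pos = cols[None, :] + shifts[:, None]
    i0 = np.clip(np.floor(pos).astype(int), 0, n_cols - 2)
    frac = pos - i0
    left = np.take_along_axis(frame.data, i0, axis=1)
    right = np.take_along_axis(frame.data, i0 + 1, axis=1)
    return replace(frame, data=left * (1.0 - frac) + right * frac)


def calibrate_axis(
    neon: CCDFrame,
    neon_lines_nm,
    acet: CCDFrame,
    acet_shifts_cm,
    *,
    window: int = 11,
) -> WavenumberAxis:
    """Solve pixel->wavelength (neon) then the effective laser wavelength (acetaminophen).

    Both frames must already be dark-subtracted, rectified and cropped.  The
    neon fit is a quadratic in the cropped column index; the Raman shift of a
    pixel is then ``1e7 * (1/lambda0 - 1/lambda(pixel))`` with ``lambda0``
    solved in closed form by least squares over the acetaminophen lines.
    """
    neon_lines_nm = np.sort(np.asarray(neon_lines_nm, dtype=float))
    acet_shifts_cm = np.sort(np.asarray(acet_shifts_cm, dtype=float))
    if neon_lines_nm.size < 3 or acet_shifts_cm.size < 2:
        raise CalibrationError("need >= 3 neon lines and >= 2 acetaminophen lines")

    neon_prof = neon.data.sum(axis=0)
    neon_cents = np.array(
        [peak_centroid(neon_prof, a, window)
         for a in _locate_peaks(neon_prof, neon_lines_nm.size, window)]
    )
    lambda_poly = Polynomial.fit(neon_cents, neon_lines_nm, deg=2).convert()

    cols = np.arange(CROP_LENGTH, dtype=float)
    lam = lambda_poly(cols)
    if np.any(np.diff(lam) <= 0):
        raise CalibrationError("fitted pixel->wavelength map is not monotone")

    acet_prof = acet.data.sum(axis=0)
    acet_cents = np.array(
        [peak_centroid(acet_prof, a, window)
         for a in _locate_peaks(acet_prof, acet_shifts_cm.size, window)]
    )
    lam_k = lambda_poly(acet_cents)
    # shift_k = 1e7*(1/lambda0 - 1/lambda_k)  =>  1/lambda0 = mean over lines
    inv_lambda0 = float(np.mean(acet_shifts_cm * 1e-7 + 1.0 / lam_k))
    lambda0 = 1.0 / inv_lambda0
    shifts = 1e7 * (inv_lambda0 - 1.0 / lam)
    return WavenumberAxis(shifts=shifts, lambda_poly=lambda_poly, lambda0_nm=lambda0)


def fit_response(
    white: CCDFrame,
    glass: CCDFrame,
    glass_certified: tuple[np.ndarray, np.ndarray],
    axis: WavenumberAxis,
    *,
    lowpass_width: int = 31,
    eps_frac: float = 1e-3,
) -> ResponseModel:
    """Derive the fixed-pattern and broadband response factors.

    Step (i): the white-lamp frame divided by its per-row moving-median
    low-pass estimates the high-frequency pixel gain.  Step (ii): the
    glass-fluorescence frame (gain-corrected, row-averaged) divided by the
    certified emission curve, smoothed and unit-mean normalized, estimates the
    broadband spectral response.
    """
    smooth = median_filter(white.data, size=(1, lowpass_width), mode="nearest")
    floor = eps_frac * np.median(np.abs(smooth))
    masked = smooth <= floor
    if masked.any():
        warnings.warn(f"{int(masked.sum())} near-zero white-lamp pixels masked")
    pattern = np.where(masked, 1.0, white.data / np.where(masked, 1.0, smooth))
    pattern = np.clip(pattern, 1e-6, None)

    glass_flat = glass.data / pattern
    row_mean = glass_flat.mean(axis=0)
    wl, certified = glass_certified
    cert = np.interp(axis.wavelength(np.arange(CROP_LENGTH)), wl, certified)
    if np.any(cert <= 0):
        raise CalibrationError("certified glass curve must be positive over the axis")
    ratio = row_mean / cert
    broadband = median_filter(ratio, size=lowpass_width, mode="nearest")
    broadband = np.clip(broadband, 1e-9, None)
    broadband /= broadband.mean()
    return ResponseModel(fixed_pattern=pattern, broadband=broadband, masked=masked)


def apply_response(frame: CCDFrame, model: ResponseModel) -> CCDFrame:
    if frame.data.shape != model.fixed_pattern.shape:
        raise ValueError("frame shape does not match the response model")
    return replace(frame, data=frame.data / (model.fixed_pattern * model.broadband[None, :]))


def correct_response(
    frame: CCDFrame,
    white: CCDFrame,
    glass: CCDFrame,
    glass_certified: tuple[np.ndarray, np.ndarray],
    axis: WavenumberAxis,
    **kwargs,
) -> CCDFrame:
    """One-call wrapper: fit the response on (white, glass) and apply it."""
    return apply_response(frame, fit_response(white, glass, glass_certified, axis, **kwargs))


def extract_bundle_spectra(
    frame: CCDFrame, layout: BundleLayout, axis: WavenumberAxis
) -> list[BundleSpectrum]:
    """Sum each bundle's rows into one spectrum per lateral offset."""
    n_rows = frame.shape[0]
    out = []
    for offset in layout.offsets():
        rows = layout.rows[offset]
        if rows.stop > n_rows:
            raise ValueError(f"bundle rows {rows} exceed frame height {n_rows}")
        out.append(
            BundleSpectrum(
                offset_mm=offset,
                shifts=axis.shifts,
                intensity=frame.data[rows.start : rows.stop].sum(axis=0),
                provenance={"rows": (rows.start, rows.stop), "frame_index": frame.index},
            )
        )
    return out
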