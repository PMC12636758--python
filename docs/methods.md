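# Methods

This note documents the models, numerical choices and limitations behind
`sorsbone`, in the order data flows through the package.

## Synthetic cohort and instrument model

The generator stands in for cadaver measurements that are not publicly
available; its defaults define the study conditions every test and the
acceptance script run under.

**Cohort.** 25 female donors in three WHO classes (Normal 8, Osteopenia 6,
Osteoporosis 11). Distal-radius T-scores are drawn from class-specific
normal distributions — means ± SD of 0.05 ± 0.45, −1.63 ± 0.38 and
−4.19 ± 0.90 T-units — truncated to the class's WHO interval so labels and
scores can never conflict. (Truncation shifts the osteoporotic mean by
−0.06 T-units; the sampler is tested against the analytic truncated-normal
moments, not the untruncated means.)

**Composition link.** Each specimen has a latent chemistry score
`c = t + η`, where `t` is the wrist T-score and `η ~ N(0, 0.8)` models the
imperfect coupling between finger-bone chemistry and the distal-radius DXA
measurement. Band amplitudes per layer follow

```
amp_b = a0_b · (1 + β_b · (t_ref − c)) + ε_b ,   t_ref = 0
```

so lower T-scores mean relatively more matrix signal against a fixed
phosphate reference. Subsurface (subcortical) slopes are
β = 0.08 (CO₃²⁻), 0.20 (Amide III), 0.11 (CH₂), 0.14 (Amide I), 0 (PO₄³⁻)
per T-unit; the surface cortex carries 25 % of these slopes and twice the
residual noise, which is what makes shallow 0-mm sampling less informative.
Per-band residuals ε are 6 % of the base amplitude subsurface (2 % for
phosphate, the strongest and most reproducible bone band — its residual
matters doubly because every spectrum is later normalized to it).

These magnitudes were sized analytically, before the acceptance suite was
run, to reproduce the fidelity scale the emulated study reports: near-total
normal-vs-osteoporotic rank separation for all five ratios at 3 mm, a 3-mm
LOO Pearson r around 0.85–0.9 with RMSE_CV near one T-unit, and visibly
worse 0-mm performance. Two derivation errors were corrected during module
development (an omitted phosphate-normalization noise term; an undersized
carbonate slope) and the parameters then frozen. The error budget at 3 mm:
decoupling η ≈ 0.8, independent band residuals ≈ 0.35, phosphate-
normalization noise ≈ 0.26 T-units, giving ≈ 1.0 with LOO estimation
overhead.

**Depth mixing.** Offset dependence is phenomenological: the rendered
spectrum is `(1−w)·surface + w·subsurface` with w = 0.2 / 0.5 / 0.6 at
0 / 3 / 6 mm. No photon transport is simulated, and the mixture weights are
free parameters, not estimates of a real probe. The generator therefore does
*not* reproduce the empirically observed 6-mm degradation (extra variance at
large offsets); in this model 6 mm is marginally *better* than 3 mm, and no
claim about 6 mm is tested.

**Bands.** Gaussian profiles at 960 (PO₄³⁻ ν₁), 1070 (CO₃²⁻), 1250
(Amide III), 1450 (CH₂) and 1660 cm⁻¹ (Amide I) — literature-standard
centers — with FWHM 12–24 cm⁻¹ and a per-specimen axis jitter of 0.5 cm⁻¹.
Base amplitudes (PO₄ 1.0, CO₃ 0.25, Amide III 0.25, CH₂ 0.35, Amide I 0.45,
matrix bands ×1.15 subsurface) give normalized spectra in the range typical
of cortical bone.

**Instrument.** 1024×256-pixel CCD behind an 830-nm laser. The
pixel→wavelength map is quadratic (near-linear dispersion, 0.8-nm bow)
spanning −100…2350 cm⁻¹ so the central 499-column crop covers
≈ 646–1826 cm⁻¹. Spectrograph smile shifts each row's columns by
−0.004·r + 5·10⁻⁵·r² pixels; a per-pixel gain field (σ = 3 %), a smooth
broadband response, a 100-count dark level, Gaussian read noise
(σ = 5 counts) and Poisson-rate cosmic-ray spikes (3 per frame, 300–3000
counts, single-pixel) complete the model. Calibration sources (synthetic
neon lamp with 15 evenly spaced lines, the 13 acetaminophen shifts of the
standard calibration list that fall inside the crop, white lamp, green-glass
fluorescence standard with a certified emission curve) uniformly illuminate
the slit. The generator renders its smile shift with cubic-spline
evaluation, so resampling smoothing appears only where it belongs: in the
analysis chain.

## Calibration chain

*Rectification.* Per-row, per-peak intensity-weighted centroids (11-pixel
window around the local maximum, window minimum subtracted) feed a single
least-squares model `centroid(k, r) = μ_k + b₁r + b₂r²` — one intercept per
peak, one shared quadratic shift law, rows rescaled to [0, 1] for
conditioning. Rows where a peak drops below 10 % of its global maximum are
excluded with a warning. Each row is then resampled by its modeled shift
(linear interpolation; the dominant term of the ≈1 % end-to-end inversion
error) and cropped to 499 columns centred on the detector.

*Axis.* A quadratic pixel→wavelength fit to the neon centroids, then the
effective laser wavelength in closed form:
`1/λ₀ = mean_k(shift_k·10⁻⁷ + 1/λ(pixel_k))` over the acetaminophen lines;
the axis is `shift(i) = 10⁷(1/λ₀ − 1/λ(i))`, checked monotone.

*Response.* Step (i): the white-lamp frame divided by its per-row moving
median (width 31 px) estimates the high-frequency fixed pattern. Step (ii):
the gain-corrected, row-averaged glass frame divided by the certified curve,
median-smoothed and unit-mean normalized, estimates the broadband response.
Because both factors are unit-mean normalized, absolute throughput is not
identifiable — calibration-inversion accuracy is therefore quoted as the
relative RMS after a least-squares amplitude match, which is the physically
meaningful comparison for arbitrary-unit Raman intensities.

*Extraction.* Bundle rows (4 / 12 / 26 fibers at 0 / 3 / 6 mm, disjoint row
blocks) are summed into one spectrum per offset.

## Spectral cleanup

Fixed order, enforced by the types: reject → average → baseline → clip.

*Cosmic rays.* Per spectral pixel across K = 5 replicates: the four lowest
values form the reference; a replicate above `mean₄ + 10·max(MAD₄, floor)`
is replaced by `mean₄` (replacement rather than deletion keeps the average
balanced). The MAD is unscaled (no 1.4826 factor) and computed over the four
lowest values. The floor matters: a 4-sample MAD's lower tail sits far below
the true noise sd, and with no floor the rule fires on ~10 % of ordinary
Gaussian pixels. By default the floor auto-scales to the stack — 1.4× the
median per-pixel MAD, about half the replicate noise sd — giving a ~10⁻⁵
false-positive rate while every spike ≥ 20 σ stays far above threshold. A
fixed floor in counts can be configured instead.

*Baseline.* Iterative modified polynomial fit: repeatedly fit an order-7
polynomial (on an axis rescaled to [−1, 1]) and clamp the working curve to
the pointwise minimum of itself and the fit; stop when the relative L2
change of the fitted polynomial drops below 0.05 % or after 10 iterations.
The final polynomial is subtracted from the original spectrum.

*Clipping.* σ_noise is the sd of the detrended residual in a signal-free
window (default 1750–1800 cm⁻¹); intensities below −0.5 σ are saturated at
−0.5 σ (not zeroed, not removed), with the clip mask recorded.

## Band metrics and statistics

Band quantities default to the chord-corrected peak height: the maximum of
(intensity − linear chord between the window endpoints) inside a ±20 cm⁻¹
window; trapezoidal area above the same chord is available. Heights are
robust at 499-pixel resolution and insensitive to residual linear baseline.
Spectra are normalized so the phosphate quantity is exactly 1, which makes
every downstream ratio invariant to per-measurement intensity scale.

Group comparisons default to the two-sided Mann–Whitney U test (groups as
small as 6; normality unverifiable) with Bonferroni correction across the
three pairwise WHO comparisons, capped at 1 — the capping reproduces the
`p = 1.0000` entries typical of corrected tables. Welch's t and uncorrected
reporting are configurable. Stars follow the inclusive thresholds
10⁻⁴ (****), 10⁻³ (***), 10⁻² (**), 0.05 (*), else ns.

## Chemometrics

PLS1 by NIPALS deflation (equivalent to SIMPLS for a single response),
mean-centering only — no per-channel variance scaling, matching the usual
treatment of processed spectra as predictors; a scaling flag exists.
Weight-vector collapse (rank-deficient data) stops extraction early with a
warning and the achieved rank. At full rank with p < n the predictions
coincide with ordinary least squares, which the tests exploit as a
closed-form oracle alongside an independent reference implementation.

Leave-one-out CV recomputes centering inside every fold (a leakage test
perturbs held-out rows and checks fold models are unchanged). One deflation
sweep per fold yields coefficients for all ranks at once; RMSE_CV is
computed per rank over the grid 1–9 (capped at n−2 with a warning), the
optimal rank is the argmin with ties broken toward the smaller rank, and
reported predictions are the LOO predictions at that rank. A nested variant
that selects the rank inside each fold is available behind
`rank_selection="per_fold"`; the global rule is the default reading of
"minimum RMSE_CV". Whether predictors are phosphate-normalized is likewise
configurable (`normalize_predictors`, default true — it removes nuisance
intensity scale).

## Pipeline, sizes, and reproducibility

`run_pipeline` derives all stage seeds from one master seed via
`SeedSequence`, so a run is bit-for-bit reproducible; the manifest stores a
canonical config hash, seed, version, timings and stage warnings. The
recovery study used by the tests and by `scripts/acceptance.py` repeats the
full chain — 25 specimens × 2 offsets × 5 frames of 1024×256 pixels each —
over 20 seeds, which keeps the whole study at a few minutes on one CPU while
leaving the per-seed analysis at the full problem size.

## Known limitations

- Layer mixing is phenomenological; mixture weights are not instrument
  estimates, and the 6-mm variance inflation seen in practice is not
  modeled.
- Cosmic rays are single-pixel; multi-pixel track morphology is out of
  scope, and rectification can split a spike across two pixels (halving its
  apparent amplitude — still far above threshold at default energies).
- Only column-direction smile is corrected; keystone distortion and
  slit-function deconvolution are out of scope.
- The generator's Gaussian bands and polynomial fluorescence are idealized;
  passing tests demonstrate correct recovery of *this* data-generating
  process, not performance on real bone spectra with overlapping bands,
  Mie-scattering baselines, or soft-tissue contributions.
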