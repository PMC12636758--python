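# Default pipeline configuration: the study conditions the package emulates.
# Every constant with a published value is set to it (5 replicate frames,
# 499 spectral pixels, baseline order 7 / 10 iterations / 0.05% convergence,
# 10-MAD cosmic-ray rule, PLS rank grid 1-9, WHO thresholds -1 / -2.5).
# Omitted keys fall back to the same built-in defaults; this file is the
# explicit, editable record of them.

cohort:
  n_per_class: {Normal: 8, Osteopenia: 6, Osteoporosis: 11}
  tscore_mean: {Normal: 0.05, Osteopenia: -1.63, Osteoporosis: -4.19}
  tscore_sd: {Normal: 0.45, Osteopenia: 0.38, Osteoporosis: 0.90}
  link_slope: {PO4: 0.0, CO3: 0.08, AmideIII: 0.20, CH2: 0.11, AmideI: 0.14}
  surface_link_fraction: 0.25
  link_noise_sd: 0.8
  residual_sd: {PO4: 0.02, CO3: 0.06, AmideIII: 0.06, CH2: 0.06, AmideI: 0.06}
  surface_residual_multiplier: 2.0
  subsurface_weight: {0: 0.2, 3: 0.5, 6: 0.6}
  noise_sigma: 5.0
  cosmic_rate: 3.0
  n_frames: 5

detector:
  n_cols: 1024
  n_rows: 256
  smile_coeffs: [0.0, -0.004, 5.0e-5]
  gain_sigma: 0.03
  dark_level: 100.0
  laser_wavelength_nm: 830.0

cosmic:
  k_mad: 10.0
  n_lowest: 4
  mad_floor: null  # auto: 1.4 x median per-pixel MAD of the stack

fluorescence:
  poly_order: 7
  max_iter: 10
  tol: 5.0e-4

cv:
  rank_grid: [1, 2, 3, 4, 5, 6, 7, 8, 9]
  rank_selection: global

offsets: [0, 3]
cv_offsets: [0, 3]
test_method: mannwhitney
correction: bonferroni
normalize_predictors: true
noise_window: [1750.0, 1800.0]
calib_noise_sigma: 2.0
seed: 0
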