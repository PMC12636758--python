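"""Clean a stack of replicate spectra: spikes, averaging, baseline, clipping.

Five replicate exposures of the same site are combined: cosmic-ray spikes are
rejected wherever a replicate exceeds the mean of the four lowest values by
10 MAD; the replicates are averaged; fluorescence is removed by an iterative
order-7 modified polynomial fit; and residual negatives below the noise floor
are clipped at -0.5 sigma.
"""

import numpy as np

from sorsbone import FrameStack, clean_stack
from sorsbone.synthetic import BAND_CENTERS

rng = np.random.default_rng(7)
axis = np.linspace(650.0, 1820.0, 499)

truth = np.zeros_like(axis)
for band, center in BAND_CENTERS.items():
    amp = {"PO4": 1000.0, "CO3": 250.0, "AmideIII": 260.0, "CH2": 350.0, "AmideI": 450.0}[band]
    truth += amp * np.exp(-0.5 * ((axis - center) / 7.0) ** 2)
baseline = 1500.0 - 0.4 * (axis - 650.0) + 2.5e-4 * (axis - 650.0) ** 2

sigma = 15.0
stack = truth + baseline + rng.normal(0.0, sigma, (5, axis.size))
spike_pixels = rng.choice(axis.size, 6, replace=False)
stack[rng.integers(0, 5, 6), spike_pixels] += rng.uniform(500, 3000, 6)

clean = clean_stack(FrameStack(spectra=stack, shifts=axis))

flagged = int(clean.cosmic_mask.sum())
print(f"cosmic rays: {flagged} replicate values flagged (6 spikes were seeded)")
print(f"baseline:    converged in {clean.n_iterations} iterations")
print(f"noise floor: sigma = {clean.sigma_noise:.1f} counts "
      f"(true per-replicate sigma {sigma:.0f}, averaged over 5 frames -> {sigma/np.sqrt(5):.1f})")
po4 = clean.intensity[np.abs(axis - 960.0) < 15].max()
print(f"PO4 peak:    {po4:.0f} counts recovered (true 1000)")
print("\nThe cleaned spectrum is baseline-free with peaks at their true heights,")
print("ready for phosphate normalization and band ratios.")
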