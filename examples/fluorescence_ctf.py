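"""Corrected total fluorescence (CTF) of a stained region against background.

Builds a synthetic confocal-like image with a bright labelled vessel region
over autofluorescent background and quantifies the signal as
CTF = integrated intensity - ROI area x mean background fluorescence.
"""

import numpy as np

from vaskit import compute_ctf
from vaskit.fluorescence import normalize_to_controls

rng = np.random.default_rng(0)
image = rng.normal(20.0, 2.0, size=(128, 128))  # autofluorescent background
roi_mask = np.zeros_like(image, dtype=bool)
roi_mask[40:80, 30:100] = True
image[roi_mask] += 35.0  # labelled vessel signal
background_mask = np.zeros_like(image, dtype=bool)
background_mask[5:25, 5:120] = True

result = compute_ctf(image, roi_mask, background_mask)
print(f"integrated intensity: {result.integrated_intensity:.0f}")
print(f"ROI area: {result.roi_area_px} px, background mean: {result.background_mean:.2f}/px")
print(f"CTF: {result.ctf:.0f}")

# offset invariance: adding a constant to the whole image cancels exactly
shifted = compute_ctf(image + 100.0, roi_mask, background_mask)
print(f"CTF after +100 offset: {shifted.ctf:.0f} (unchanged)")

folds = normalize_to_controls([result.ctf], [result.ctf * 0.9, result.ctf * 1.1])
print(f"fold change vs controls: {folds[0]:.3f}")
print("-> CTF isolates the label's signal from uniform background and offsets.")
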