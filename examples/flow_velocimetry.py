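"""Kymograph velocimetry on a synthetic vessel recording with a flow reversal.

Simulates a vessel movie whose flow runs at +2 px/frame for the first half
and -2 px/frame for the second, builds and normalizes the kymograph along
the center line, and estimates the signed per-timepoint velocity.
"""

import numpy as np

from vaskit import (
    FlowSimParams,
    LineRoi,
    VelocimetryConfig,
    estimate_velocity_trace,
    extract_kymograph,
    normalize_kymograph,
    simulate_vessel_movie,
    summarize_vessel_velocity,
)

profile = tuple([2.0] * 100 + [-2.0] * 99)  # one mid-recording reversal
params = FlowSimParams(n_frames=200, velocity_profile=profile, seed=1)
stack = simulate_vessel_movie(params)

_, height, length = stack.shape
center = LineRoi(points=[(2, height / 2), (length - 3, height / 2)], kind="axial")
kymo = normalize_kymograph(extract_kymograph(stack, center))
trace = estimate_velocity_trace(kymo, VelocimetryConfig(section_frames=3, corr_threshold=0.8))
summary = summarize_vessel_velocity(trace)

speed_px = np.nanmedian(np.abs(trace.shift_px))
print(f"timepoints: {trace.n_timepoints}, valid: {100 * summary.valid_fraction:.1f}%")
print(f"median speed: {speed_px:.2f} px/frame = {np.nanmedian(np.abs(trace.velocity_um_s)):.2f} um/s")
print(f"maximum flow speed: {summary.v_max_um_s:.2f} um/s")
print(f"flow reversals detected: {summary.n_reversals}")
print("-> the estimator recovers the 2 px/frame speed, converts it with the")
print("   0.313 um/px / 0.177 s/frame calibration, and sees exactly one reversal.")
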