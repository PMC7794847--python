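"""Simulate one imaging session and run the calibration chain.

A session is an 80-minute time-lapse of probe fluorescence plus four
calibration frames (dark, pre-injection background, uniform phantom,
Rhodamine-equivalent standard). Calibration removes the camera offset,
tissue autofluorescence, the Gaussian beam profile, and day-to-day gain,
leaving frames in standard-equivalent units comparable across sessions.
"""

import numpy as np

from ivmquant import calibrate_session
from ivmquant.simulator import SimulationConfig, simulate_session

cfg = SimulationConfig(image_shape=(80, 105))
stack, cal, truth = simulate_session(cfg, seed=1)

print(f"raw stack: {len(stack)} frames of {stack.shape}, "
      f"t = {stack.times_min[0]:g}..{stack.times_min[-1]:g} min "
      f"(negative = pre-injection)")
print(f"raw 60-min frame mean: {stack.frame_at(60).mean():8.2f}  (camera units)")

out = calibrate_session(stack, cal)
i60 = list(out.times_min).index(60.0)
print(f"calibration factor: {out.calibration_factor:.5f}  "
      f"(standard-equivalent units per camera unit)")
print(f"chain applied: {' -> '.join(out.provenance)}")
print(f"calibrated 60-min frame mean: {out.frames[i60].mean():.4f}")
print(f"ground-truth expected mean:   {truth.calibrated_frame(i60).mean():.4f}")

resid = out.frames[i60] - truth.calibrated_frame(i60)
print(f"residual mean {resid.mean():+.2e} (shot noise only; "
      f"pixel sd {resid.std():.2e})")
# The calibrated mean matches the known simulated uptake field: the four
# instrument signatures have been removed, not the biology.
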