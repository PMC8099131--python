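"""Perspective (parallax) errors in step length across the walkway.

Simulates the same bout through a pinhole camera 3.3 m from the walking
plane.  Because the two legs sit at slightly different depths, perspective
magnifies them differently, and the error grows toward the edges of the
field of view: step lengths measured at left heel-strike drift one way
along the walkway while right-heel-strike steps drift the other way, and the
two largely cancel in the bout mean.
"""

import numpy as np

from gaitpose import SyntheticGaitSpec, detect_gait_events, simulate
from gaitpose.compare import bin_by_walkway
from gaitpose.preprocess import compute_scaling, preprocess_pose
from gaitpose.spatiotemporal import compute_step_table

spec = SyntheticGaitSpec(bout_length=6.0, camera_mode="pinhole")
pose, _, truth = simulate(spec)
pt_a, pt_b = truth.reference_points_px
cal = compute_scaling(pt_a, pt_b, spec.reference_distance_m)
ts, _ = preprocess_pose(pose, cal)
events = detect_gait_events(ts)
steps = compute_step_table(events, ts).steps
gt = truth.step_table.steps

print("per-step length error vs walkway position (camera-centered origin):")
positions, errors = [], []
center = (steps["walkway_position"].min() + steps["walkway_position"].max()) / 2
for _, row in steps.iterrows():
    match = gt[(gt["side"] == row["side"]) & (np.abs(gt["hs_time"] - row["hs_time"]) < 0.1)]
    if not len(match):
        continue
    err = row["step_length"] - match["step_length"].iloc[0]
    pos = row["walkway_position"] - center
    positions.append(pos)
    errors.append(err)
    print(f"  {row['side']:>5s} heel-strike at x = {pos:+.2f} m:  error {err:+.3f} m")

errors = np.array(errors)
print(f"\nbout-mean error {errors.mean():+.4f} m vs worst per-step error "
      f"{np.max(np.abs(errors)):.3f} m")
print("binned mean |error| (Start / Middle / End of walkway at +-0.50 m):")
for name, entry in bin_by_walkway(np.array(positions), np.abs(errors), center=0.0).items():
    print(f"  {name:6s} n={entry['n']}  {entry['mae']:.3f} m")
print("\nerrors flip sign across the walkway center, run opposite for left "
      "vs right steps, and largely cancel in the participant mean — the "
      "signature of perspective distortion in single-camera sagittal video.")
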