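# gaitpose

Two-dimensional video-based human gait analysis from pose-estimation
keypoints.

Clinical and research gait analysis traditionally needs a motion-capture
laboratory. Markerless pose estimation makes it possible to measure gait
from a single sagittal-view video: a pose network (e.g. OpenPose with the
BODY_25 model) emits per-frame pixel keypoints, and everything downstream is
signal processing. `gaitpose` implements that downstream workflow for
researchers and clinicians who want spatiotemporal gait parameters and
sagittal joint kinematics from ordinary video, together with the agreement
statistics needed to validate the video stream against optical motion
capture — plus a ground-truthed synthetic walker so the entire chain can be
tested end to end without recording anyone.

## What it computes

**Pipeline** (per walking bout, from per-frame BODY_25 JSON at a known frame
rate, camera side, and a pixel-space reference distance):

1. *Preprocessing* — coordinates re-expressed with +x along the direction of
   travel and +y up; automatic repair of frames where the pose estimator
   switched left/right leg identity; linear interpolation of detection gaps
   up to 2 frames (0.08–0.12 s at 25 Hz); zero-lag 4th-order low-pass
   Butterworth filtering at 5 Hz; scaling to meters via
   `s = reference_distance / reference_pixel_length`, `x_dim = s · x_pixel`.
2. *Gait events* — heel-strikes and toe-offs as the positive and negative
   peaks of the anterior–posterior ankle trajectory relative to the pelvis,
   `r(t) = x_ankle(t) − x_pelvis(t)` (midhip keypoint for video; mid
   ASIS/PSIS for markers).
3. *Spatiotemporal parameters* — per step: step time (consecutive bilateral
   heel-strikes), stance time (heel-strike to same-leg toe-off), swing time,
   double-support time (heel-strike to contralateral toe-off), step length
   (AP ankle separation at heel-strike); participant means and
   `gait speed = mean step length / mean step time`.
4. *Kinematics* — sagittal hip, knee and ankle angles (flexion/dorsiflexion
   positive), each stride resampled to a 101-point 0–100 % gait-cycle grid
   with ensemble mean ± SD.
5. *Agreement statistics* — paired event/step matching, mean ± SD of signed
   and absolute differences, Pearson r, two-way single-measure intraclass
   correlations ICC(C,1) and ICC(A,1), one-way repeated-measures ANOVA with
   Bonferroni post-hoc tests, lag-zero cross-correlation and MAE of cycle
   profiles, and walkway-position binning (Start/Middle/End at ±0.50 m).

**Simulator** — a forward-kinematic sagittal walker (periodic hip/knee/ankle
profiles, the legs half a stride out of phase) recorded by an orthographic or
pinhole camera at the geometry of a typical gait lab (25 Hz, 960×540, camera
3.3 m from the walking plane at 1.3 m height), with a synchronized 100 Hz
marker stream and exact ground-truth events, step table and angle profiles.
Defect injection reproduces the failure modes of real pose output: keypoint
noise, detection gaps, limb-identity swaps (~5 % of frames in practice) and
false-positive "people" (~20 % of frames).

## Worked example

```bash
python examples/simulate_and_analyze.py
```

prints (exact numbers, deterministic):

```
simulated 151 video frames at 25 Hz (6 m at 1 m/s)
detected 20 gait events; mean |error| vs ground truth = 1.1 ms

participant means (video pipeline vs programmed):
  step time        0.600 s   (true 0.600 s)
  step length      0.600 m   (true 0.600 m)
  gait speed       1.000 m/s (true 1.000 m/s)
  stance / swing   0.720 / 0.480 s
  double support   0.120 s

joint-angle cycle recovery (mean |error| over the 101-point cycle):
  hip    0.06 deg
  knee   0.05 deg
  ankle  0.02 deg
```

The pipeline recovers the programmed bout to within ~1 ms in event timing,
sub-millimeter in mean step length, and well under a degree in the joint
angle cycles. `examples/agreement_statistics.py` runs a ten-participant
simulated validation study (video vs marker stream) and prints the
difference/ICC/ANOVA tables; `examples/parallax_demo.py` shows how
perspective makes per-step length errors flip sign across the walkway while
canceling in the bout mean.

The same pipeline runs from the shell:

```bash
gaitpose simulate --out fixture --seed 1      # synthetic bout + ground truth
gaitpose analyze --config fixture/analysis_config.yaml
gaitpose compare fixture/analysis other_run/analysis --out report.json
```

Marker CSV convention for the motion-capture stand-in: a `time` column plus
`<name>_x` / `<name>_y` columns in meters, with at least `hip_L/R`,
`knee_L/R`, `ankle_L/R`, `toe_L/R`, `pelvis` and `trunk` (C7-equivalent).

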