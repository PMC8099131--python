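# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `gaitpose`. It is written for users who need to judge
whether the pipeline's assumptions hold for their own recordings.

## Coordinate conventions and scaling

Pose keypoints arrive in image coordinates (origin upper-left, y downward).
All analysis happens in a *walking frame*: +x along the direction of travel,
+y up. For a left-side sagittal view the origin is placed at the lower-right
image corner (`x' = width − x`, `y' = height − y`); for a right-side view at
the lower-left (`x' = x`, `y' = height − y`). Every downstream quantity is
invariant to translation (events, lengths, angles) and to uniform scaling
(events, angles), so the origin choice is immaterial; only step length and
gait speed depend on the pixel-to-meter scale.

The scale is a single factor `s = reference_distance / reference_pixel_length`
(m/px), taken from the horizontal pixel separation of two floor landmarks a
known distance apart (default 6.30 m, the walkway-tape separation of the
recording setup the defaults emulate). Applying one global scale assumes the
participant walks perpendicular to the optical axis at the depth of the
reference — the pinhole simulations below quantify what breaks when that
assumption fails. Lens distortion and depth-varying scale are out of scope.

## Limb-swap correction

Pose estimators intermittently exchange the left/right identity of the leg
keypoints (hip, knee, ankle, heel, big toe, small toe) — around 5 % of
frames in practice. The corrector chooses, per frame, the assignment (keep
or swap) that minimizes the summed distance of both legs' ankle and knee
points from their constant-velocity predictions. Velocity extrapolation is
what makes leg crossings decidable: twice per stride the two legs occupy
nearly the same image region (in our simulations every leg landmark pair
comes within ~10 px), but they move in opposite directions at ~10–15 px per
frame at 25 Hz, well above the few-px noise of the velocity estimate.

Two safeguards matter in the noisy regime:

* *Deferral at ambiguous frames.* When the keep and swap costs differ by
  less than 25 % of their sum (a crossing), the frame receives a provisional
  label but does not update the reference; the next clear frame is then
  judged by extrapolation from before the crossing, where the legs were
  separable. References are force-refreshed after 4 frames so the tracker
  cannot deadlock on stale predictions.
* *Majority-parity flip.* Continuity alone cannot fix a global label
  exchange: if the anchor frame itself carried swapped labels, the pass
  makes the whole bout consistent with the wrong parity. Since genuine swaps
  are sparse, ending with the majority of frames "swapped" signals a wrong
  anchor, and the entire labeling is flipped once. This also resolves the
  ambiguous-first-frame case.

An earlier design used a forward pass plus a backward consistency pass; the
backward pass was removed after it proved harmful — starting fresh from the
record end, a single wrong call at a crossing propagates coherently over
half the bout, whereas the deferral + parity scheme above kept the worst
participant-mean step-time error at 15 ms over thirty simulated bouts with
2 px noise and 5 % injected swaps.

Frames where both ankle keypoints land on the same leg (closer than 5 px,
both confident) have the lower-confidence leg's keypoints marked missing;
the 5 px threshold is a free parameter (real validation work corrected such
frames by eye without stating a criterion) and is configurable.

## Gap filling and filtering

Missing keypoints (confidence ≤ 0 by default; the threshold is configurable)
are linearly interpolated across runs of at most 2 frames bounded by valid
samples — 0.08 s between anchors at 25 Hz, matching the common "gaps up to
0.12 s" rule when the bounding interval is counted. Longer and boundary runs
stay missing, and valid samples are never altered.

Trajectories are filtered with a 4th-order low-pass Butterworth at 5 Hz
applied forward and backward (`filtfilt`): zero phase, exact unit DC gain,
and an effective 8th-order magnitude. "Zero-lag 4th order" is ambiguous in
the gait literature (4th-order design run bidirectionally vs a 2nd-order
design squared); this package fixes the former and exposes the order. Spans
shorter than the filter warm-up (15 samples) are left unfiltered with a
warning. Gait's fundamental at comfortable speed is ~0.8 Hz, so the passband
deviation for real gait content is below 1 %.

## Event detection

Heel-strike and toe-off are defined kinematically: with +x along travel, the
ankle is farthest ahead of the pelvis at heel-strike and farthest behind at
toe-off, so events are the positive/negative peaks of
`r(t) = x_ankle − x_pelvis` (midhip keypoint for pose; mid-ASIS/PSIS,
i.e. the `pelvis` marker, for motion capture). Peaks must be separated by at
least 0.4 s (healthy stride times are ~1.0–1.4 s; the floor guards against
noise doublets without excluding fast walking) and must have prominence of
at least 25 % of the robust amplitude of `r` (half the 5th–95th percentile
span — insensitive to isolated spikes). Event time is the sample time of the
peak frame; no sub-frame interpolation is attempted, so single-event timing
error is bounded by half a frame (20 ms at 25 Hz).

Events within one filter warm-up length (0.6 s at 25 Hz) of the record edges
are flagged `boundary`. Overground bouts include gait initiation and
termination, where steady-state definitions are unreliable; boundary-flagged
events stay in the event tables but steps touching them are excluded from
participant means by default (configurable).

## Spatiotemporal parameters

A *right step* ends at right heel-strike. Per step: step time = time from
the preceding contralateral heel-strike; stance = to the same leg's next
toe-off; swing = that toe-off to the same leg's next heel-strike;
double-support = to the contralateral leg's next toe-off (the first of the
two double-support phases of the stride — not the per-stride sum; the
participant-mean value of ~0.12–0.14 s should be read accordingly); step
length = leading-minus-trailing AP ankle separation at the heel-strike.
Gait speed is mean step length over mean step time, an exact identity of
the participant means. Walkway position is the AP trunk-reference (C7/neck)
position at the heel-strike.

## Joint angles

All angles are planar, in degrees, flexion/dorsiflexion positive:

* **hip** — signed angle of the thigh vector (hip→knee) from vertical-down;
  positive when the knee is forward of the hip.
* **knee** — signed angle between thigh and shank (knee→ankle) vectors;
  positive when the ankle falls behind the thigh line.
* **ankle** — signed angle between the foot vector (ankle→big toe) and the
  forward perpendicular of the shank. Neutral (0°) is a foot perpendicular
  to the shank — horizontal when the shank is vertical:

```
        knee ●
             |          shank (knee→ankle)
             |
       ankle ●────────● big toe     ← 0°: foot ⟂ shank
              \
               ● toes raised        ← dorsiflexion, positive
```

The ankle convention reconciles "0° is horizontal" phrasing with the use of
the shank as the reference segment; it is stated here as this package's
definition rather than inferred from any source. Both data streams use the
same hip/knee/ankle/toe landmarks (no hip-joint-center regression for the
marker stream; with markers placed on comparable landmarks this contributes
a small systematic offset, not a cycle-shape error).

Each same-side heel-strike-to-heel-strike stride is linearly resampled to
101 points (0–100 % in 1 % steps — the field convention), preserving
endpoint values exactly; the participant profile is the ensemble mean ± SD
across strides.

## Agreement statistics

Event lists and step rows from two systems are paired by greedy
nearest-neighbor matching within half the median step time; on gait-sized
instances this equals the exhaustive minimal-cost assignment (verified
against `linear_sum_assignment` in the tests). The ICCs are the McGraw–Wong
two-way single-measure forms computed from the mean squares (subjects MS_R,
raters MS_C, error MS_E, k raters):

    ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E)
    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with significance from F = MS_R/MS_E on (n−1, (n−1)(k−1)) degrees of
freedom. With no subject variance the coefficients are undefined and
returned as NaN (as is Pearson r for a zero-variance vector). The
repeated-measures ANOVA is the classical within-subject one-way form with no
sphericity correction (k = 3 systems; with two effective comparisons the
correction is minor and its omission is documented rather than silently
applied); post-hoc tests are paired t-tests with p multiplied by the number
of comparisons and capped at 1. Cycle profiles are compared by mean absolute
error and by Pearson-normalized cross-correlation at lag zero. Per-stride
records are binned by mean AP trunk position into Start (< −0.50 m of the
walkway center), Middle (±0.50 m) and End (> +0.50 m); the center defaults
to the midrange of the observed positions. Difference ranges are raw
min/max with no outlier exclusion.

## The synthetic walker

The generator emulates the recording conditions the pipeline targets: a ~5 m
overground bout at 1.0 m/s (0.6 s steps, 0.6 m step length), 25 Hz 960×540
sagittal video with the camera 3.3 m from the walking plane at 1.3 m height,
and a synchronized 100 Hz marker stream sharing t = 0 (every fourth marker
sample coincides with a video frame).

The pelvis translates at constant speed; hip, knee and ankle follow
parametric sinusoid sums of the stride phase, the two legs offset by half a
stride, and the leg keypoints are placed by forward kinematics (thigh and
shank 0.42 m, foot 0.25 m). The hip profile carries a second harmonic
(relative weight 0.309) that places the minimum of the relative ankle
trajectory ~60 % of the cycle after its maximum — i.e. a realistic 60/40
stance/swing split with ~0.12 s double support; a single harmonic would put
toe-off exactly half a cycle after heel-strike and make double-support time
degenerate. The hip amplitude is solved (Brent's method) so the model's step
length equals the requested value; amplitudes default to physiological
ranges (knee 5–45°, ankle ±10°). Profiles are strictly periodic: there is no
stride-to-stride variability, so between-step variance in clean simulations
is zero and per-step ICCs on a single clean bout are undefined by
construction (the agreement example instead varies parameters across
simulated participants).

Ground-truth events are the programmed extrema of the relative AP ankle
trajectory — the same definition the detector uses — located on the
continuous model by dense sampling plus bounded scalar minimization
(tolerance 1e-12), so ground-truth heel-strikes are exactly one step time
apart, alternating sides. The default first heel-strike falls at 0.32 s,
which lies on the video frame grid at the default rates; programmed events
then coincide with frames, and detector error reflects the method rather
than deliberate clock misalignment (set `first_hs_time` off-grid to study
quantization). The ground-truth step table is computed from the exact model
positions with the same definitions as the analysis module, so it satisfies
all stride identities to machine precision.

The orthographic camera (0.008 m/px) is the clean baseline. The pinhole
camera projects through a focal length of 480 px with the two legs offset
±0.10 m in depth from the mid-sagittal plane (the near leg is the one on the
camera's side). This reproduces the parallax phenomenology of real sagittal
video: per-step length errors grow linearly toward the walkway ends
(~±0.15 m at ±2.4 m for the default geometry), run in opposite directions
for left-heel-strike vs right-heel-strike steps, cross zero at the walkway
center, and largely cancel in the bout mean.

Defect injection (seeded, fully logged) adds Gaussian pixel noise, drops
keypoints in runs of 1–2 frames, exchanges leg labels, and appends a static
4-keypoint false person of the kind a tripod produces; observed real-world
rates (~5 % swapped frames, ~20 % false-person frames) are provided as
constants. The marker stream is always clean — it stands in for the
motion-capture gold standard, which arrives pre-smoothed.

What passing the synthetic tests does *not* show: robustness to the error
structure of real pose estimators (correlated, pose-dependent,
heavy-tailed, clothing- and lighting-sensitive), to camera tilt or lens
distortion, to soft-tissue and marker-placement error in the reference
stream, or to pathological gait. The simulator validates the *processing*
chain, not the pose network.

## Problem sizes and determinism

Recovery runs use a 6 m bout (151 video frames, ≥8 full steps at the default
0.6 m steps); swap-repair runs use a 40 m bout (1001 frames) so that a 5 %
swap rate yields ~50 injected events; the statistical oracles use 20 random
instances of n ≤ 10. Each piece completes in seconds. All randomness flows
from a single integer seed through `numpy.random.default_rng`; identical
configuration and seed give bit-identical output files, and every output
embeds a hash of the scientific configuration (paths excluded) for
provenance.
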