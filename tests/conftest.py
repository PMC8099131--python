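"""Shared fixtures: simulated bouts and full pipeline runs.

Everything is generated programmatically; the default study conditions are a
~1.0 m/s overground bout with 0.6 s steps recorded at 25 Hz from a sagittal
view, with a simultaneous 100 Hz marker stream.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitpose import SyntheticGaitSpec, detect_gait_events, simulate
from gaitpose.kinematics import joint_angle_series, normalize_strides
from gaitpose.preprocess import compute_scaling, preprocess_pose
from gaitpose.spatiotemporal import compute_step_table, participant_summary


@pytest.fixture(scope="session")
def bout_spec() -> SyntheticGaitSpec:
    """Noiseless orthographic bout long enough for >= 8 full steps."""
    return SyntheticGaitSpec(bout_length=6.0)


@pytest.fixture(scope="session")
def sim_bout(bout_spec):
    return simulate(bout_spec)


class PipelineRun:
    """Full pipeline output on one simulated pose stream."""

    def __init__(self, spec, pose, truth):
        self.spec = spec
        self.truth = truth
        pt_a, pt_b = truth.reference_points_px
        self.calibration = compute_scaling(pt_a, pt_b, spec.reference_distance_m)
        self.trajectories, self.preprocess_report = preprocess_pose(
            pose, self.calibration
        )
        self.events = detect_gait_events(self.trajectories)
        self.step_table = compute_step_table(self.events, self.trajectories)
        self.summary = participant_summary(self.step_table)
        self.angles = joint_angle_series(self.trajectories)
        self.cycles = normalize_strides(self.angles, self.events, self.trajectories)


@pytest.fixture(scope="session")
def pipeline_run(bout_spec, sim_bout) -> PipelineRun:
    pose, _markers, truth = sim_bout
    return PipelineRun(bout_spec, pose, truth)


@pytest.fixture(scope="session")
def pinhole_run() -> PipelineRun:
    spec = SyntheticGaitSpec(bout_length=6.0, camera_mode="pinhole")
    pose, _markers, truth = simulate(spec)
    return PipelineRun(spec, pose, truth)


def event_errors(truth_events, detected_events) -> dict[tuple[str, str], np.ndarray]:
    """Absolute time differences between each ground-truth event and its
    nearest detected event of the same side and type."""
    from gaitpose import match_events

    out = {}
    for side in ("left", "right"):
        for event_type, getter in (
            ("heel_strike", "heel_strikes"),
            ("toe_off", "toe_offs"),
        ):
            true_times = getattr(truth_events, getter)(side)
            det_times = getattr(detected_events, getter)(side)
            matched = match_events(true_times, det_times, tolerance_s=0.3)
            if len(matched.a) < len(true_times):
                # unmatched ground-truth events count as gross failures
                out[(side, event_type)] = np.full(len(true_times), np.inf)
            else:
                out[(side, event_type)] = np.abs(matched.a - matched.b)
    return out
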