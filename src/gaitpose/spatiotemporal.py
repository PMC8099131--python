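"""Per-step and participant-mean spatiotemporal gait parameters.

Definitions (all per step, a step being the interval ending at a heel-strike
of the named side; a "right step" ends at right heel-strike):

* step time: duration between consecutive bilateral heel-strikes;
* stance time: heel-strike to toe-off of the same leg;
* swing time: toe-off to next heel-strike of the same leg;
* double support time: heel-strike of one leg to toe-off of the contralateral
  leg (the first of the stride's two double-support phases);
* step length: anterior-posterior distance between the two ankles at the
  heel-strike that ends the step (leading minus trailing, so positive for
  forward steps);
* gait speed: mean step length divided by mean step time, computed from the
  participant means (an exact identity, not an average of per-step speeds).

``walkway_position`` records the anterior-posterior position of the trunk
reference (C7 marker / neck keypoint) at the step's heel-strike, used for the
positional error analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .events import GaitEvents
from .preprocess import TrajectorySet

logger = logging.getLogger(__name__)

STEP_COLUMNS = [
    "side",
    "hs_time",
    "step_time",
    "stance_time",
    "swing_time",
    "double_support_time",
    "step_length",
    "walkway_position",
    "boundary",
]

#: signature: lookup(landmark_name, times) -> anterior-posterior positions
PositionLookup = Callable[[str, np.ndarray], np.ndarray]


@dataclass
class StepTable:
    """Per-step spatiotemporal records; see module docstring for definitions."""

    steps: pd.DataFrame
    log: list[str] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def included(self, exclude_boundary: bool = True) -> pd.DataFrame:
        if exclude_boundary and len(self.steps):
            return self.steps.loc[~self.steps["boundary"].astype(bool)]
        return self.steps


def trajectory_lookup(ts: TrajectorySet) -> PositionLookup:
    """Anterior-posterior position lookup that linearly interpolates a
    :class:`TrajectorySet` at arbitrary times (missing samples skipped)."""

    def lookup(name: str, times: np.ndarray) -> np.ndarray:
        x = ts.x(name)
        valid = np.isfinite(x)
        if not valid.any():
            return np.full(np.shape(times), np.nan)
        return np.interp(np.asarray(times, dtype=float), ts.time[valid], x[valid])

    return lookup


def _next_after(times: np.ndarray, t: float) -> float:
    later = times[times > t + 1e-12]
    return float(later[0]) if len(later) else np.nan


def _prev_before(times: np.ndarray, t: float) -> float:
    earlier = times[times < t - 1e-12]
    return float(earlier[-1]) if len(earlier) else np.nan


def compute_step_table(
    events: GaitEvents,
    trajectories: TrajectorySet | PositionLookup,
    *,
    trunk_landmark: str = "neck",
) -> StepTable:
    """Build the per-step table from gait events and ankle/trunk trajectories.

    ``trajectories`` may be a :class:`TrajectorySet` or a bare position-lookup
    callable (the simulator passes its exact continuous model).  Steps whose
    step time cannot be formed (no preceding contralateral heel-strike) are
    omitted with a log entry; steps touching any boundary-flagged event are
    kept but flagged so participant means can exclude them.
    """
    lookup = (
        trajectory_lookup(trajectories)
        if isinstance(trajectories, TrajectorySet)
        else trajectories
    )
    hs = {s: events.heel_strikes(s) for s in ("left", "right")}
    to = {s: events.toe_offs(s) for s in ("left", "right")}
    if len(hs["left"]) + len(hs["right"]) < 2:
        return StepTable(
            steps=pd.DataFrame(columns=STEP_COLUMNS),
            log=["fewer than two heel-strikes; no steps"],
        )

    suffix = {"left": "L", "right": "R"}
    rows = []
    log: list[str] = []
    for side in ("left", "right"):
        contra = "right" if side == "left" else "left"
        for t in hs[side]:
            prev_contra_hs = _prev_before(hs[contra], t)
            if np.isnan(prev_contra_hs):
                log.append(f"{side} heel-strike at {t:.3f}s: no preceding "
                           f"contralateral heel-strike; step omitted")
                continue
            step_time = t - prev_contra_hs
            next_to_same = _next_after(to[side], t)
            next_hs_same = _next_after(hs[side], t)
            stance = next_to_same - t if not np.isnan(next_to_same) else np.nan
            if not np.isnan(next_to_same) and not np.isnan(next_hs_same):
                swing = next_hs_same - next_to_same
            else:
                swing = np.nan
            next_to_contra = _next_after(to[contra], t)
            double_support = (
                next_to_contra - t if not np.isnan(next_to_contra) else np.nan
            )
            ankle_lead = float(lookup(f"ankle_{suffix[side]}", np.array([t]))[0])
            ankle_trail = float(lookup(f"ankle_{suffix[contra]}", np.array([t]))[0])
            step_length = ankle_lead - ankle_trail
            walkway = float(lookup(trunk_landmark, np.array([t]))[0])
            boundary = events.is_boundary(side, "heel_strike", t) or events.is_boundary(
                contra, "heel_strike", prev_contra_hs
            )
            if not np.isnan(next_to_same):
                boundary = boundary or events.is_boundary(side, "toe_off", next_to_same)
            if not np.isnan(next_hs_same):
                boundary = boundary or events.is_boundary(side, "heel_strike", next_hs_same)
            if not np.isnan(next_to_contra):
                boundary = boundary or events.is_boundary(contra, "toe_off", next_to_contra)
            rows.append(
                {
                    "side": side,
                    "hs_time": t,
                    "step_time": step_time,
                    "stance_time": stance,
                    "swing_time": swing,
                    "double_support_time": double_support,
                    "step_length": step_length,
                    "walkway_position": walkway,
                    "boundary": bool(boundary),
                }
            )
    steps = pd.DataFrame(rows, columns=STEP_COLUMNS)
    steps = steps.sort_values("hs_time").reset_index(drop=True)
    return StepTable(steps=steps, log=log)


def participant_summary(
    table: StepTable, exclude_boundary: bool = True
) -> dict[str, float]:
    """Participant means of each parameter plus gait speed.

    Gait speed is the mean step length divided by the mean step time, exactly
    (computed from the participant means, not averaged per step).
    """
    df = table.included(exclude_boundary)
    out: dict[str, float] = {"n_steps": int(len(df))}
    for col in (
        "step_time",
        "stance_time",
        "swing_time",
        "double_support_time",
        "step_length",
        "walkway_position",
    ):
        values = df[col].to_numpy(dtype=float) if len(df) else np.array([])
        values = values[np.isfinite(values)]
        out[col] = float(np.mean(values)) if len(values) else np.nan
    if out["step_time"] and np.isfinite(out["step_time"]) and out["step_time"] > 0:
        out["gait_speed"] = out["step_length"] / out["step_time"]
    else:
        out["gait_speed"] = np.nan
    return out


__all__ = [
    "StepTable",
    "STEP_COLUMNS",
    "compute_step_table",
    "participant_summary",
    "trajectory_lookup",
]
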