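"""Sagittal hip, knee and ankle angles and stride-normalized cycle profiles.

Angle conventions (walking frame: +x travel direction, +y up; all angles in
degrees):

* hip: signed angle of the thigh vector (hip -> knee) from vertical-down;
  0 deg with the thigh vertical, flexion (knee forward of hip) positive,
  extension negative.
* knee: signed angle between the thigh vector and the shank vector
  (knee -> ankle); 0 deg with the leg straight, flexion (ankle behind the
  thigh line) positive.
* ankle: signed angle between the foot vector (ankle -> big toe) and the
  forward perpendicular of the shank; 0 deg when the foot is perpendicular to
  the shank (i.e. horizontal when the shank is vertical), dorsiflexion (toes
  toward the shin) positive, plantarflexion negative.

All three are invariant to translating and uniformly scaling the
coordinates, so they can be computed before or after dimensionalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import GaitEvents
from .preprocess import TrajectorySet

logger = logging.getLogger(__name__)

JOINTS = ("hip", "knee", "ankle")
SIDES = ("L", "R")


def _segment_angle_from_vertical(v: np.ndarray) -> np.ndarray:
    """Signed angle (deg) of a segment vector from the downward vertical;
    positive when the distal end is forward (+x) of the proximal end."""
    return np.degrees(np.arctan2(v[..., 0], -v[..., 1]))


def joint_angle_series(ts: TrajectorySet) -> pd.DataFrame:
    """Per-frame hip/knee/ankle angles for both legs.

    Returns a DataFrame with a ``time`` column and ``{joint}_{L,R}`` angle
    columns in degrees.  Frames with a missing contributing landmark yield
    NaN for the affected joint.
    """
    out = {"time": ts.time.copy()}
    for side in SIDES:
        hip = ts.data[f"hip_{side}"]
        knee = ts.data[f"knee_{side}"]
        ankle = ts.data[f"ankle_{side}"]
        toe = ts.data[f"big_toe_{side}"]

        thigh = knee - hip
        shank = ankle - knee
        foot = toe - ankle

        theta_thigh = _segment_angle_from_vertical(thigh)
        theta_shank = _segment_angle_from_vertical(shank)
        out[f"hip_{side}"] = theta_thigh
        out[f"knee_{side}"] = theta_thigh - theta_shank

        # forward perpendicular of the shank: rotate the shank direction
        # d by +90 deg -> p = (-d_y, d_x); for a vertical shank p = +x.
        p = np.stack([-shank[:, 1], shank[:, 0]], axis=1)
        cross = p[:, 0] * foot[:, 1] - p[:, 1] * foot[:, 0]
        dot = p[:, 0] * foot[:, 0] + p[:, 1] * foot[:, 1]
        out[f"ankle_{side}"] = np.degrees(np.arctan2(cross, dot))
    return pd.DataFrame(out)


CYCLE_COLUMNS = [
    "side",
    "joint",
    "stride",
    "hs_time",
    "walkway_position",
    "cycle_pct",
    "angle_deg",
]


@dataclass
class JointAngleCycles:
    """Stride-cycle-normalized joint angle profiles.

    ``cycles`` maps ``(side, joint)`` -> ``(n_strides, n_samples)`` arrays on
    the 0-100% gait-cycle grid; ``mean``/``sd`` hold the participant ensemble
    statistics; ``stride_hs_times`` and ``stride_positions`` give, per side,
    the heel-strike time starting each stride and the mean anterior-posterior
    trunk position over the stride.
    """

    pct: np.ndarray
    cycles: dict[tuple[str, str], np.ndarray]
    stride_hs_times: dict[str, np.ndarray]
    stride_positions: dict[str, np.ndarray]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.pct)

    def n_strides(self, side: str) -> int:
        return len(self.stride_hs_times.get(side, ()))

    def mean(self, side: str, joint: str) -> np.ndarray:
        return self.cycles[(side, joint)].mean(axis=0)

    def sd(self, side: str, joint: str) -> np.ndarray:
        return self.cycles[(side, joint)].std(axis=0, ddof=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (side, joint), arr in sorted(self.cycles.items()):
            for k in range(arr.shape[0]):
                hs_t = self.stride_hs_times[side][k]
                pos = self.stride_positions[side][k]
                for pct, angle in zip(self.pct, arr[k]):
                    rows.append(
                        {
                            "side": side,
                            "joint": joint,
                            "stride": k,
                            "hs_time": hs_t,
                            "walkway_position": pos,
                            "cycle_pct": pct,
                            "angle_deg": angle,
                        }
                    )
        return pd.DataFrame(rows, columns=CYCLE_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "JointAngleCycles":
        missing = set(CYCLE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"angle-cycle table missing columns: {sorted(missing)}")
        pct = np.sort(frame["cycle_pct"].unique())
        cycles: dict[tuple[str, str], np.ndarray] = {}
        hs_times: dict[str, np.ndarray] = {}
        positions: dict[str, np.ndarray] = {}
        for (side, joint), grp in frame.groupby(["side", "joint"]):
            strides = np.sort(grp["stride"].unique())
            arr = np.full((len(strides), len(pct)), np.nan)
            for i, k in enumerate(strides):
                g = grp[grp["stride"] == k].sort_values("cycle_pct")
                arr[i] = g["angle_deg"].to_numpy(float)
            cycles[(side, joint)] = arr
            if side not in hs_times:
                per_stride = (
                    grp.groupby("stride")[["hs_time", "walkway_position"]]
                    .first()
                    .sort_index()
                )
                hs_times[side] = per_stride["hs_time"].to_numpy(float)
                positions[side] = per_stride["walkway_position"].to_numpy(float)
        return cls(
            pct=pct.astype(float),
            cycles=cycles,
            stride_hs_times=hs_times,
            stride_positions=positions,
        )


def normalize_strides(
    angles: pd.DataFrame,
    events: GaitEvents,
    ts: TrajectorySet | None = None,
    *,
    n_samples: int = 101,
    exclude_boundary: bool = True,
    trunk_landmark: str = "neck",
) -> JointAngleCycles:
    """Resample each same-side heel-strike-to-heel-strike stride onto a fixed
    0-100% gait-cycle grid and form the participant ensemble mean and SD.

    Linear resampling preserves the stride endpoint values exactly.  Strides
    whose bounding heel-strikes carry a boundary flag are excluded by
    default.  With zero complete strides the result is empty with a warning.
    """
    pct = np.linspace(0.0, 100.0, n_samples)
    time = angles["time"].to_numpy(float)
    cycles: dict[tuple[str, str], np.ndarray] = {}
    hs_times: dict[str, np.ndarray] = {}
    positions: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    for side_name, suffix in (("left", "L"), ("right", "R")):
        hs = events.heel_strikes(side_name, include_boundary=True)
        strides = []
        for t0, t1 in zip(hs[:-1], hs[1:]):
            if exclude_boundary and (
                events.is_boundary(side_name, "heel_strike", t0)
                or events.is_boundary(side_name, "heel_strike", t1)
            ):
                continue
            strides.append((t0, t1))
        if not strides:
            warnings.append(f"{side_name}: zero complete strides")
            hs_times[side_name] = np.array([])
            positions[side_name] = np.array([])
            for joint in JOINTS:
                cycles[(side_name, joint)] = np.empty((0, n_samples))
            continue
        hs_times[side_name] = np.array([t0 for t0, _ in strides])
        pos = []
        for t0, t1 in strides:
            if ts is not None and trunk_landmark in ts.data:
                xs = ts.x(trunk_landmark)
                m = np.isfinite(xs) & (ts.time >= t0) & (ts.time <= t1)
                pos.append(float(np.mean(xs[m])) if m.any() else np.nan)
            else:
                pos.append(np.nan)
        positions[side_name] = np.array(pos)
        for joint in JOINTS:
            series = angles[f"{joint}_{suffix}"].to_numpy(float)
            valid = np.isfinite(series)
            arr = np.full((len(strides), n_samples), np.nan)
            for k, (t0, t1) in enumerate(strides):
                grid = t0 + pct / 100.0 * (t1 - t0)
                if valid.any():
                    arr[k] = np.interp(grid, time[valid], series[valid])
            cycles[(side_name, joint)] = arr
    if all(len(v) == 0 for v in hs_times.values()):
        logger.warning("normalize_strides: no complete strides on either side")
    return JointAngleCycles(
        pct=pct,
        cycles=cycles,
        stride_hs_times=hs_times,
        stride_positions=positions,
        warnings=warnings,
    )


__all__ = [
    "JOINTS",
    "joint_angle_series",
    "JointAngleCycles",
    "normalize_strides",
    "CYCLE_COLUMNS",
]
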