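"""Coordinate-based gait event detection.

Heel-strikes and toe-offs are identified from the anterior-posterior
trajectory of each ankle relative to the pelvis: with +x in the direction of
travel, the ankle is farthest ahead of the pelvis at heel-strike and farthest
behind at toe-off, so positive peaks of ``r(t) = x_ankle(t) - x_pelvis(t)``
mark heel-strikes and negative peaks mark toe-offs.  The pelvis reference is
the midhip keypoint for pose data and the mid-ASIS/PSIS point (``pelvis``
marker) for motion capture.

Detection is invariant to translating or uniformly scaling the coordinates,
so it can run on pixel or metric trajectories alike.  Event times are the
sample times of the peak frames; no sub-frame interpolation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import TrajectorySet, fill_gaps_series, filter_warmup_samples

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["side", "event_type", "time_s", "frame_index", "boundary"]


@dataclass
class GaitEvents:
    """Timestamped left/right heel-strikes and toe-offs.

    ``frame`` holds one row per event with columns ``side`` (left/right),
    ``event_type`` (heel_strike/toe_off), ``time_s``, ``frame_index`` and a
    ``boundary`` flag marking events close to the record edges (within one
    filter warm-up length by default), which are excluded from parameter
    computation downstream.
    """

    frame: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def empty(cls, warnings: list[str] | None = None) -> "GaitEvents":
        return cls(
            frame=pd.DataFrame(columns=EVENT_COLUMNS), warnings=warnings or []
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GaitEvents":
        missing = set(EVENT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        return cls(frame=frame.reset_index(drop=True))

    @classmethod
    def from_times(
        cls,
        heel_strikes: dict[str, np.ndarray],
        toe_offs: dict[str, np.ndarray],
        boundary: dict | None = None,
        frame_rate: float | None = None,
    ) -> "GaitEvents":
        """Build events from per-side time arrays (used by the simulator and
        in tests)."""
        rows = []
        for event_type, per_side in (
            ("heel_strike", heel_strikes),
            ("toe_off", toe_offs),
        ):
            for side, times in per_side.items():
                for t in np.sort(np.asarray(times, dtype=float)):
                    flag = False
                    if boundary is not None:
                        flag = bool(boundary.get((side, event_type, float(t)), False))
                    rows.append(
                        {
                            "side": side,
                            "event_type": event_type,
                            "time_s": float(t),
                            "frame_index": (
                                int(round(t * frame_rate)) if frame_rate else -1
                            ),
                            "boundary": flag,
                        }
                    )
        frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        frame = frame.sort_values(["side", "event_type", "time_s"]).reset_index(
            drop=True
        )
        return cls(frame=frame)

    def _times(
        self, side: str, event_type: str, include_boundary: bool
    ) -> np.ndarray:
        df = self.frame
        sel = (df["side"] == side) & (df["event_type"] == event_type)
        if not include_boundary:
            sel &= ~df["boundary"].astype(bool)
        return np.sort(df.loc[sel, "time_s"].to_numpy(dtype=float))

    def heel_strikes(self, side: str, include_boundary: bool = True) -> np.ndarray:
        return self._times(side, "heel_strike", include_boundary)

    def toe_offs(self, side: str, include_boundary: bool = True) -> np.ndarray:
        return self._times(side, "toe_off", include_boundary)

    def is_boundary(self, side: str, event_type: str, time_s: float) -> bool:
        df = self.frame
        sel = (
            (df["side"] == side)
            & (df["event_type"] == event_type)
            & (np.isclose(df["time_s"], time_s))
        )
        return bool(df.loc[sel, "boundary"].any())

    @property
    def n_events(self) -> int:
        return len(self.frame)

    def validate_alternation(self) -> list[dict]:
        """Check that consecutive same-side heel-strikes bracket exactly one
        toe-off.  Violations are reported, not silently fixed."""
        violations = []
        for side in ("left", "right"):
            hs = self.heel_strikes(side)
            to = self.toe_offs(side)
            for t0, t1 in zip(hs[:-1], hs[1:]):
                n_to = int(np.sum((to > t0) & (to < t1)))
                if n_to != 1:
                    violations.append(
                        {"side": side, "between": (float(t0), float(t1)), "n_toe_offs": n_to}
                    )
        return violations


def _relative_ap(ts: TrajectorySet, side: str, pelvis_landmark: str) -> np.ndarray:
    r = ts.x(f"ankle_{side}") - ts.x(pelvis_landmark)
    # Internal gaps are bridged for peak picking only; the stored
    # trajectories are not modified.
    return fill_gaps_series(r, max_gap_frames=len(r))


def detect_gait_events(
    ts: TrajectorySet,
    *,
    pelvis_landmark: str = "pelvis",
    min_period_s: float = 0.4,
    prominence_frac: float = 0.25,
    boundary_margin_s: float | None = None,
) -> GaitEvents:
    """Detect heel-strikes and toe-offs for both legs.

    Parameters
    ----------
    ts:
        Walking-frame trajectories containing ``ankle_L``/``ankle_R`` and the
        pelvis reference landmark.
    min_period_s:
        Minimum separation between same-type events on one side; default 0.4 s
        (comfortably below the ~1.2 s stride times of healthy adults walking
        at ~1 m/s, but above half a stride).
    prominence_frac:
        Required peak prominence as a fraction of the robust amplitude of the
        relative ankle trajectory (half the 5th-95th percentile span).
    boundary_margin_s:
        Events within this margin of the record edges are flagged
        ``boundary``; default is one filter warm-up length.
    """
    fs = ts.sampling_rate
    if boundary_margin_s is None:
        boundary_margin_s = filter_warmup_samples() / fs
    duration = float(ts.time[-1] - ts.time[0]) if ts.n_samples else 0.0

    rows = []
    warnings: list[str] = []
    for side, suffix in (("left", "L"), ("right", "R")):
        r = _relative_ap(ts, suffix, pelvis_landmark)
        finite = np.isfinite(r)
        if not finite.any():
            warnings.append(f"{side}: relative ankle trajectory entirely missing")
            continue
        amp = 0.5 * float(
            np.nanpercentile(r, 95) - np.nanpercentile(r, 5)
        )
        if not np.isfinite(amp) or amp <= 0:
            warnings.append(f"{side}: flat relative ankle trajectory; no events")
            continue
        distance = max(1, int(round(min_period_s * fs)))
        prominence = prominence_frac * amp
        r_detect = np.where(finite, r, np.nanmedian(r))
        peaks_hs, _ = find_peaks(r_detect, distance=distance, prominence=prominence)
        peaks_to, _ = find_peaks(-r_detect, distance=distance, prominence=prominence)
        if len(peaks_hs) == 0 and len(peaks_to) == 0:
            warnings.append(f"{side}: fewer than one full oscillation; no events")
        for event_type, idx in (("heel_strike", peaks_hs), ("toe_off", peaks_to)):
            for i in idx:
                t = float(ts.time[i])
                near_edge = (
                    t - ts.time[0] < boundary_margin_s
                    or ts.time[-1] - t < boundary_margin_s
                )
                rows.append(
                    {
                        "side": side,
                        "event_type": event_type,
                        "time_s": t,
                        "frame_index": int(i),
                        "boundary": bool(near_edge),
                    }
                )
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame = frame.sort_values(["side", "event_type", "time_s"]).reset_index(drop=True)
    events = GaitEvents(frame=frame, warnings=warnings)
    for v in events.validate_alternation():
        msg = f"alternation violation: {v}"
        warnings.append(msg)
        logger.warning(msg)
    if duration and duration < 2 * min_period_s and events.n_events == 0:
        warnings.append("record shorter than one gait oscillation")
    return events


__all__ = ["GaitEvents", "detect_gait_events", "EVENT_COLUMNS"]
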