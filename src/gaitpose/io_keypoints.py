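"""Readers and writers for pose keypoints, marker tables and result tables.

Two input streams are supported:

* directories of per-frame OpenPose BODY_25 JSON files (one file per video
  frame, zero or more detected people per file), read into a
  :class:`PoseSequence`;
* marker trajectory CSV files (``time`` plus ``<marker>_x`` / ``<marker>_y``
  columns in meters) standing in for optical motion capture, read into a
  :class:`MarkerTable`.

All result tables (events, step tables, angle cycles, comparison reports) are
written as plain CSV/JSON with a ``# key=value`` comment header so that a
run's configuration hash travels with every file; the paired readers
round-trip numeric fields at full precision.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._body25 import BODY25_NAMES, N_KEYPOINTS, NAME_TO_INDEX


class FormatError(ValueError):
    """Malformed on-disk data (bad JSON, wrong keypoint array length...)."""


class SchemaError(ValueError):
    """A table is missing required columns or contains invalid values."""


# ---------------------------------------------------------------------------
# Pose sequences
# ---------------------------------------------------------------------------


@dataclass
class PoseSequence:
    """Per-frame pixel keypoints with confidences for a single tracked person.

    Attributes
    ----------
    xy:
        ``(n_frames, 25, 2)`` pixel coordinates in the native image frame
        (origin at the upper-left corner, y downward).
    confidence:
        ``(n_frames, 25)`` detection confidences in [0, 1]; a confidence of
        exactly 0 marks the keypoint missing in that frame.
    frame_rate:
        Video frame rate in Hz.
    camera_side:
        ``"left"`` or ``"right"`` sagittal view.
    image_size:
        ``(width, height)`` in pixels.
    multi_person_frames:
        Frame indices where more than one person was detected and the
        participant had to be selected (see :func:`select_person`).
    """

    xy: np.ndarray
    confidence: np.ndarray
    frame_rate: float
    camera_side: str
    image_size: tuple[int, int]
    source_id: str = ""
    multi_person_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError(f"xy must be (n, {N_KEYPOINTS}, 2), got {self.xy.shape}")
        if self.confidence.shape != self.xy.shape[:2]:
            raise ValueError("confidence shape must match xy frames x keypoints")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.camera_side not in ("left", "right"):
            raise ValueError("camera_side must be 'left' or 'right'")
        conf = self.confidence > 0
        if not np.all(np.isfinite(self.xy[conf])):
            raise ValueError("keypoints with confidence > 0 must have finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, first frame at t = 0."""
        return np.arange(self.n_frames) / self.frame_rate


def select_person(people: np.ndarray) -> tuple[int, np.ndarray]:
    """Pick the tracked participant among candidate detections in one frame.

    The candidate with the most confident (c > 0) keypoints wins; ties are
    broken by larger bounding-box area over the confident keypoints, then by
    lowest person index.  Deterministic by construction — person IDs assigned
    by the pose estimator are not relied upon.

    Parameters
    ----------
    people:
        ``(n_people, 25, 3)`` array of ``(x, y, confidence)`` rows.

    Returns
    -------
    (index, keypoints):
        Index of the selected person and its ``(25, 3)`` keypoint array.
    """
    people = np.asarray(people, dtype=float)
    if people.ndim != 3 or people.shape[1:] != (N_KEYPOINTS, 3):
        raise ValueError(f"people must be (m, {N_KEYPOINTS}, 3)")
    if people.shape[0] == 0:
        raise ValueError("select_person requires at least one candidate")
    best = None
    for i, person in enumerate(people):
        conf = person[:, 2] > 0
        count = int(conf.sum())
        if count:
            pts = person[conf, :2]
            area = float(np.ptp(pts[:, 0]) * np.ptp(pts[:, 1]))
        else:
            area = 0.0
        key = (count, area, -i)
        if best is None or key > best[0]:
            best = (key, i)
    idx = best[1]
    return idx, people[idx]


_NUM_SUFFIX = re.compile(r"(\d+)")


def _frame_number(path: Path) -> int:
    groups = _NUM_SUFFIX.findall(path.stem)
    if not groups:
        raise FormatError(f"cannot infer frame number from file name: {path.name}")
    return int(groups[-1])


def read_openpose_dir(
    path: str | Path,
    frame_rate: float,
    camera_side: str,
    image_size: tuple[int, int] = (960, 540),
    source_id: str | None = None,
) -> PoseSequence:
    """Read a directory of per-frame OpenPose BODY_25 JSON files.

    Files are ordered by the last numeric group in their (zero-padded) file
    names; non-contiguous frame numbers are an error rather than silently
    resampled.  Frames with an empty ``people`` list yield all-missing
    keypoints; frames with several people are resolved by
    :func:`select_person` and logged in ``multi_person_frames``.
    """
    path = Path(path)
    files = sorted(path.glob("*.json"), key=_frame_number)
    if not files:
        raise FormatError(f"no JSON files found in {path}")
    numbers = [_frame_number(f) for f in files]
    if len(set(numbers)) != len(numbers):
        raise FormatError(f"duplicate frame numbers in {path}")
    if numbers != list(range(numbers[0], numbers[0] + len(numbers))):
        raise FormatError(f"frame numbers in {path} are not contiguous")

    n = len(files)
    xy = np.zeros((n, N_KEYPOINTS, 2))
    conf = np.zeros((n, N_KEYPOINTS))
    multi: list[int] = []
    for i, f in enumerate(files):
        try:
            doc = json.loads(f.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed JSON in {f}: {exc}") from exc
        people_raw = doc.get("people", [])
        people = []
        for person in people_raw:
            flat = person.get("pose_keypoints_2d", [])
            if len(flat) != 3 * N_KEYPOINTS:
                raise FormatError(
                    f"{f}: pose_keypoints_2d has length {len(flat)}, expected {3 * N_KEYPOINTS}"
                )
            people.append(np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3))
        if not people:
            continue  # all-missing frame
        if len(people) > 1:
            multi.append(i)
        _, chosen = select_person(np.stack(people))
        xy[i] = chosen[:, :2]
        conf[i] = chosen[:, 2]
    return PoseSequence(
        xy=xy,
        confidence=conf,
        frame_rate=frame_rate,
        camera_side=camera_side,
        image_size=tuple(image_size),
        source_id=source_id if source_id is not None else path.name,
        multi_person_frames=multi,
    )


# ---------------------------------------------------------------------------
# Marker tables (motion-capture stand-in)
# ---------------------------------------------------------------------------

#: Marker columns required from a motion-capture CSV.  ``toe`` plays the role
#: of the big-toe keypoint, ``pelvis`` of the mid-ASIS/PSIS reference and
#: ``trunk`` of the C7 marker.
REQUIRED_MARKERS = (
    "hip_L",
    "hip_R",
    "knee_L",
    "knee_R",
    "ankle_L",
    "ankle_R",
    "toe_L",
    "toe_R",
    "pelvis",
    "trunk",
)

#: Marker name -> canonical landmark name used by the analysis modules.
_MARKER_TO_LANDMARK = {
    "toe_L": "big_toe_L",
    "toe_R": "big_toe_R",
    "trunk": "neck",
}


@dataclass
class MarkerTable:
    """Uniformly sampled metric marker trajectories (sagittal components).

    ``markers`` maps marker names to ``(n, 2)`` arrays of (x along travel, y
    vertical) in meters.
    """

    time: np.ndarray
    markers: dict[str, np.ndarray]
    rate: float

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def to_trajectory_set(self):
        """Convert to a :class:`~gaitpose.preprocess.TrajectorySet` using the
        canonical landmark names shared with the pose stream."""
        from .preprocess import TrajectorySet

        data = {
            _MARKER_TO_LANDMARK.get(name, name): arr.copy()
            for name, arr in self.markers.items()
        }
        return TrajectorySet(
            time=self.time.copy(),
            data=data,
            sampling_rate=self.rate,
            provenance="mocap",
            units="m",
        )


def read_marker_csv(
    path: str | Path, required: tuple[str, ...] = REQUIRED_MARKERS
) -> MarkerTable:
    """Read a marker CSV (``time`` + ``<name>_x``/``<name>_y`` columns, meters).

    The loader rejects tables with missing required markers, NaN samples or
    non-uniform sampling.
    """
    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise SchemaError("marker CSV must contain a 'time' column")
    names = sorted(
        {c[:-2] for c in df.columns if c.endswith("_x") or c.endswith("_y")}
    )
    missing_cols = [
        f"{name}_{axis}"
        for name in required
        for axis in ("x", "y")
        if f"{name}_{axis}" not in df.columns
    ]
    if missing_cols:
        raise SchemaError(f"marker CSV missing required columns: {missing_cols}")
    if df.isna().any().any():
        raise SchemaError("marker CSV contains NaN values")
    time = df["time"].to_numpy(dtype=float)
    dt = np.diff(time)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SchemaError("marker CSV time column is not uniformly sampled")
    rate = 1.0 / dt[0] if len(dt) else 0.0
    markers = {
        name: np.column_stack(
            [df[f"{name}_x"].to_numpy(float), df[f"{name}_y"].to_numpy(float)]
        )
        for name in names
    }
    return MarkerTable(time=time, markers=markers, rate=rate)


def write_marker_csv(table: MarkerTable, path: str | Path, meta: dict | None = None) -> None:
    cols = {"time": table.time}
    for name in sorted(table.markers):
        cols[f"{name}_x"] = table.markers[name][:, 0]
        cols[f"{name}_y"] = table.markers[name][:, 1]
    write_table(pd.DataFrame(cols), path, meta)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV with an optional ``# key=value`` header.

    Floats are stored with 10 significant digits so that writer/reader pairs
    round-trip numerically.
    """
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_events(events, path: str | Path, meta: dict | None = None) -> None:
    """Write a :class:`~gaitpose.events.GaitEvents` to CSV."""
    write_table(events.frame, path, meta)


def read_events(path: str | Path):
    from .events import GaitEvents

    return GaitEvents.from_frame(read_table(path))


def write_step_table(table, path: str | Path, meta: dict | None = None) -> None:
    write_table(table.steps, path, meta)


def read_step_table(path: str | Path):
    from .spatiotemporal import StepTable

    return StepTable(steps=read_table(path))


def write_angle_cycles(cycles, path: str | Path, meta: dict | None = None) -> None:
    """Write joint-angle cycles in long format (one row per cycle sample)."""
    write_table(cycles.to_frame(), path, meta)


def read_angle_cycles(path: str | Path):
    from .kinematics import JointAngleCycles

    return JointAngleCycles.from_frame(read_table(path))


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


__all__ = [
    "BODY25_NAMES",
    "NAME_TO_INDEX",
    "FormatError",
    "SchemaError",
    "PoseSequence",
    "MarkerTable",
    "REQUIRED_MARKERS",
    "select_person",
    "read_openpose_dir",
    "read_marker_csv",
    "write_marker_csv",
    "write_table",
    "read_table",
    "write_events",
    "read_events",
    "write_step_table",
    "read_step_table",
    "write_angle_cycles",
    "read_angle_cycles",
    "write_report",
    "read_report",
]
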