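"""Ground-truthed synthetic walking bouts.

A planar forward-kinematic walker emulates the recording conditions of an
overground gait lab: a ~5 m bout at ~1.0 m/s, filmed from a sagittal view at
25 Hz and 960x540 px by a camera ~3.3 m from the walking plane at ~1.3 m
height, with a simultaneous 100 Hz metric marker stream from the same
underlying motion.

The pelvis translates at constant speed while periodic sinusoidal joint-angle
profiles (hip, knee, ankle; the two legs offset by half a stride) drive the
leg keypoints through forward kinematics.  Ground-truth heel-strikes and
toe-offs are the programmed extrema of the anterior-posterior ankle position
relative to the pelvis — the same definition the event detector uses — so
every pipeline stage can be scored against exact truth.  The hip amplitude is
solved so that the model's step length equals the requested value.

Two camera models are available: ``orthographic`` (clean baseline, constant
magnification) and ``pinhole`` (perspective projection with the two legs at
slightly different depths, reproducing the position-dependent step-length
errors that parallax causes in real sagittal video).

Defect injection degrades a clean pose sequence with Gaussian pixel noise,
detection gaps, left/right limb-identity swaps and a static false-positive
person, logging every altered frame so repairs can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import optimize

from ._body25 import BODY25_NAMES, N_KEYPOINTS, NAME_TO_INDEX, LEG_PAIRS
from .events import GaitEvents, EVENT_COLUMNS
from .io_keypoints import MarkerTable, PoseSequence
from .preprocess import filter_warmup_samples
from .spatiotemporal import StepTable, compute_step_table

#: Defect rates observed in real OpenPose output of the emulated recordings:
#: false-positive persons in ~20% of frames, switched limb identities in ~5%.
OPENPOSE_FALSE_PERSON_RATE = 0.20
OPENPOSE_SWAP_RATE = 0.05


class ValidationError(ValueError):
    """Inconsistent simulation specification."""


@dataclass
class DefectSpec:
    """Rates and magnitudes for degrading a clean pose sequence."""

    noise_sd_px: float = 0.0
    gap_rate: float = 0.0  # per-frame probability of starting a keypoint gap
    max_gap_len: int = 2
    swap_rate: float = 0.0  # per-frame probability of a left/right leg swap
    false_person_rate: float = 0.0

    @property
    def any_active(self) -> bool:
        return (
            self.noise_sd_px > 0
            or self.gap_rate > 0
            or self.swap_rate > 0
            or self.false_person_rate > 0
        )


@dataclass
class SyntheticGaitSpec:
    """Study conditions for one simulated walking bout.

    Defaults emulate the recording setup of the gait dataset the analysis
    chain targets: 0.6 s steps at 1.0 m/s (0.6 m step length), a ~5 m bout,
    25 Hz 960x540 sagittal video with the camera 3.3 m away at 1.3 m height,
    and a synchronized 100 Hz marker stream.
    """

    step_time: float = 0.6  # s, per side
    step_length: float = 0.6  # m
    bout_length: float = 5.0  # m
    frame_rate: float = 25.0  # Hz (video)
    marker_rate: float = 100.0  # Hz (motion-capture stand-in)
    image_size: tuple[int, int] = (960, 540)
    camera_side: str = "left"
    camera_mode: str = "orthographic"  # or "pinhole"
    camera_distance: float = 3.3  # m, camera to walking plane
    camera_height: float = 1.3  # m
    focal_px: float = 480.0  # pinhole focal length
    ortho_scale: float = 0.008  # m/px in orthographic mode
    leg_depth_offset: float = 0.10  # m, lateral offset of each leg from midline
    reference_distance_m: float = 6.30  # floor-tape separation for scaling
    # segment lengths (m)
    thigh: float = 0.42
    shank: float = 0.42
    foot: float = 0.25
    pelvis_height: float = 0.92
    # joint-angle profile parameters (deg); hip_amp None -> solved for step_length
    hip_amp: float | None = None
    hip_offset: float = 0.0
    #: relative weight of the hip's second harmonic; 0.309 places the minimum
    #: of the relative ankle trajectory ~60% of the cycle after its maximum,
    #: i.e. a realistic ~60/40 stance/swing split and short double support
    hip_h2: float = 0.309
    knee_offset: float = 25.0
    knee_amp: float = 20.0
    knee_phase: float = 0.70  # fraction of stride
    ankle_offset: float = 0.0
    ankle_amp: float = 10.0
    ankle_phase: float = 0.55
    #: first left heel-strike; 0.32 s lands on the video frame grid at the
    #: default 25 Hz rate and 0.6 s step time, so programmed events coincide
    #: with frames (the event detector reports whole-frame times)
    first_hs_time: float = 0.32
    defects: DefectSpec = field(default_factory=DefectSpec)
    seed: int = 0

    @property
    def gait_speed(self) -> float:
        return self.step_length / self.step_time

    @property
    def stride_time(self) -> float:
        return 2.0 * self.step_time

    @property
    def duration(self) -> float:
        return self.bout_length / self.gait_speed

    def validate(self) -> None:
        positive = {
            "step_time": self.step_time,
            "step_length": self.step_length,
            "bout_length": self.bout_length,
            "frame_rate": self.frame_rate,
            "marker_rate": self.marker_rate,
            "camera_distance": self.camera_distance,
            "thigh": self.thigh,
            "shank": self.shank,
            "foot": self.foot,
            "reference_distance_m": self.reference_distance_m,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.camera_mode not in ("orthographic", "pinhole"):
            raise ValidationError(f"unknown camera_mode: {self.camera_mode}")
        if self.camera_side not in ("left", "right"):
            raise ValidationError(f"unknown camera_side: {self.camera_side}")
        if self.step_length >= 1.6 * (self.thigh + self.shank):
            raise ValidationError(
                "step_length is not anatomically reachable with the given segment lengths"
            )


@dataclass
class InjectionLog:
    """Record of every frame altered by :func:`inject_defects`."""

    noise_sd_px: float = 0.0
    gap_frames: dict[int, list[int]] = field(default_factory=dict)
    swap_frames: list[int] = field(default_factory=list)
    false_person_frames: list[int] = field(default_factory=list)
    extra_people: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "noise_sd_px": self.noise_sd_px,
            "gap_frames": {str(k): v for k, v in self.gap_frames.items()},
            "swap_frames": self.swap_frames,
            "false_person_frames": self.false_person_frames,
        }


@dataclass
class GroundTruth:
    """Exact truth for one simulated bout, consistent with the generated
    trajectories by construction."""

    events: GaitEvents
    step_table: StepTable
    angle_profiles: dict[str, np.ndarray]  # joint -> (n_pct,) deg
    cycle_pct: np.ndarray
    reference_points_px: tuple[np.ndarray, np.ndarray]
    reference_distance_m: float
    injection: InjectionLog | None
    spec: SyntheticGaitSpec
    walker: "Walker"


class Walker:
    """Continuous-time forward-kinematic walker (world coordinates).

    World frame: x along travel (bout centered on 0), y up, ``lat`` the
    lateral offset from the mid-sagittal plane (positive toward the
    participant's left).
    """

    _STATIC_UPPER = {
        # name: (dx, dy, lat) relative to the pelvis
        "neck": (0.0, 0.55, 0.0),
        "nose": (0.06, 0.68, 0.0),
        "eye_R": (0.07, 0.70, -0.03),
        "eye_L": (0.07, 0.70, 0.03),
        "ear_R": (0.02, 0.68, -0.07),
        "ear_L": (0.02, 0.68, 0.07),
        "shoulder_R": (0.0, 0.50, -0.18),
        "shoulder_L": (0.0, 0.50, 0.18),
        "elbow_R": (0.01, 0.25, -0.20),
        "elbow_L": (0.01, 0.25, 0.20),
        "wrist_R": (0.04, 0.02, -0.20),
        "wrist_L": (0.04, 0.02, 0.20),
    }

    def __init__(self, spec: SyntheticGaitSpec):
        spec.validate()
        self.spec = spec
        self.hip_amp = (
            spec.hip_amp if spec.hip_amp is not None else self._solve_hip_amp()
        )
        self.psi_hs = self._extremum_phase(self.hip_amp, largest=True)
        self.psi_to = self._extremum_phase(self.hip_amp, largest=False)
        # phase offset so the first left heel-strike lands at first_hs_time
        T = spec.stride_time
        self.psi0_left = (self.psi_hs - spec.first_hs_time / T) % 1.0
        self.psi0_right = (self.psi0_left + 0.5) % 1.0

    # -- programmed joint profiles (deg) as functions of stride phase --------

    def hip_angle(self, psi, amp: float | None = None):
        a = self.hip_amp if amp is None else amp
        psi = np.asarray(psi)
        h2 = self.spec.hip_h2
        shape = (np.cos(2 * np.pi * psi) + h2 * np.cos(4 * np.pi * psi)) / (1.0 + h2)
        return self.spec.hip_offset + a * shape

    def knee_angle(self, psi):
        s = self.spec
        return s.knee_offset + s.knee_amp * np.cos(2 * np.pi * (np.asarray(psi) - s.knee_phase))

    def ankle_angle(self, psi):
        s = self.spec
        return s.ankle_offset + s.ankle_amp * np.cos(
            2 * np.pi * (np.asarray(psi) - s.ankle_phase)
        )

    # -- relative AP ankle position and its programmed extrema ---------------

    def _relative_ankle(self, psi, amp: float | None = None):
        s = self.spec
        th = np.radians(self.hip_angle(psi, amp))
        tk = np.radians(self.knee_angle(psi))
        return s.thigh * np.sin(th) + s.shank * np.sin(th - tk)

    def _extremum_phase(self, amp: float, largest: bool) -> float:
        grid = np.linspace(0.0, 1.0, 4097)[:-1]
        r = self._relative_ankle(grid, amp)
        i = int(np.argmax(r) if largest else np.argmin(r))
        lo, hi = grid[i] - 2.5e-4, grid[i] + 2.5e-4
        sign = -1.0 if largest else 1.0
        res = optimize.minimize_scalar(
            lambda p: sign * self._relative_ankle(p, amp),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return float(res.x % 1.0)

    def _step_length_for_amp(self, amp: float) -> float:
        psi_hs = self._extremum_phase(amp, largest=True)
        lead = self._relative_ankle(psi_hs, amp)
        trail = self._relative_ankle(psi_hs - 0.5, amp)
        return float(lead - trail)

    def _solve_hip_amp(self) -> float:
        target = self.spec.step_length
        lo, hi = 0.5, 70.0
        if self._step_length_for_amp(hi) < target:
            raise ValidationError(
                "step_length is not reachable with the given segment lengths"
            )
        return float(
            optimize.brentq(
                lambda a: self._step_length_for_amp(a) - target, lo, hi, xtol=1e-10
            )
        )

    # -- kinematics -----------------------------------------------------------

    def phase(self, t, side: str):
        psi0 = self.psi0_left if side == "L" else self.psi0_right
        return (np.asarray(t, dtype=float) / self.spec.stride_time + psi0) % 1.0

    def pelvis_x(self, t):
        s = self.spec
        return -s.bout_length / 2.0 + s.gait_speed * np.asarray(t, dtype=float)

    def landmarks(self, t) -> dict[str, np.ndarray]:
        """All 25 keypoints at times ``t``: ``(n, 3)`` arrays of (x, y, lat)."""
        s = self.spec
        t = np.atleast_1d(np.asarray(t, dtype=float))
        px = self.pelvis_x(t)
        py = np.full_like(px, s.pelvis_height)
        out: dict[str, np.ndarray] = {}
        out["pelvis"] = np.column_stack([px, py, np.zeros_like(px)])
        for name, (dx, dy, lat) in self._STATIC_UPPER.items():
            out[name] = np.column_stack(
                [px + dx, py + dy, np.full_like(px, lat)]
            )
        for side, lat_sign in (("L", 1.0), ("R", -1.0)):
            lat = np.full_like(px, lat_sign * s.leg_depth_offset)
            psi = self.phase(t, side)
            th = np.radians(self.hip_angle(psi))
            tk = np.radians(self.knee_angle(psi))
            ta = np.radians(self.ankle_angle(psi))
            ts_ = th - tk  # shank angle from vertical
            hip = np.column_stack([px, py])
            knee = hip + s.thigh * np.column_stack([np.sin(th), -np.cos(th)])
            ankle = knee + s.shank * np.column_stack([np.sin(ts_), -np.cos(ts_)])
            foot_dir = np.column_stack([np.cos(ts_ + ta), np.sin(ts_ + ta)])
            toe = ankle + s.foot * foot_dir
            heel = ankle - 0.07 * foot_dir
            small_toe = ankle + 0.95 * s.foot * foot_dir
            for name, arr in (
                (f"hip_{side}", hip),
                (f"knee_{side}", knee),
                (f"ankle_{side}", ankle),
                (f"big_toe_{side}", toe),
                (f"small_toe_{side}", small_toe),
                (f"heel_{side}", heel),
            ):
                out[name] = np.column_stack([arr, lat])
        return out

    def landmark_x(self, name: str, times) -> np.ndarray:
        """Exact anterior-posterior world position of one landmark."""
        return self.landmarks(times)[name][:, 0]

    # -- ground-truth events --------------------------------------------------

    def event_times(self, duration: float) -> dict[tuple[str, str], np.ndarray]:
        T = self.spec.stride_time
        out = {}
        for side, psi0 in (("left", self.psi0_left), ("right", self.psi0_right)):
            for event_type, psi_star in (
                ("heel_strike", self.psi_hs),
                ("toe_off", self.psi_to),
            ):
                t0 = ((psi_star - psi0) % 1.0) * T
                times = np.arange(t0, duration + 1e-9, T)
                out[(side, event_type)] = times
        return out


# ---------------------------------------------------------------------------
# Camera projection
# ---------------------------------------------------------------------------


def project_points(world: np.ndarray, spec: SyntheticGaitSpec) -> np.ndarray:
    """Project world (x, y, lat) points to image pixels (origin upper-left).

    Orthographic mode applies a constant scale; pinhole mode projects through
    a camera at the walkway center, ``camera_distance`` from the mid-sagittal
    plane at ``camera_height``, so magnification depends on each point's
    depth and parallax errors grow toward the edges of the field of view.
    For a left-side view the image x axis runs against the travel direction.
    """
    world = np.asarray(world, dtype=float)
    width, height = spec.image_size
    x, y, lat = world[..., 0], world[..., 1], world[..., 2]
    sign = -1.0 if spec.camera_side == "left" else 1.0
    if spec.camera_mode == "orthographic":
        u = width / 2.0 + sign * x / spec.ortho_scale
        v = (height - 40.0) - y / spec.ortho_scale
    else:
        # depth: the camera sits on the viewed side, so for a left-side view
        # the participant's left leg (positive lat) is nearer the camera.
        lat_toward_camera = lat if spec.camera_side == "left" else -lat
        z = spec.camera_distance - lat_toward_camera
        u = width / 2.0 + sign * spec.focal_px * x / z
        v = height / 2.0 - spec.focal_px * (y - spec.camera_height) / z
    return np.stack([u, v], axis=-1)


def reference_tape_pixels(spec: SyntheticGaitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixel positions of the two floor-tape midpoints used for scaling."""
    half = spec.reference_distance_m / 2.0
    pts = project_points(
        np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]]), spec
    )
    return pts[0], pts[1]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _pose_from_walker(walker: Walker) -> PoseSequence:
    spec = walker.spec
    n = int(round(spec.duration * spec.frame_rate)) + 1
    t = np.arange(n) / spec.frame_rate
    lm = walker.landmarks(t)
    xy = np.zeros((n, N_KEYPOINTS, 2))
    for name, arr in lm.items():
        xy[:, NAME_TO_INDEX[name], :] = project_points(arr, spec)
    conf = np.ones((n, N_KEYPOINTS))
    return PoseSequence(
        xy=xy,
        confidence=conf,
        frame_rate=spec.frame_rate,
        camera_side=spec.camera_side,
        image_size=spec.image_size,
        source_id="synthetic",
    )


_MARKER_NAMES = {
    "pelvis": "pelvis",
    "neck": "trunk",
    "hip_L": "hip_L",
    "hip_R": "hip_R",
    "knee_L": "knee_L",
    "knee_R": "knee_R",
    "ankle_L": "ankle_L",
    "ankle_R": "ankle_R",
    "big_toe_L": "toe_L",
    "big_toe_R": "toe_R",
    "heel_L": "heel_L",
    "heel_R": "heel_R",
}


def _markers_from_walker(walker: Walker) -> MarkerTable:
    spec = walker.spec
    n = int(round(spec.duration * spec.marker_rate)) + 1
    t = np.arange(n) / spec.marker_rate
    lm = walker.landmarks(t)
    markers = {
        out_name: lm[name][:, :2].copy() for name, out_name in _MARKER_NAMES.items()
    }
    return MarkerTable(time=t, markers=markers, rate=spec.marker_rate)


def _ground_truth_events(walker: Walker) -> GaitEvents:
    spec = walker.spec
    duration = (int(round(spec.duration * spec.frame_rate))) / spec.frame_rate
    margin = filter_warmup_samples() / spec.frame_rate
    rows = []
    for (side, event_type), times in walker.event_times(duration).items():
        for t in times:
            rows.append(
                {
                    "side": side,
                    "event_type": event_type,
                    "time_s": float(t),
                    "frame_index": int(round(t * spec.frame_rate)),
                    "boundary": bool(t < margin or duration - t < margin),
                }
            )
    import pandas as pd

    frame = (
        pd.DataFrame(rows, columns=EVENT_COLUMNS)
        .sort_values(["side", "event_type", "time_s"])
        .reset_index(drop=True)
    )
    return GaitEvents(frame=frame)


def _true_angle_profiles(walker: Walker, n_samples: int = 101):
    pct = np.linspace(0.0, 100.0, n_samples)
    psi = (walker.psi_hs + pct / 100.0) % 1.0
    return pct, {
        "hip": np.asarray(walker.hip_angle(psi), dtype=float),
        "knee": np.asarray(walker.knee_angle(psi), dtype=float),
        "ankle": np.asarray(walker.ankle_angle(psi), dtype=float),
    }


def simulate(spec: SyntheticGaitSpec) -> tuple[PoseSequence, MarkerTable, GroundTruth]:
    """Generate one bout: pose sequence, marker table and exact ground truth.

    With non-zero defect rates in ``spec.defects`` the returned pose sequence
    is degraded (seeded by ``spec.seed``) and the injection log is recorded
    in the ground truth; the marker table is always clean (it stands in for
    the motion-capture gold standard).  Identical specs (including seed)
    produce bit-identical outputs.
    """
    walker = Walker(spec)
    pose = _pose_from_walker(walker)
    markers = _markers_from_walker(walker)
    events = _ground_truth_events(walker)
    step_table = compute_step_table(
        events,
        lambda name, times: walker.landmark_x(name, times),
    )
    pct, profiles = _true_angle_profiles(walker)
    injection = None
    if spec.defects.any_active:
        pose, injection = inject_defects(pose, spec.defects, spec.seed)
    truth = GroundTruth(
        events=events,
        step_table=step_table,
        angle_profiles=profiles,
        cycle_pct=pct,
        reference_points_px=reference_tape_pixels(spec),
        reference_distance_m=spec.reference_distance_m,
        injection=injection,
        spec=spec,
        walker=walker,
    )
    return pose, markers, truth


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------

_LEG_INDICES = sorted(
    NAME_TO_INDEX[name] for pair in LEG_PAIRS for name in pair
)

_TRIPOD_KEYPOINTS = ("nose", "neck", "pelvis", "ankle_R")


def _tripod_person(image_size: tuple[int, int]) -> np.ndarray:
    """A static 4-keypoint false positive, as a tripod at the image edge
    would produce."""
    person = np.zeros((N_KEYPOINTS, 3))
    xs = 0.06 * image_size[0]
    ys = np.linspace(0.3, 0.9, len(_TRIPOD_KEYPOINTS)) * image_size[1]
    for name, y in zip(_TRIPOD_KEYPOINTS, ys):
        person[NAME_TO_INDEX[name]] = (xs, y, 0.8)
    return person


def inject_defects(
    seq: PoseSequence, defects: DefectSpec, seed: int
) -> tuple[PoseSequence, InjectionLog]:
    """Degrade a pose sequence at the configured rates; log every change.

    Draw order per defect type is fixed so a given (sequence, defects, seed)
    triple always produces the same degradation.
    """
    rng = np.random.default_rng(seed)
    xy = seq.xy.copy()
    conf = seq.confidence.copy()
    n = seq.n_frames
    log = InjectionLog(noise_sd_px=defects.noise_sd_px)

    if defects.noise_sd_px > 0:
        noise = rng.normal(0.0, defects.noise_sd_px, size=xy.shape)
        mask = (conf > 0)[:, :, None]
        xy = np.where(mask, xy + noise, xy)

    if defects.gap_rate > 0:
        for i in range(n):
            if rng.random() < defects.gap_rate:
                kp = int(rng.choice(_LEG_INDICES))
                length = int(rng.integers(1, defects.max_gap_len + 1))
                for j in range(i, min(i + length, n)):
                    conf[j, kp] = 0.0
                    xy[j, kp] = 0.0
                    log.gap_frames.setdefault(j, []).append(kp)

    if defects.swap_rate > 0:
        for i in range(n):
            if rng.random() < defects.swap_rate:
                for left, right in LEG_PAIRS:
                    li, ri = NAME_TO_INDEX[left], NAME_TO_INDEX[right]
                    xy[i, [li, ri]] = xy[i, [ri, li]]
                    conf[i, [li, ri]] = conf[i, [ri, li]]
                log.swap_frames.append(i)

    if defects.false_person_rate > 0:
        tripod = _tripod_person(seq.image_size)
        for i in range(n):
            if rng.random() < defects.false_person_rate:
                log.false_person_frames.append(i)
                log.extra_people.setdefault(i, []).append(tripod.copy())

    degraded = PoseSequence(
        xy=xy,
        confidence=conf,
        frame_rate=seq.frame_rate,
        camera_side=seq.camera_side,
        image_size=seq.image_size,
        source_id=seq.source_id,
    )
    return degraded, log


# ---------------------------------------------------------------------------
# OpenPose JSON output
# ---------------------------------------------------------------------------


def write_openpose_json(
    seq: PoseSequence,
    directory: str | Path,
    extra_people: dict[int, list[np.ndarray]] | None = None,
) -> list[Path]:
    """Write one BODY_25 JSON file per frame in the OpenPose dialect.

    Frames where every keypoint is missing get an empty ``people`` list.
    ``extra_people`` (e.g. from an :class:`InjectionLog`) appends false
    positives after the participant.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = seq.source_id or "frame"
    paths = []
    for i in range(seq.n_frames):
        people = []
        if np.any(seq.confidence[i] > 0):
            flat = np.column_stack([seq.xy[i], seq.confidence[i][:, None]]).ravel()
            people.append({"person_id": [-1], "pose_keypoints_2d": flat.tolist()})
        for extra in (extra_people or {}).get(i, []):
            people.append(
                {"person_id": [-1], "pose_keypoints_2d": np.asarray(extra).ravel().tolist()}
            )
        doc = {"version": 1.3, "people": people}
        path = directory / f"{prefix}_{i:012d}_keypoints.json"
        path.write_text(json.dumps(doc))
        paths.append(path)
    return paths


def spec_to_json_dict(spec: SyntheticGaitSpec) -> dict:
    d = asdict(spec)
    d["image_size"] = list(spec.image_size)
    return d


def spec_from_dict(d: dict) -> SyntheticGaitSpec:
    d = dict(d)
    if "defects" in d and isinstance(d["defects"], dict):
        d["defects"] = DefectSpec(**d["defects"])
    if "image_size" in d:
        d["image_size"] = tuple(d["image_size"])
    known = {f.name for f in SyntheticGaitSpec.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown spec keys: {sorted(unknown)}")
    return SyntheticGaitSpec(**d)


__all__ = [
    "OPENPOSE_FALSE_PERSON_RATE",
    "OPENPOSE_SWAP_RATE",
    "ValidationError",
    "DefectSpec",
    "SyntheticGaitSpec",
    "InjectionLog",
    "GroundTruth",
    "Walker",
    "project_points",
    "reference_tape_pixels",
    "simulate",
    "inject_defects",
    "write_openpose_json",
    "spec_to_json_dict",
    "spec_from_dict",
]
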