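"""Raw pixel keypoints to clean, metric, walking-frame trajectories.

The processing chain mirrors the standard video post-processing sequence for
sagittal gait recordings:

1. re-express pixel coordinates so +x is the direction of travel and +y is up
   (:func:`to_walking_frame`);
2. repair frames where the pose estimator switched the left/right identity of
   the leg keypoints (:func:`correct_limb_swaps`);
3. fill short detection gaps by linear interpolation (:func:`fill_gaps`);
4. low-pass filter with a zero-lag Butterworth filter (:func:`lowpass_filter`);
5. scale pixels to meters using a known reference distance on the floor
   (:func:`compute_scaling` / :func:`dimensionalize`).

:func:`preprocess_pose` chains all five steps in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._body25 import BODY25_NAMES, LEG_PAIRS
from .io_keypoints import PoseSequence

logger = logging.getLogger(__name__)

#: Reference distance between the two floor-tape strips used for scaling, in
#: meters (ensemble estimate for the public dataset's walkway).
DEFAULT_REFERENCE_DISTANCE_M = 6.30


@dataclass
class TrajectorySet:
    """Uniformly sampled 2D trajectories in the walking frame.

    ``data`` maps landmark names to ``(n, 2)`` arrays of (x, y); +x points in
    the direction of travel and +y up.  ``units`` is ``"px"`` before
    dimensionalization and ``"m"`` after.  Missing samples are NaN.
    """

    time: np.ndarray
    data: dict[str, np.ndarray]
    sampling_rate: float
    provenance: str  # 'pose_left' | 'pose_right' | 'mocap'
    units: str = "m"
    confidence: dict[str, np.ndarray] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def landmarks(self) -> list[str]:
        return list(self.data)

    def x(self, name: str) -> np.ndarray:
        return self.data[name][:, 0]

    def y(self, name: str) -> np.ndarray:
        return self.data[name][:, 1]

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            time=self.time.copy(),
            data={k: v.copy() for k, v in self.data.items()},
            sampling_rate=self.sampling_rate,
            provenance=self.provenance,
            units=self.units,
            confidence=(
                {k: v.copy() for k, v in self.confidence.items()}
                if self.confidence is not None
                else None
            ),
        )


@dataclass
class SwapReport:
    """Frames altered by :func:`correct_limb_swaps`."""

    swapped_frames: list[int] = field(default_factory=list)
    same_leg_frames: list[int] = field(default_factory=list)

    @property
    def n_changes(self) -> int:
        return len(self.swapped_frames) + len(self.same_leg_frames)


@dataclass
class ScalingCalibration:
    """Pixel-to-meter scaling from a known horizontal reference distance."""

    reference_distance: float  # m
    reference_pixel_length: float  # px
    s: float  # m / px

    def __post_init__(self) -> None:
        if min(self.reference_distance, self.reference_pixel_length, self.s) <= 0:
            raise ValueError("scaling quantities must be positive")
        if not np.isclose(self.s, self.reference_distance / self.reference_pixel_length):
            raise ValueError("s must equal reference_distance / reference_pixel_length")


# ---------------------------------------------------------------------------
# Step 1: walking-frame convention
# ---------------------------------------------------------------------------


def flip_to_travel(
    xy: np.ndarray, camera_side: str, image_size: tuple[int, int]
) -> np.ndarray:
    """Map image coordinates to the travel-positive, up-positive convention.

    For a left-side view the origin moves to the lower-right image corner
    (``x' = width - x``); for a right-side view to the lower-left corner
    (``x' = x``); both flip y (``y' = height - y``).  On a given view the x
    transform is an involution.  Downstream analyses are invariant to the
    location of the origin.
    """
    width, height = image_size
    out = np.array(xy, dtype=float, copy=True)
    if camera_side == "left":
        out[..., 0] = width - out[..., 0]
    elif camera_side != "right":
        raise ValueError("camera_side must be 'left' or 'right'")
    out[..., 1] = height - out[..., 1]
    return out


def to_walking_frame(
    seq: PoseSequence, confidence_threshold: float = 0.0
) -> TrajectorySet:
    """Convert a :class:`PoseSequence` to walking-frame pixel trajectories.

    Keypoints with confidence <= ``confidence_threshold`` become NaN.
    """
    xy = flip_to_travel(seq.xy, seq.camera_side, seq.image_size)
    missing = seq.confidence <= confidence_threshold
    xy[missing] = np.nan
    data = {name: xy[:, i, :] for i, name in enumerate(BODY25_NAMES)}
    conf = {name: seq.confidence[:, i].copy() for i, name in enumerate(BODY25_NAMES)}
    return TrajectorySet(
        time=seq.times,
        data=data,
        sampling_rate=seq.frame_rate,
        provenance=f"pose_{seq.camera_side}",
        units="px",
        confidence=conf,
    )


# ---------------------------------------------------------------------------
# Step 2: limb-swap correction
# ---------------------------------------------------------------------------


def _swap_frame(ts: TrajectorySet, i: int) -> None:
    for left, right in LEG_PAIRS:
        ts.data[left][i], ts.data[right][i] = (
            ts.data[right][i].copy(),
            ts.data[left][i].copy(),
        )
        if ts.confidence is not None:
            ts.confidence[left][i], ts.confidence[right][i] = (
                ts.confidence[right][i],
                ts.confidence[left][i],
            )


def _swap_pass(ts: TrajectorySet, order: range) -> tuple[list[int], int]:
    # Choose, per frame, the left/right assignment of the leg keypoints that
    # minimizes the summed displacement of both legs' ankle and knee points
    # from their constant-velocity predictions.  Velocity extrapolation is
    # what disambiguates ankle crossings: the two legs momentarily occupy the
    # same position but move in opposite directions.
    ref: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, int]] = {}
    swapped = []
    n_evaluated = 0
    for i in order:
        keep_cost = swap_cost = 0.0
        n_terms = 0
        for lm in ("ankle", "knee"):
            cur = {"L": ts.data[f"{lm}_L"][i], "R": ts.data[f"{lm}_R"][i]}
            for side in ("L", "R"):
                other = "R" if side == "L" else "L"
                last = ref.get((side, lm))
                if last is None:
                    continue
                pos, vel, last_i = last
                predicted = pos + vel * (i - last_i)
                if np.all(np.isfinite(cur[side])) and np.all(np.isfinite(cur[other])):
                    keep_cost += float(np.hypot(*(cur[side] - predicted)))
                    swap_cost += float(np.hypot(*(cur[other] - predicted)))
                    n_terms += 1
        clear = True
        if n_terms:
            n_evaluated += 1
            if swap_cost < keep_cost:
                _swap_frame(ts, i)
                swapped.append(i)
            # near a leg crossing the two assignments cost almost the same;
            # such frames get a provisional label but do not update the
            # reference, so the next clear frame is judged by extrapolation
            # from before the crossing, where the legs were separable
            clear = abs(keep_cost - swap_cost) > 0.25 * (keep_cost + swap_cost)
        for lm in ("ankle", "knee"):
            for side in ("L", "R"):
                p = ts.data[f"{lm}_{side}"][i]
                if not np.all(np.isfinite(p)):
                    continue
                last = ref.get((side, lm))
                stale = last is not None and i - last[2] > 4  # crossings last ~2-3 frames
                if clear or last is None or stale:
                    if last is not None and abs(i - last[2]) <= 3:
                        vel = (p - last[0]) / (i - last[2])
                    else:
                        vel = np.zeros(2)
                    ref[(side, lm)] = (p.copy(), vel, i)
    return swapped, n_evaluated


def correct_limb_swaps(
    ts: TrajectorySet, same_leg_eps: float = 5.0
) -> tuple[TrajectorySet, SwapReport]:
    """Repair frames with switched left/right leg identification.

    A forward pass decides per frame whether to keep or exchange the six leg
    keypoint pairs, minimizing summed displacement of the ankle and knee
    points from their constant-velocity predictions.  The pass anchors on
    the first usable frame; if that anchor frame itself carried swapped
    labels, the pass makes the whole bout consistent with the wrong parity
    and ends up "swapping" the majority of frames — in that case the entire
    labeling is flipped once, which also resolves an ambiguous first frame.
    Frames where both ankle keypoints land on the same leg (closer than
    ``same_leg_eps`` in the current units, both confident) have the
    lower-confidence leg marked missing.  Idempotent: a second application
    reports zero changes.
    """
    out = ts.copy()
    report = SwapReport()
    if out.n_samples > 1:
        swapped, n_evaluated = _swap_pass(out, range(out.n_samples))
        if len(swapped) > 0.5 * max(1, n_evaluated):
            for i in range(out.n_samples):
                _swap_frame(out, i)
            swapped = sorted(set(range(out.n_samples)) - set(swapped))
        report.swapped_frames = sorted(swapped)

    # Both-legs-on-one-leg frames: requires confidences to rank the two sets.
    if out.confidence is not None:
        left_names = [left for left, _ in LEG_PAIRS]
        right_names = [right for _, right in LEG_PAIRS]
        for i in range(out.n_samples):
            al, ar = out.data["ankle_L"][i], out.data["ankle_R"][i]
            if not (np.all(np.isfinite(al)) and np.all(np.isfinite(ar))):
                continue
            if np.hypot(*(al - ar)) >= same_leg_eps:
                continue
            conf_l = np.mean([out.confidence[n][i] for n in left_names])
            conf_r = np.mean([out.confidence[n][i] for n in right_names])
            drop = left_names if conf_l <= conf_r else right_names
            for name in drop:
                out.data[name][i] = np.nan
                out.confidence[name][i] = 0.0
            report.same_leg_frames.append(i)
    return out, report


# ---------------------------------------------------------------------------
# Step 3: gap filling
# ---------------------------------------------------------------------------


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of consecutive True runs."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def fill_gaps_series(x: np.ndarray, max_gap_frames: int = 2) -> np.ndarray:
    """Linearly interpolate NaN runs of at most ``max_gap_frames`` samples.

    Runs bounded by valid samples on both sides are filled; longer runs and
    runs touching the series boundary remain missing.  Valid samples are never
    altered.
    """
    x = np.array(x, dtype=float, copy=True)
    missing = ~np.isfinite(x)
    if missing.all():
        logger.warning("fill_gaps: series is entirely missing; returned unchanged")
        return x
    for start, stop in _nan_runs(missing):
        length = stop - start + 1
        if length > max_gap_frames or start == 0 or stop == len(x) - 1:
            continue
        x0, x1 = x[start - 1], x[stop + 1]
        frac = np.arange(1, length + 1) / (length + 1)
        x[start : stop + 1] = x0 + frac * (x1 - x0)
    return x


def fill_gaps(ts: TrajectorySet, max_gap_frames: int = 2) -> TrajectorySet:
    """Apply :func:`fill_gaps_series` to every landmark coordinate."""
    out = ts.copy()
    for name, arr in out.data.items():
        for j in (0, 1):
            arr[:, j] = fill_gaps_series(arr[:, j], max_gap_frames)
    return out


# ---------------------------------------------------------------------------
# Step 4: low-pass filtering
# ---------------------------------------------------------------------------


def lowpass_filter_series(
    x: np.ndarray, sampling_rate: float, cutoff_hz: float = 5.0, order: int = 4
) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter applied forward and backward.

    The forward-backward application doubles the effective magnitude order
    and cancels the phase (cross-correlation of output and passband input
    peaks at lag zero).  DC gain is exactly 1.  Each contiguous valid span is
    filtered independently; spans shorter than the filter warm-up length are
    left unfiltered with a warning.
    """
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate)
    padlen = 3 * max(len(a), len(b))  # filtfilt default edge padding
    x = np.array(x, dtype=float, copy=True)
    valid = np.isfinite(x)
    for start, stop in _nan_runs(valid):
        span = slice(start, stop + 1)
        if stop - start + 1 <= padlen:
            logger.warning(
                "lowpass_filter: span of %d samples shorter than warm-up (%d); left unfiltered",
                stop - start + 1,
                padlen,
            )
            continue
        x[span] = signal.filtfilt(b, a, x[span])
    return x


def filter_warmup_samples(order: int = 4) -> int:
    """Edge-padding length of the zero-lag Butterworth filter, in samples."""
    return 3 * (order + 1)


def lowpass_filter(
    ts: TrajectorySet, cutoff_hz: float = 5.0, order: int = 4
) -> TrajectorySet:
    out = ts.copy()
    for arr in out.data.values():
        for j in (0, 1):
            arr[:, j] = lowpass_filter_series(
                arr[:, j], out.sampling_rate, cutoff_hz, order
            )
    return out


# ---------------------------------------------------------------------------
# Steps 5-6: scaling
# ---------------------------------------------------------------------------


def compute_scaling(
    point_a_px,
    point_b_px,
    reference_distance_m: float = DEFAULT_REFERENCE_DISTANCE_M,
) -> ScalingCalibration:
    """Scaling factor from the horizontal pixel separation of two landmarks.

    The landmarks are typically the midpoints of two floor-tape strips a
    known distance apart; the scale ``s = distance / pixel_length`` (m/px)
    assumes the participant walks perpendicular to the camera at the depth of
    the reference.
    """
    if reference_distance_m <= 0:
        raise ValueError("reference distance must be positive")
    xa = np.asarray(point_a_px, dtype=float).ravel()[0]
    xb = np.asarray(point_b_px, dtype=float).ravel()[0]
    pixel_length = abs(xb - xa)
    if pixel_length == 0:
        raise ValueError("reference points have zero horizontal separation")
    return ScalingCalibration(
        reference_distance=reference_distance_m,
        reference_pixel_length=pixel_length,
        s=reference_distance_m / pixel_length,
    )


def dimensionalize(ts: TrajectorySet, calibration: ScalingCalibration) -> TrajectorySet:
    """Multiply every coordinate by the scale factor: x_dim = s * x_pixel."""
    if ts.units != "px":
        raise ValueError("dimensionalize expects pixel-unit trajectories")
    out = ts.copy()
    for arr in out.data.values():
        arr *= calibration.s
    out.units = "m"
    return out


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


@dataclass
class PreprocessReport:
    swap_report: SwapReport
    calibration: ScalingCalibration | None


def preprocess_pose(
    seq: PoseSequence,
    calibration: ScalingCalibration | None = None,
    *,
    confidence_threshold: float = 0.0,
    same_leg_eps_px: float = 5.0,
    max_gap_frames: int = 2,
    cutoff_hz: float = 5.0,
    filter_order: int = 4,
) -> tuple[TrajectorySet, PreprocessReport]:
    """Run the full chain: walking frame -> swap correction -> gap fill ->
    zero-lag low-pass filter -> dimensionalize (if a calibration is given)."""
    ts = to_walking_frame(seq, confidence_threshold)
    ts, swap_report = correct_limb_swaps(ts, same_leg_eps_px)
    ts = fill_gaps(ts, max_gap_frames)
    ts = lowpass_filter(ts, cutoff_hz, filter_order)
    if calibration is not None:
        ts = dimensionalize(ts, calibration)
    return ts, PreprocessReport(swap_report=swap_report, calibration=calibration)


__all__ = [
    "DEFAULT_REFERENCE_DISTANCE_M",
    "TrajectorySet",
    "SwapReport",
    "ScalingCalibration",
    "PreprocessReport",
    "flip_to_travel",
    "to_walking_frame",
    "correct_limb_swaps",
    "fill_gaps",
    "fill_gaps_series",
    "lowpass_filter",
    "lowpass_filter_series",
    "filter_warmup_samples",
    "compute_scaling",
    "dimensionalize",
    "preprocess_pose",
]
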