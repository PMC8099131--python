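"""Preprocessing: coordinate convention, swap repair, gap fill, filtering, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitpose import (
    DefectSpec,
    SyntheticGaitSpec,
    correct_limb_swaps,
    simulate,
    to_walking_frame,
)
from gaitpose.preprocess import (
    ScalingCalibration,
    compute_scaling,
    dimensionalize,
    fill_gaps_series,
    flip_to_travel,
    lowpass_filter_series,
    preprocess_pose,
)


class TestWalkingFrame:
    def test_left_view_corner_maps_to_origin(self):
        out = flip_to_travel(np.array([[960.0, 540.0]]), "left", (960, 540))
        np.testing.assert_allclose(out, [[0.0, 0.0]])

    def test_right_view_keeps_x_flips_y(self):
        out = flip_to_travel(np.array([[100.0, 40.0]]), "right", (960, 540))
        np.testing.assert_allclose(out, [[100.0, 500.0]])

    @given(x=st.floats(-1e4, 1e4), y=st.floats(-1e4, 1e4))
    @settings(max_examples=30, derandomize=True)
    def test_left_view_x_transform_is_involution(self, x, y):
        once = flip_to_travel(np.array([[x, y]]), "left", (960, 540))
        twice = flip_to_travel(once, "left", (960, 540))
        assert twice[0, 0] == pytest.approx(x, abs=1e-9)

    def test_missing_keypoints_become_nan(self, sim_bout):
        pose, _, _ = sim_bout
        pose = pose.__class__(
            xy=pose.xy.copy(),
            confidence=pose.confidence.copy(),
            frame_rate=pose.frame_rate,
            camera_side=pose.camera_side,
            image_size=pose.image_size,
        )
        pose.confidence[3, 14] = 0.0  # ankle_L
        ts = to_walking_frame(pose)
        assert np.isnan(ts.data["ankle_L"][3]).all()
        assert np.isfinite(ts.data["ankle_L"][2]).all()


class TestLimbSwapCorrection:
    def test_clean_sequence_unchanged_empty_report(self, sim_bout):
        pose, _, _ = sim_bout
        ts = to_walking_frame(pose)
        fixed, report = correct_limb_swaps(ts)
        assert report.n_changes == 0
        np.testing.assert_allclose(fixed.data["ankle_L"], ts.data["ankle_L"])

    def test_injected_swaps_repaired_and_reported(self):
        spec = SyntheticGaitSpec(
            bout_length=40.0, defects=DefectSpec(swap_rate=0.05), seed=7
        )
        pose, _, truth = simulate(spec)
        clean_pose, _, _ = simulate(SyntheticGaitSpec(bout_length=40.0))
        fixed, report = correct_limb_swaps(to_walking_frame(pose))
        clean = to_walking_frame(clean_pose)
        injected = truth.injection.swap_frames
        assert len(injected) > 20
        assert set(injected) <= set(report.swapped_frames)
        repaired = 0
        for i in injected:
            err = max(
                np.max(np.abs(fixed.data[n][i] - clean.data[n][i]))
                for n in ("ankle_L", "ankle_R", "knee_L", "knee_R")
            )
            repaired += err < 1.0  # px
        assert repaired / len(injected) >= 0.99

    def test_idempotent(self):
        spec = SyntheticGaitSpec(
            bout_length=20.0, defects=DefectSpec(swap_rate=0.05), seed=3
        )
        pose, _, _ = simulate(spec)
        fixed, _ = correct_limb_swaps(to_walking_frame(pose))
        _, report2 = correct_limb_swaps(fixed)
        assert report2.n_changes == 0

    def test_single_frame_sequence_unchanged(self, sim_bout):
        pose, _, _ = sim_bout
        one = pose.__class__(
            xy=pose.xy[:1].copy(),
            confidence=pose.confidence[:1].copy(),
            frame_rate=pose.frame_rate,
            camera_side=pose.camera_side,
            image_size=pose.image_size,
        )
        ts = to_walking_frame(one)
        fixed, report = correct_limb_swaps(ts)
        assert report.swapped_frames == []
        np.testing.assert_allclose(fixed.data["ankle_R"], ts.data["ankle_R"])

    def test_same_leg_frames_drop_lower_confidence_side(self, sim_bout):
        pose, _, _ = sim_bout
        seq = pose.__class__(
            xy=pose.xy.copy(),
            confidence=pose.confidence.copy(),
            frame_rate=pose.frame_rate,
            camera_side=pose.camera_side,
            image_size=pose.image_size,
        )
        # collapse right-leg keypoints onto the left leg at frame 10, with
        # lower confidence
        for li, ri in ((12, 9), (13, 10), (14, 11), (21, 24), (19, 22), (20, 23)):
            seq.xy[10, ri] = seq.xy[10, li]
            seq.confidence[10, ri] = 0.4
        ts = to_walking_frame(seq)
        fixed, report = correct_limb_swaps(ts)
        assert 10 in report.same_leg_frames
        assert np.isnan(fixed.data["ankle_R"][10]).all()
        assert np.isfinite(fixed.data["ankle_L"][10]).all()


class TestFillGaps:
    def test_linear_gap_restored_exactly(self):
        x = np.array([0.0, 1.0, np.nan, np.nan, 4.0])
        np.testing.assert_allclose(fill_gaps_series(x), [0, 1, 2, 3, 4])

    def test_three_frame_gap_left_missing(self):
        x = np.array([0.0, np.nan, np.nan, np.nan, 4.0])
        out = fill_gaps_series(x)
        assert np.isnan(out[1:4]).all()

    def test_leading_gap_left_missing(self):
        x = np.array([np.nan, 1.0, 2.0])
        out = fill_gaps_series(x)
        assert np.isnan(out[0]) and out[1] == 1.0

    @given(
        values=st.lists(st.floats(-100, 100), min_size=4, max_size=30),
        gap_start=st.integers(1, 20),
    )
    @settings(max_examples=40, derandomize=True)
    def test_valid_samples_never_altered(self, values, gap_start):
        x = np.asarray(values)
        if gap_start >= len(x) - 1:
            gap_start = len(x) - 2
        with_gap = x.copy()
        with_gap[gap_start] = np.nan
        out = fill_gaps_series(with_gap)
        keep = np.arange(len(x)) != gap_start
        np.testing.assert_array_equal(out[keep], x[keep])

    def test_all_missing_returned_unchanged(self):
        x = np.full(5, np.nan)
        assert np.isnan(fill_gaps_series(x)).all()


class TestLowpassFilter:
    def test_unit_dc_gain_on_constant(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(lowpass_filter_series(x, 25.0), x, atol=1e-9)

    def test_zero_phase_on_passband_tone(self):
        t = np.arange(0, 8, 1 / 25)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_filter_series(x, 25.0)
        lags = np.arange(-len(x) + 1, len(x))
        xc = np.correlate(y - y.mean(), x - x.mean(), mode="full")
        assert lags[np.argmax(xc)] == 0

    def test_stopband_attenuation_matches_butterworth_magnitude(self):
        # oracle: the squared magnitude response of the order-4 design at
        # 10 Hz (the filter runs forward and backward, squaring |H|)
        from scipy.signal import butter, freqz

        t = np.arange(0, 10, 1 / 100)
        x = np.sin(2 * np.pi * 10.0 * t)
        y = lowpass_filter_series(x, 100.0)
        mid = slice(200, 800)  # avoid edge transients
        gain = np.max(np.abs(y[mid]))
        b, a = butter(4, 5.0, fs=100.0)
        _, h = freqz(b, a, worN=[10.0], fs=100.0)
        expected = float(np.abs(h[0]) ** 2)
        assert gain < 0.01
        assert gain == pytest.approx(expected, rel=0.05)

    def test_energy_never_amplified_for_zero_mean_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        x -= x.mean()
        y = lowpass_filter_series(x, 100.0)
        assert np.sum(y**2) <= np.sum(x**2)

    def test_short_span_left_unfiltered(self):
        x = np.sin(np.arange(10))
        out = lowpass_filter_series(x, 25.0)
        np.testing.assert_array_equal(out, x)


class TestScaling:
    def test_arithmetic(self):
        cal = compute_scaling([0.0, 0.0], [630.0, 0.0], 6.3)
        assert cal.s == pytest.approx(0.01)
        assert cal.reference_pixel_length == pytest.approx(630.0)

    def test_linear_in_distance(self):
        s1 = compute_scaling([0, 0], [500, 0], 3.0).s
        s2 = compute_scaling([0, 0], [500, 0], 6.0).s
        assert s2 == pytest.approx(2 * s1)

    def test_default_reference_distance_is_walkway_tape_separation(self):
        from gaitpose.preprocess import DEFAULT_REFERENCE_DISTANCE_M

        assert DEFAULT_REFERENCE_DISTANCE_M == 6.30

    def test_zero_pixel_separation_rejected(self):
        with pytest.raises(ValueError):
            compute_scaling([10.0, 0.0], [10.0, 5.0], 6.3)

    def test_dimensionalize_multiplies_by_s(self, sim_bout):
        pose, _, truth = sim_bout
        ts = to_walking_frame(pose)
        cal = ScalingCalibration(6.3, 630.0, 0.01)
        out = dimensionalize(ts, cal)
        np.testing.assert_allclose(
            out.data["ankle_L"], ts.data["ankle_L"] * 0.01
        )
        assert out.units == "m"

    def test_identity_scale(self, sim_bout):
        pose, _, _ = sim_bout
        ts = to_walking_frame(pose)
        out = dimensionalize(ts, ScalingCalibration(6.3, 6.3, 1.0))
        np.testing.assert_allclose(out.data["pelvis"], ts.data["pelvis"])


class TestFullChain:
    def test_pelvis_displacement_matches_programmed_bout(self, pipeline_run):
        ts = pipeline_run.trajectories
        x = ts.x("pelvis")
        displacement = x[-1] - x[0]
        spec = pipeline_run.spec
        # one pixel-second of slack on the programmed bout length
        assert displacement == pytest.approx(spec.bout_length, abs=0.02)

    def test_defect_free_input_essentially_unchanged(self, sim_bout, pipeline_run):
        # low-frequency gait content must pass the 5 Hz filter untouched
        pose, _, truth = sim_bout
        ts_raw = to_walking_frame(pose)
        cal = pipeline_run.calibration
        raw_m = ts_raw.data["knee_L"] * cal.s
        filtered = pipeline_run.trajectories.data["knee_L"]
        mid = slice(20, -20)
        amp = np.ptp(raw_m[mid, 0])
        assert np.nanmax(np.abs(filtered[mid] - raw_m[mid])) < 0.01 * amp
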