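"""Heel-strike detection, GRF events, segmentation and normalization."""

import numpy as np
import pytest

from gaitstress import (
    ankle_hip_distance,
    detect_heel_strikes,
    detect_heel_strikes_grf,
    segment_strides,
)
from gaitstress.events import GaitEvents, InsufficientStridesError
from gaitstress.keypoints import KEYPOINT_NAMES, GrfSeries, KeypointSeries


def series_with(points: dict[str, np.ndarray], n: int) -> KeypointSeries:
    data = np.zeros((n, 17, 3))
    data[..., 2] = 1.0
    data[..., 0] = 100.0
    data[..., 1] = 100.0
    idx = {name: i for i, name in enumerate(KEYPOINT_NAMES)}
    for name, xy in points.items():
        data[:, idx[name], :2] = xy
    return KeypointSeries("p", "slow", 50.0, data)


# ---------------------------------------------------------------------------
# ankle-hip distance


def test_distance_zero_when_coincident():
    s = series_with({}, 10)  # all keypoints identical
    np.testing.assert_allclose(ankle_hip_distance(s, "left"), 0.0)


def test_distance_axis_aligned():
    pts = {
        "left_hip": np.tile([0.0, 0.0], (10, 1)),
        "left_ankle": np.tile([0.0, 100.0], (10, 1)),
    }
    np.testing.assert_allclose(ankle_hip_distance(series_with(pts, 10), "left"), 100.0)


def test_distance_translation_invariant(rng):
    n = 40
    hip = rng.uniform(0, 500, (n, 2))
    ankle = rng.uniform(0, 500, (n, 2))
    base = ankle_hip_distance(series_with({"left_hip": hip, "left_ankle": ankle}, n))
    for _ in range(5):
        shift = rng.uniform(-1000, 1000, size=2)
        moved = ankle_hip_distance(
            series_with({"left_hip": hip + shift, "left_ankle": ankle + shift}, n)
        )
        np.testing.assert_allclose(moved, base, atol=1e-8)


def test_distance_missing_flags_propagate(rng):
    n = 40
    s = series_with(
        {"left_hip": rng.uniform(0, 10, (n, 2)), "left_ankle": rng.uniform(0, 10, (n, 2))},
        n,
    )
    s.data[5, 15, 2] = 0.0  # left_ankle missing on frame 5
    d = ankle_hip_distance(s)
    assert np.isnan(d[5]) and np.isfinite(d[4])


# ---------------------------------------------------------------------------
# heel strikes from the distance series


def test_sinusoid_peaks_detected_at_argmax_plus_offset():
    """Brute-force oracle: exhaustive local-maxima scan on a noiseless sinusoid."""
    period = 60
    n = period * 10
    x = np.sin(2 * np.pi * np.arange(n) / period)
    # oracle: every interior strict local maximum
    truth = np.array(
        [i for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] >= x[i + 1]]
    )
    ev = detect_heel_strikes(x, fps=50.0, offset_frames=1)
    np.testing.assert_array_equal(ev.heel_strike_frames, truth + 1)
    assert np.all(np.diff(ev.heel_strike_frames) == period)


def test_offset_is_one_frame_at_50hz():
    # +1 frame at 50 Hz corresponds to a 0.02 s shift
    period = 50
    x = np.sin(2 * np.pi * np.arange(500) / period)
    ev0 = detect_heel_strikes(x, 50.0, offset_frames=0)
    ev1 = detect_heel_strikes(x, 50.0, offset_frames=1)
    np.testing.assert_array_equal(ev1.heel_strike_frames, ev0.heel_strike_frames + 1)
    assert (ev1.heel_strike_frames[0] - ev0.heel_strike_frames[0]) / 50.0 == 0.02


def test_monotone_series_has_no_events():
    with pytest.raises(InsufficientStridesError):
        detect_heel_strikes(np.linspace(0, 1, 500), 50.0, min_period_s=0.5)


def test_plateau_maxima_resolve_to_first_frame():
    x = np.zeros(300)
    for start in (50, 150, 250):
        x[start : start + 5] = 1.0  # 5-frame plateaus
    ev = detect_heel_strikes(x, 50.0, min_period_s=1.0, offset_frames=1)
    np.testing.assert_array_equal(ev.heel_strike_frames, [51, 151, 251])


def test_scaling_and_translation_invariance(noiseless_walker):
    kp, _, _ = noiseless_walker
    base = detect_heel_strikes(ankle_hip_distance(kp), kp.fps).heel_strike_frames
    moved = kp.data.copy()
    moved[..., :2] = moved[..., :2] * 3.7 + np.array([211.0, -97.0])
    kp2 = KeypointSeries(kp.participant_id, kp.bout, kp.fps, moved)
    np.testing.assert_array_equal(
        detect_heel_strikes(ankle_hip_distance(kp2), kp.fps).heel_strike_frames, base
    )


# ---------------------------------------------------------------------------
# GRF events


def test_grf_square_wave_rising_edges():
    sr = 1000.0
    n = int(6 * sr)
    t = np.arange(n) / sr
    force = np.where((t % 1.2) < 0.7, 700.0, 0.0)
    grf = GrfSeries("p", "slow", sr, force, np.zeros(n))
    ev = detect_heel_strikes_grf(grf, threshold_n=20.0)
    # rising edges at 1.2 s intervals, converted to 50 Hz frames
    np.testing.assert_array_equal(np.diff(ev.heel_strike_frames), 60)


def test_grf_all_zero_raises():
    grf = GrfSeries("p", "slow", 1000.0, np.zeros(5000), np.zeros(5000))
    with pytest.raises(InsufficientStridesError):
        detect_heel_strikes_grf(grf)


def test_grf_and_keypoint_events_agree(noiseless_walker):
    kp, grf, truth = noiseless_walker
    kp_ev = detect_heel_strikes(ankle_hip_distance(kp), kp.fps)
    grf_ev = detect_heel_strikes_grf(grf, keypoint_fps=kp.fps)
    # align on overlapping events and compare frame indices
    common = min(kp_ev.n_events, grf_ev.n_events)
    diff = kp_ev.heel_strike_frames[:common] - grf_ev.heel_strike_frames[:common]
    assert np.all(np.abs(diff) <= 2)


# ---------------------------------------------------------------------------
# segmentation


def test_single_stride_arithmetic():
    ev = GaitEvents("p", "slow", [0, 60], "keypoint", fps=50.0)
    ss = segment_strides(np.arange(100.0), ev)
    assert ss.n_strides == 1
    assert ss.stride_times[0] == pytest.approx(1.2)
    assert ss.strides.shape == (1, 101)


def test_linear_ramp_resampled_exactly():
    ev = GaitEvents("p", "slow", [10, 65], "keypoint", fps=50.0)
    ramp = 3.0 * np.arange(200.0) - 7.0
    ss = segment_strides(ramp, ev)
    expected = np.linspace(ramp[10], ramp[65], 101)
    np.testing.assert_allclose(ss.strides[0], expected, atol=1e-9)


def test_implausible_stride_dropped_and_counted():
    ev = GaitEvents("p", "slow", [0, 5, 65, 125], "keypoint", fps=50.0)  # 0.1 s glitch
    ss = segment_strides(np.sin(np.arange(200.0)), ev)
    assert ss.n_strides == 2
    assert ss.dropped == 1


def test_stride_count_matches_events(noiseless_walker):
    kp, _, _ = noiseless_walker
    ev = detect_heel_strikes(ankle_hip_distance(kp), kp.fps)
    ss = segment_strides(ankle_hip_distance(kp), ev)
    assert ss.n_strides + ss.dropped == ev.n_events - 1


def test_stride_time_recovery_within_one_frame(noiseless_walker):
    kp, _, truth = noiseless_walker
    ev = detect_heel_strikes(ankle_hip_distance(kp), kp.fps)
    mae = np.abs(ev.stride_times_s - truth.stride_time_s).mean()
    assert mae <= 0.02
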