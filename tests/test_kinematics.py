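"""Joint-angle conventions, arm-stride exclusion, cv and ROM features."""

import numpy as np
import pytest

from gaitstress import (
    ankle_hip_distance,
    coefficient_of_variation,
    detect_heel_strikes,
    joint_angles,
    range_of_motion,
    segment_strides,
)
from gaitstress.events import StrideSet
from gaitstress.keypoints import KEYPOINT_NAMES, KeypointSeries
from gaitstress.kinematics import (
    UndefinedCvError,
    build_feature_table,
    exclude_nonfunctional_arm_strides,
    nonfunctional_arm_strides,
)
from gaitstress.simulate import DEFAULT_WAVEFORMS

_IDX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}


def pose(points: dict[str, tuple[float, float]], n=3) -> KeypointSeries:
    data = np.zeros((n, 17, 3))
    data[..., 2] = 1.0
    # spread unspecified keypoints so no segment degenerates
    for i in range(17):
        data[:, i, 0] = 10.0 * i
        data[:, i, 1] = 5.0 * i
    for name, (x, y) in points.items():
        data[:, _IDX[name], 0] = x
        data[:, _IDX[name], 1] = y
    return KeypointSeries("p", "slow", 50.0, data)


def test_vertical_posture_gives_zero_hip_and_knee():
    # hip above knee above ankle on one vertical line, trunk vertical (y down)
    s = pose(
        {
            "left_shoulder": (0, -100),
            "left_hip": (0, 0),
            "left_knee": (0, 50),
            "left_ankle": (0, 100),
        }
    )
    a = joint_angles(s, forward="+x")
    np.testing.assert_allclose(a["hip_flexion"], 0.0, atol=1e-9)
    np.testing.assert_allclose(a["knee_flexion"], 0.0, atol=1e-9)


def test_right_angle_knee_example():
    # direct vector computation: thigh vertical, shank horizontal -> 90 deg
    s = pose(
        {
            "left_shoulder": (0, -100),
            "left_hip": (0, 0),
            "left_knee": (0, 50),
            "left_ankle": (50, 50),
        }
    )
    a = joint_angles(s, forward="-x")
    np.testing.assert_allclose(a["knee_flexion"], 90.0, atol=1e-9)


def test_straight_hanging_arm_zero_angles():
    s = pose(
        {
            "left_hip": (0, 0),
            "left_shoulder": (0, -100),
            "left_elbow": (0, -40),
            "left_wrist": (0, 20),
        }
    )
    a = joint_angles(s)
    np.testing.assert_allclose(a["shoulder_flexion"], 0.0, atol=1e-9)
    np.testing.assert_allclose(a["elbow_flexion"], 0.0, atol=1e-7)
    np.testing.assert_allclose(a["arm_swing"], 0.0, atol=1e-9)


def test_angles_invariant_to_translation_and_scale(noiseless_walker, rng):
    kp, _, _ = noiseless_walker
    base = joint_angles(kp)
    moved = kp.data.copy()
    moved[..., :2] = moved[..., :2] * 2.5 + np.array([-300.0, 140.0])
    a2 = joint_angles(KeypointSeries(kp.participant_id, kp.bout, kp.fps, moved))
    for name in base.angles:
        np.testing.assert_allclose(a2[name], base[name], atol=1e-8)


def test_degenerate_segment_flagged_nan():
    s = pose({"left_hip": (0, 0), "left_knee": (0, 0), "left_ankle": (10, 50),
              "left_shoulder": (0, -100)})
    a = joint_angles(s)
    assert np.isnan(a["knee_flexion"]).all()
    assert np.isfinite(a["arm_swing"]).all()


def test_angle_recovery_noiseless(noiseless_walker):
    """Stride-segmented angles match the generating waveforms within 1 deg."""
    kp, _, truth = noiseless_walker
    angles = joint_angles(kp)
    ev = detect_heel_strikes(ankle_hip_distance(kp), kp.fps)
    for name in ("hip_flexion", "knee_flexion", "shoulder_flexion", "elbow_flexion"):
        ss = segment_strides(angles[name], ev, signal_name=name)
        m = min(ss.n_strides, truth.angle_strides[name].shape[0])
        rmse = np.sqrt(np.mean((ss.strides[:m] - truth.angle_strides[name][:m]) ** 2))
        assert rmse <= 1.0, f"{name}: RMSE {rmse:.2f} deg"


def test_angle_recovery_with_keypoint_noise(noiseless_walker, noisy_walker):
    """Per-frame angles from 2 px-noise keypoints stay within 3 deg RMSE of
    the generating angles (after the pipeline's 10 Hz low-pass)."""
    from gaitstress import filter_trajectories

    kp_clean, _, _ = noiseless_walker
    kp_noisy, _, _ = noisy_walker
    truth = joint_angles(kp_clean)
    recovered = joint_angles(filter_trajectories(kp_noisy))
    edge = 25  # skip filter edge transients
    for name in truth.angles:
        err = recovered[name][edge:-edge] - truth[name][edge:-edge]
        rmse = np.sqrt(np.mean(err**2))
        assert rmse <= 3.0, f"{name}: RMSE {rmse:.2f} deg"


# ---------------------------------------------------------------------------
# arm-stride exclusion


def _strides(mat, name="elbow_flexion"):
    mat = np.asarray(mat, dtype=float)
    return StrideSet("p", "slow", name, mat, np.full(mat.shape[0], 1.1))


def test_high_interior_angle_not_excluded():
    elbow = _strides(np.full((3, 101), 10.0))  # interior 170 deg
    assert not nonfunctional_arm_strides(elbow).any()


def test_dipping_stride_excluded_everywhere():
    flex = np.full((3, 101), 20.0)
    flex[1, 50] = 105.0  # interior dips to 75 deg on stride 1
    sets = {
        "elbow_flexion": _strides(flex),
        "arm_swing": _strides(np.ones((3, 101)), "arm_swing"),
        "hip_flexion": _strides(np.ones((3, 101)), "hip_flexion"),
    }
    out, mask = exclude_nonfunctional_arm_strides(sets)
    np.testing.assert_array_equal(mask, [False, True, False])
    assert out["elbow_flexion"].n_strides == 2
    assert out["arm_swing"].n_strides == 2
    assert out["hip_flexion"].n_strides == 3  # leg signals untouched


def test_zero_threshold_disables_exclusion():
    flex = np.full((2, 101), 150.0)  # interior 30 deg, normally excluded
    out, mask = exclude_nonfunctional_arm_strides(
        {"elbow_flexion": _strides(flex)}, interior_threshold_deg=0.0
    )
    assert not mask.any()
    assert out["elbow_flexion"].n_strides == 2


def test_all_excluded_drops_arm_features():
    flex = np.full((2, 101), 150.0)
    out, mask = exclude_nonfunctional_arm_strides({"elbow_flexion": _strides(flex)})
    assert mask.all() and "elbow_flexion" not in out


# ---------------------------------------------------------------------------
# coefficient of variation


def test_cv_zero_for_identical_strides():
    assert coefficient_of_variation(_strides(np.tile(np.sin(np.arange(101)), (5, 1)) + 3)) == 0.0


def test_cv_two_constant_strides_hand_value():
    # sigma_i = sample SD of {1, 3} = sqrt(2), mean |X_i| = 2 -> cv = sqrt(2)/2
    cv = coefficient_of_variation(_strides([np.ones(101), 3 * np.ones(101)]))
    assert cv == pytest.approx(np.sqrt(2) / 2, abs=1e-12)


def test_cv_scale_invariant_offset_sensitive(rng):
    mat = rng.normal(10, 1, size=(6, 101))
    base = coefficient_of_variation(_strides(mat))
    assert coefficient_of_variation(_strides(4.2 * mat)) == pytest.approx(base, rel=1e-12)
    shifted = coefficient_of_variation(_strides(mat + 50.0))
    assert shifted != pytest.approx(base, rel=1e-3)  # denominator grows
    assert shifted < base


def test_cv_zero_mean_waveform_undefined():
    with pytest.raises(UndefinedCvError):
        coefficient_of_variation(_strides([np.ones(101), -np.ones(101)]))


# ---------------------------------------------------------------------------
# range of motion


def test_rom_constant_stride_zero():
    assert range_of_motion(_strides(np.full((2, 101), 7.0))) == 0.0


def test_rom_sinusoid_twice_amplitude():
    x = np.linspace(0, 1, 101)
    mat = 5.0 * np.sin(2 * np.pi * x)[None, :] + 20.0
    assert range_of_motion(_strides(mat)) == pytest.approx(10.0, rel=1e-3)


def test_rom_node_count_bias_small():
    # at 101 nodes the ROM bias on one sinusoidal cycle is < 0.1 %
    x = np.linspace(0, 1, 101)
    rom = range_of_motion(_strides(np.sin(2 * np.pi * x)[None, :]))
    assert abs(rom - 2.0) / 2.0 < 1e-3


def test_rom_recovery_on_walker(noiseless_walker):
    kp, _, truth = noiseless_walker
    angles = joint_angles(kp)
    ev = detect_heel_strikes(ankle_hip_distance(kp), kp.fps)
    ss = segment_strides(angles["arm_swing"], ev, signal_name="arm_swing")
    assert range_of_motion(ss) == pytest.approx(truth.rom["arm_swing"], abs=1.0)


# ---------------------------------------------------------------------------
# feature table


def test_feature_table_is_mean_of_bouts():
    feats_a = {"stride_time_s": 1.1, "cv_hip": 0.1}
    feats_b = {"stride_time_s": 1.3, "cv_hip": 0.3}
    table = build_feature_table({"p1": {"slow": feats_a, "fast": feats_b}}, {"p1": "OMC"})
    row = table.iloc[0]
    assert row["stride_time_s"] == pytest.approx(1.2)
    assert row["cv_hip"] == pytest.approx(0.2)
    # identical bouts reproduce either bout exactly
    same = build_feature_table({"p1": {"slow": feats_a, "fast": dict(feats_a)}}, {"p1": "OMC"})
    assert same.iloc[0]["stride_time_s"] == pytest.approx(1.1)


def test_feature_table_requires_both_bouts():
    with pytest.raises(ValueError, match="bouts"):
        build_feature_table({"p1": {"slow": {"stride_time_s": 1.0}}}, {"p1": "OMC"})
    table = build_feature_table(
        {"p1": {"slow": {"stride_time_s": 1.0}}}, {"p1": "OMC"}, allow_single_bout=True
    )
    assert len(table) == 1
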