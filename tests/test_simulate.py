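"""Synthetic-data generator: determinism, truth recovery, effect injection."""

import numpy as np
import pytest

from gaitstress import (
    ankle_hip_distance,
    cortisol_features,
    detect_heel_strikes,
    joint_angles,
    segment_strides,
    simulate_cortisol,
    simulate_walker,
)
from gaitstress.kinematics import coefficient_of_variation
from gaitstress.simulate import (
    CohortSpec,
    WalkerParams,
    default_control_group,
    default_omc_group,
    simulate_cohort,
)

SAMPLES = (0.0, 15.0, 25.0, 32.5, 47.5, 57.5)


def test_same_seed_bit_identical():
    p = WalkerParams(stride_time=1.2, duration=10.0, noise_sd=2.0, seed=42)
    kp1, grf1, _ = simulate_walker(p)
    kp2, grf2, _ = simulate_walker(p)
    np.testing.assert_array_equal(kp1.data, kp2.data)
    np.testing.assert_array_equal(grf1.force_left, grf2.force_left)


def test_different_seeds_differ():
    kp1 = simulate_walker(WalkerParams(duration=5.0, noise_sd=2.0, seed=1))[0]
    kp2 = simulate_walker(WalkerParams(duration=5.0, noise_sd=2.0, seed=2))[0]
    assert not np.array_equal(kp1.data, kp2.data)


def test_noiseless_recovery_and_zero_cv(noiseless_walker):
    kp, _, truth = noiseless_walker
    ev = detect_heel_strikes(ankle_hip_distance(kp), kp.fps)
    det, exp = ev.heel_strike_frames, truth.heel_strike_frames + 1
    inner = det[(det >= exp[0]) & (det <= exp[-1])]
    np.testing.assert_array_equal(inner, exp)
    assert np.abs(ev.stride_times_s - truth.stride_time_s).max() <= 0.02
    # identical strides by construction -> pipeline cv = 0
    angles = joint_angles(kp)
    for name in ("hip_flexion", "knee_flexion"):
        ss = segment_strides(angles[name], ev, signal_name=name)
        assert coefficient_of_variation(ss) == pytest.approx(0.0, abs=1e-10)


def test_clothing_bias_isolates_knee_artifact():
    """A knee-keypoint offset (clothing slipping over the knee) shifts
    recovered late-stance knee flexion while late-stance hip flexion stays
    essentially unchanged — the clothing-artifact mechanism."""
    base = WalkerParams(stride_time=1.1, duration=12.0, noise_sd=0.0, seed=5)
    biased = WalkerParams(
        stride_time=1.1, duration=12.0, noise_sd=0.0, seed=5,
        clothing_bias={"left_knee": (0.0, 8.0)},
    )
    out = {}
    for tag, params in (("plain", base), ("biased", biased)):
        kp, _, _ = simulate_walker(params)
        ev = detect_heel_strikes(ankle_hip_distance(kp), kp.fps)
        ang = joint_angles(kp)
        out[tag] = {
            n: segment_strides(ang[n], ev, signal_name=n).mean_waveform()
            for n in ("hip_flexion", "knee_flexion")
        }
    late = slice(40, 61)  # 40-60% of the gait cycle
    knee_shift = np.abs(
        out["biased"]["knee_flexion"][late] - out["plain"]["knee_flexion"][late]
    ).max()
    hip_shift = np.abs(
        out["biased"]["hip_flexion"][late] - out["plain"]["hip_flexion"][late]
    ).max()
    assert knee_shift > 1.0
    assert hip_shift < 0.5


def test_hyperextension_guard():
    from gaitstress.simulate import FourierWaveform

    with pytest.raises(ValueError, match="hyperextend"):
        WalkerParams(
            waveforms={
                "hip_flexion": FourierWaveform(8.0, (22.0,), (0.0,)),
                "knee_flexion": FourierWaveform(0.0, (30.0,), (np.pi,)),
                "shoulder_flexion": FourierWaveform(-2.0),
                "elbow_flexion": FourierWaveform(25.0),
            }
        )


# ---------------------------------------------------------------------------
# cortisol curves


def test_zero_amplitude_flat_non_responder():
    series, truth = simulate_cortisol(3.0, 0.0, 10.0, SAMPLES)
    np.testing.assert_allclose(series.concentration, 3.0)
    assert not truth["true_responder"]
    assert not cortisol_features(series).responder


def test_sample_at_peak_recovers_amplitude():
    # S2 at onset + peak delay hits the pulse maximum exactly
    times = (0.0, 15.0, 10.0 + 17.5, 40.0, 50.0, 60.0)
    series, truth = simulate_cortisol(3.0, 3.0, 10.0, times, peak_delay_min=17.5)
    f = cortisol_features(series)
    assert f.max_increase == pytest.approx(3.0, abs=1e-12)
    assert f.responder and truth["true_responder"]


def test_peak_between_samples_attenuates():
    # no sample lands on the peak: the sampled max underestimates amplitude
    times = (0.0, 5.0, 40.0, 50.0, 60.0, 70.0)
    series, truth = simulate_cortisol(3.0, 3.0, 10.0, times)
    f = cortisol_features(series)
    assert f.max_increase < 3.0
    assert f.max_increase == pytest.approx(truth["true_max_increase"], abs=1e-12)


def test_peak_delay_physiological_window():
    # the pulse peaks peak_delay minutes after onset, inside 15-20 min
    t = np.linspace(0, 120, 24001)
    for delay in (15.0, 17.5, 20.0):
        series, _ = simulate_cortisol(
            3.0, 2.0, 0.0, (0.0, 10.0, 20.0, 30.0, 40.0, 50.0), peak_delay_min=delay
        )
        k = delay / 10.0
        pulse = np.where(t > 0, (t / delay) ** k * np.exp((delay - t) / 10.0), 0)
        assert t[np.argmax(pulse)] == pytest.approx(delay, abs=0.01)


def test_noise_clipped_non_negative(rng):
    series, _ = simulate_cortisol(0.1, 0.0, 10.0, SAMPLES, noise_sd=2.0, rng=rng)
    assert (series.concentration >= 0).all()


# ---------------------------------------------------------------------------
# cohort


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(
        omc=default_omc_group(3), control=default_control_group(3), duration_s=40.0, seed=11
    )
    return simulate_cohort(spec)


def test_cohort_structure(small_cohort):
    assert len(small_cohort.participants) == 6
    omc = small_cohort.by_group("OMC")
    ctl = small_cohort.by_group("control")
    assert len(omc) == 3 and len(ctl) == 3
    for p in omc:
        assert {q.timepoint for q in p.questionnaires} == {"Q-pre", "Q-marker", "Q-post"}
        assert set(p.keypoints) == {"slow", "fast"}
    for p in ctl:
        # control group never fills Q-marker, as in the protocol
        assert {q.timepoint for q in p.questionnaires} == {"Q-pre", "Q-post"}


def test_cohort_seed_determinism():
    spec = CohortSpec(
        omc=default_omc_group(2), control=default_control_group(2), duration_s=20.0, seed=4
    )
    c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
    for p1, p2 in zip(c1.participants, c2.participants):
        np.testing.assert_array_equal(p1.keypoints["slow"].data, p2.keypoints["slow"].data)
        np.testing.assert_array_equal(p1.cortisol.concentration, p2.cortisol.concentration)
        for q1, q2 in zip(p1.questionnaires, p2.questionnaires):
            np.testing.assert_array_equal(q1.items, q2.items)


def test_responder_count_by_construction(small_cohort):
    # classification from noiseless truth must match the truth flag when the
    # sampled increase is far from the 1.5 nmol/L boundary
    for p in small_cohort.participants:
        truth = p.cortisol_truth
        f = cortisol_features(p.cortisol)
        margin = abs(truth["true_max_increase"] - 1.5)
        if margin > 3 * 0.05 * max(1.0, truth["baseline"] + truth["true_max_increase"]):
            assert f.responder == truth["true_responder"], p.participant_id


def test_cohort_writes_readable_dataset(tmp_path, small_cohort):
    from gaitstress import read_cortisol, read_keypoints, read_questionnaires

    out = tmp_path / "ds"
    small_cohort.write(out)
    assert (out / "truth.json").exists()
    cort = read_cortisol(out / "cortisol.csv")
    assert len(cort) == 6
    kp = read_keypoints(out / "P001_slow_keypoints.csv")
    np.testing.assert_allclose(
        kp.data, small_cohort.participants[0].keypoints["slow"].data, atol=1e-9
    )
    quest = read_questionnaires(out / "questionnaires.csv")
    assert len(quest) == sum(len(p.questionnaires) for p in small_cohort.participants)
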