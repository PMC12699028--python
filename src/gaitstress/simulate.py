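"""Ground-truth-labelled synthetic inputs for every pipeline stage.

A planar kinematic walker generates sagittal keypoint trajectories by
forward kinematics of a trunk-leg-arm chain driven by truncated-Fourier
joint-angle waveforms, with an accompanying vertical ground-reaction-force
trace; delayed gamma-shaped cortisol pulses emulate the salivary response
to a stressor (peaking 15-20 min after onset); Likert item responses are
drawn around configurable subscale means per group and timepoint. Every
generator records its generating quantities losslessly as simulation
truth, so recovery by the analysis pipeline can be checked exactly.

The default cohort emulates the study conditions the package targets:
two groups (OMC with tight clothing, markers and a pose-estimation
clothing bias on the knee keypoint; control in everyday clothing), two
four-minute treadmill bouts per participant (0.9 and 1.2 m/s, video at
50 Hz), six saliva samples S0-S5, and PANAS/SSSQ questionnaires at Q-pre,
Q-marker (OMC only) and Q-post.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .events import N_NODES, GaitEvents, StrideSet, segment_strides
from .keypoints import (
    KEYPOINT_NAMES,
    CortisolSeries,
    GrfSeries,
    KeypointSeries,
    QuestionnaireResponse,
    write_cortisol,
    write_grf,
    write_keypoints,
    write_questionnaires,
)
from .kinematics import coefficient_of_variation, range_of_motion
from .stress import (
    DEFAULT_PANAS_KEY,
    DEFAULT_SSSQ_KEY,
    PANAS_SUBSCALES,
    RESPONDER_THRESHOLD_NMOL_L,
    SSSQ_DIMENSIONS,
)

__all__ = [
    "FourierWaveform",
    "WalkerParams",
    "WalkerTruth",
    "simulate_walker",
    "simulate_cortisol",
    "CohortSpec",
    "GroupSpec",
    "ParticipantData",
    "CohortData",
    "simulate_cohort",
]

_KP_INDEX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}


@dataclass(frozen=True)
class FourierWaveform:
    """Joint-angle waveform over the gait cycle: truncated Fourier series.

    angle(phase) = mean + sum_k amps[k] * cos(2 pi (k+1) phase + phases[k]),
    in degrees, with phase in cycles (0..1, 0 = heel strike).
    """

    mean: float
    amps: tuple[float, ...] = ()
    phases: tuple[float, ...] = ()

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        out = np.full_like(phase, self.mean)
        for k, (a, p) in enumerate(zip(self.amps, self.phases), start=1):
            out = out + a * np.cos(2.0 * np.pi * k * phase + p)
        return out


# Default joint waveforms: smooth normative-shaped sagittal curves
# (heel strike at phase 0; hip maximally flexed at contact, knee nearly
# extended at contact with a single swing-flexion peak, arms antiphase
# with the ipsilateral leg).
DEFAULT_WAVEFORMS: dict[str, FourierWaveform] = {
    "hip_flexion": FourierWaveform(8.0, (22.0,), (0.0,)),
    "knee_flexion": FourierWaveform(27.0, (25.0, 6.0), (np.pi, -0.6)),
    "shoulder_flexion": FourierWaveform(-2.0, (10.0,), (np.pi,)),
    "elbow_flexion": FourierWaveform(25.0, (10.0,), (np.pi,)),
}


@dataclass
class WalkerParams:
    """Planar-walker configuration (pixels, seconds, degrees)."""

    stride_time: float = 1.2
    fps: float = 50.0
    duration: float = 240.0
    trunk_len: float = 250.0
    thigh_len: float = 200.0
    shank_len: float = 200.0
    upper_arm_len: float = 150.0
    forearm_len: float = 130.0
    hip_xy: tuple[float, float] = (600.0, 500.0)
    hip_bounce_px: float = 5.0
    trunk_lean_deg: float = 3.0
    forward: str = "+x"
    waveforms: dict[str, FourierWaveform] = field(
        default_factory=lambda: dict(DEFAULT_WAVEFORMS)
    )
    noise_sd: float = 0.0
    clothing_bias: dict[str, tuple[float, float]] = field(default_factory=dict)
    grf_sample_rate: float = 1000.0
    body_weight_n: float = 700.0
    stance_fraction: float = 0.6  # standard gait value; used for GRF synthesis
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.6 <= self.stride_time <= 2.0:
            raise ValueError("stride_time must lie in [0.6, 2.0] s")
        if self.fps <= 0 or self.duration <= 0 or self.noise_sd < 0:
            raise ValueError("fps/duration must be positive, noise_sd >= 0")
        if self.forward not in ("+x", "-x"):
            raise ValueError("forward must be '+x' or '-x'")
        phases = np.linspace(0.0, 1.0, 2001)
        knee = self.waveforms["knee_flexion"](phases)
        if knee.min() < -10.0:
            raise ValueError(
                f"knee waveform hyperextends to {knee.min():.1f} deg; "
                "adjust the Fourier coefficients"
            )


@dataclass
class WalkerTruth:
    """Generating quantities of one walker run, stored losslessly.

    Heel strikes are the frames of maximum ankle-hip distance (recorded
    *before* the one-frame detection offset). Angle strides are the
    noiseless generating angle signals segmented at the offset events and
    resampled to 101 nodes; cv and ROM are computed from them.
    """

    heel_strike_frames: np.ndarray
    stride_time_s: float
    angle_strides: dict[str, np.ndarray]  # signal -> (M, 101)
    mean_waveforms: dict[str, np.ndarray]  # signal -> (101,)
    cv: dict[str, float]
    rom: dict[str, float]

    def to_jsonable(self) -> dict:
        return {
            "heel_strike_frames": self.heel_strike_frames.tolist(),
            "stride_time_s": self.stride_time_s,
            "mean_waveforms": {k: v.tolist() for k, v in self.mean_waveforms.items()},
            "cv": self.cv,
            "rom": self.rom,
        }


def _dir_down(theta_rad: np.ndarray, f: float) -> np.ndarray:
    """Unit vector at inclination theta from the downward image vertical."""
    return np.stack([f * np.sin(theta_rad), np.cos(theta_rad)], axis=-1)


def _dir_up(theta_rad: np.ndarray, f: float) -> np.ndarray:
    return np.stack([f * np.sin(theta_rad), -np.cos(theta_rad)], axis=-1)


def simulate_walker(
    params: WalkerParams,
    *,
    participant_id: str = "sim",
    bout: str = "slow",
    offset_frames: int = 1,
) -> tuple[KeypointSeries, GrfSeries, WalkerTruth]:
    """Generate one walking trial with keypoints, GRF and ground truth.

    The hip bounces vertically at stride frequency; leg and arm keypoints
    follow from forward kinematics of the planar chain under the
    joint-angle waveforms. Vertical GRF is a double-bump profile active
    for ``stance_fraction`` of each cycle starting at each true heel
    strike. Gaussian pixel noise and per-keypoint clothing-bias offsets
    are added after the truth is recorded; runs are reproducible under
    ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    f = 1.0 if p.forward == "+x" else -1.0
    n = int(round(p.duration * p.fps))
    t = np.arange(n) / p.fps
    phase = t / p.stride_time

    deg = np.pi / 180.0
    theta_tr = np.full(n, p.trunk_lean_deg * deg)
    hip_f = p.waveforms["hip_flexion"](phase) * deg
    knee_f = p.waveforms["knee_flexion"](phase) * deg
    sh_f = p.waveforms["shoulder_flexion"](phase) * deg
    el_f = p.waveforms["elbow_flexion"](phase) * deg
    hip_f_r = p.waveforms["hip_flexion"](phase + 0.5) * deg
    knee_f_r = p.waveforms["knee_flexion"](phase + 0.5) * deg
    sh_f_r = p.waveforms["shoulder_flexion"](phase + 0.5) * deg
    el_f_r = p.waveforms["elbow_flexion"](phase + 0.5) * deg

    hip_l = np.column_stack(
        [
            np.full(n, p.hip_xy[0]),
            p.hip_xy[1] + p.hip_bounce_px * np.sin(2.0 * np.pi * phase),
        ]
    )
    shoulder_l = hip_l + p.trunk_len * _dir_up(theta_tr, f)

    def leg(hip_pt, hipflex, kneeflex):
        th_thigh = theta_tr + hipflex
        knee = hip_pt + p.thigh_len * _dir_down(th_thigh, f)
        ankle = knee + p.shank_len * _dir_down(th_thigh - kneeflex, f)
        return knee, ankle

    def arm(sh_pt, shflex, elflex):
        th_ua = theta_tr + shflex
        elbow = sh_pt + p.upper_arm_len * _dir_down(th_ua, f)
        wrist = elbow + p.forearm_len * _dir_down(th_ua + elflex, f)
        return elbow, wrist

    hip_r = hip_l + np.array([0.0, 3.0])
    shoulder_r = shoulder_l + np.array([0.0, 3.0])
    knee_l, ankle_l = leg(hip_l, hip_f, knee_f)
    knee_r, ankle_r = leg(hip_r, hip_f_r, knee_f_r)
    elbow_l, wrist_l = arm(shoulder_l, sh_f, el_f)
    elbow_r, wrist_r = arm(shoulder_r, sh_f_r, el_f_r)

    # rigid head placed relative to the left shoulder
    head = {
        "nose": shoulder_l + np.array([f * 18.0, -35.0]),
        "left_eye": shoulder_l + np.array([f * 14.0, -45.0]),
        "right_eye": shoulder_l + np.array([f * 10.0, -47.0]),
        "left_ear": shoulder_l + np.array([f * 4.0, -42.0]),
        "right_ear": shoulder_l + np.array([f * 1.0, -44.0]),
    }

    points = {
        "left_shoulder": shoulder_l,
        "right_shoulder": shoulder_r,
        "left_elbow": elbow_l,
        "right_elbow": elbow_r,
        "left_wrist": wrist_l,
        "right_wrist": wrist_r,
        "left_hip": hip_l,
        "right_hip": hip_r,
        "left_knee": knee_l,
        "right_knee": knee_r,
        "left_ankle": ankle_l,
        "right_ankle": ankle_r,
        **head,
    }

    # ---- truth: events from the noiseless ankle-hip distance -------------
    dist = np.linalg.norm(ankle_l - hip_l, axis=1)
    min_sep = max(1, int(round(0.6 * p.stride_time * p.fps)))
    peaks, props = _sig.find_peaks(dist, distance=min_sep, plateau_size=(1, None))
    true_events = props["left_edges"]
    # keep only peaks with at least half a cycle of margin to the trial
    # edges: truncated edge cycles have no well-defined distance maximum
    margin = int(round(0.45 * p.stride_time * p.fps))
    true_events = true_events[(true_events >= margin) & (true_events <= n - 1 - margin)]
    if true_events.size < 2:
        raise ValueError("trial too short: fewer than two gait cycles")

    angles_true = {
        "hip_flexion": hip_f / deg,
        "knee_flexion": knee_f / deg,
        "shoulder_flexion": sh_f / deg,
        "elbow_flexion": el_f / deg,
        "arm_swing": np.degrees(
            np.arctan2(f * (wrist_l - shoulder_l)[:, 0], (wrist_l - shoulder_l)[:, 1])
        ),
    }
    seg_events = GaitEvents(participant_id, bout, true_events + offset_frames, "keypoint", p.fps)
    angle_strides: dict[str, np.ndarray] = {}
    mean_wave: dict[str, np.ndarray] = {}
    cv: dict[str, float] = {}
    rom: dict[str, float] = {}
    for name, sig in angles_true.items():
        ss = segment_strides(sig, seg_events, signal_name=name)
        angle_strides[name] = ss.strides
        mean_wave[name] = ss.mean_waveform()
        cv[name] = coefficient_of_variation(ss) if ss.n_strides >= 2 else float("nan")
        rom[name] = range_of_motion(ss)
    truth = WalkerTruth(
        true_events, p.stride_time, angle_strides, mean_wave, cv, rom
    )

    # ---- GRF: double-bump stance profile per cycle, both belts ----------
    n_grf = int(round(p.duration * p.grf_sample_rate))
    t_grf = np.arange(n_grf) / p.grf_sample_rate
    stance_dur = p.stance_fraction * p.stride_time

    def belt(event_times: np.ndarray) -> np.ndarray:
        force = np.zeros(n_grf)
        for t0 in event_times:
            i0 = max(0, int(np.ceil(t0 * p.grf_sample_rate)))
            i1 = min(n_grf, int(np.floor((t0 + stance_dur) * p.grf_sample_rate)) + 1)
            if i0 >= i1:
                continue
            s = (t_grf[i0:i1] - t0) / stance_dur
            force[i0:i1] += p.body_weight_n * np.maximum(
                1.1 * np.sin(np.pi * s) + 0.3 * np.sin(3.0 * np.pi * s), 0.0
            )
        return force

    left_times = true_events / p.fps
    right_times = left_times + 0.5 * p.stride_time
    grf = GrfSeries(
        participant_id, bout, p.grf_sample_rate, belt(left_times), belt(right_times)
    )

    # ---- assemble keypoints, add bias + noise after truth ---------------
    data = np.ones((n, 17, 3))
    for name, xy in points.items():
        data[:, _KP_INDEX[name], :2] = xy
    for name, (dx, dy) in p.clothing_bias.items():
        data[:, _KP_INDEX[name], 0] += dx
        data[:, _KP_INDEX[name], 1] += dy
    if p.noise_sd > 0:
        data[..., :2] += rng.normal(0.0, p.noise_sd, size=(n, 17, 2))

    series = KeypointSeries(participant_id, bout, p.fps, data)
    return series, grf, truth


# ---------------------------------------------------------------------------
# cortisol


def simulate_cortisol(
    baseline: float,
    amplitude: float,
    onset_min: float,
    sample_times: Sequence[float],
    peak_delay_min: float = 17.5,
    decay_min: float = 10.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    participant_id: str = "sim",
    group: str = "OMC",
) -> tuple[CortisolSeries, dict]:
    """Salivary cortisol at the six protocol sample times (nmol/L).

    The response curve is baseline + amplitude * g(t - onset) with g a
    gamma-shaped pulse of unit peak reaching its maximum ``peak_delay_min``
    minutes after stress onset (physiological delay: 15-20 min) and an
    exponential decay scale of ``decay_min``. Optional multiplicative
    lognormal measurement noise; negative values are clipped at zero.
    Returns the series plus the generating-truth dict.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    times = np.asarray(sample_times, dtype=float)
    if times.shape != (6,):
        raise ValueError("need exactly six sample times S0..S5")
    tau = times - onset_min
    k = peak_delay_min / decay_min
    with np.errstate(invalid="ignore"):
        pulse = np.where(
            tau > 0,
            (tau / peak_delay_min) ** k * np.exp((peak_delay_min - tau) / decay_min),
            0.0,
        )
    conc = baseline + amplitude * pulse
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        conc = conc * np.exp(rng.normal(0.0, noise_sd, size=6))
    conc = np.maximum(conc, 0.0)
    true_max = float((amplitude * pulse[1:]).max())  # over S1..S5
    truth = {
        "baseline": baseline,
        "amplitude": amplitude,
        "onset_min": onset_min,
        "peak_delay_min": peak_delay_min,
        "decay_min": decay_min,
        "true_max_increase": true_max,
        "true_responder": bool(true_max > RESPONDER_THRESHOLD_NMOL_L),
    }
    return (
        CortisolSeries(participant_id, group, times, conc),
        truth,
    )


# ---------------------------------------------------------------------------
# cohort


#: Subscale means used to draw Likert items, per (instrument, subscale).
DEFAULT_SUBSCALE_MEANS = {
    ("PANAS", "positive"): 3.0,
    ("PANAS", "negative"): 1.4,
    ("SSSQ", "distress"): 1.8,
    ("SSSQ", "worry"): 2.0,
    ("SSSQ", "confidence"): 3.5,
    ("SSSQ", "negative_affect"): 1.6,
    ("SSSQ", "motivation"): 3.3,
    ("SSSQ", "self_evaluation"): 3.0,
}


@dataclass
class GroupSpec:
    """Per-group generating conditions."""

    name: str
    n: int = 20
    # gait
    stride_time_slow_mean: float = 1.25  # s, 0.9 m/s bout
    stride_time_fast_mean: float = 1.10  # s, 1.2 m/s bout
    stride_time_sd: float = 0.07
    keypoint_noise_sd: float = 2.0  # px
    clothing_bias: dict[str, tuple[float, float]] = field(default_factory=dict)
    armswing_extra_amp_sd: float = 1.5  # deg, stride-to-stride arm variability
    # between-participant kinematic variability (deg, sd of waveform
    # mean/first-harmonic-amplitude offsets; draws clipped at 2 sd)
    hip_mean_sd: float = 2.0
    hip_amp_sd: float = 1.5
    knee_mean_sd: float = 2.0
    knee_amp_sd: float = 2.5
    elbow_mean_sd: float = 1.5
    # cortisol
    cortisol_baseline_mean: float = 2.4  # nmol/L (lognormal median)
    cortisol_baseline_sigma: float = 0.4
    # pulse amplitude ~ N(mean, sd), signed: negative draws model the
    # afternoon circadian decline below baseline; the sd mirrors the
    # response variability of an everyday-clothing control condition
    cortisol_amplitude_mean: float = 0.3  # nmol/L
    cortisol_amplitude_sd: float = 0.85
    cortisol_onset_min: float = 10.0
    cortisol_onset_jitter_sd: float = 3.0  # min, anticipation varies
    cortisol_peak_delay_range: tuple[float, float] = (15.0, 20.0)  # min
    cortisol_sample_times: tuple[float, ...] = (0.0, 12.0, 19.0, 27.0, 42.0, 52.0)
    cortisol_noise_sd: float = 0.12  # lognormal assay/physiology noise
    # questionnaires
    timepoints: tuple[str, ...] = ("Q-pre", "Q-post")
    subscale_shifts: dict[tuple[str, str, str], float] = field(default_factory=dict)
    # ^ (timepoint, instrument, subscale) -> additive shift of the mean


def default_omc_group(n: int = 20) -> GroupSpec:
    """OMC group: marker clothing bias, stronger cortisol pulse, Q-marker."""
    return GroupSpec(
        name="OMC",
        n=n,
        clothing_bias={"left_knee": (0.0, 8.0)},
        cortisol_amplitude_mean=1.0,
        cortisol_amplitude_sd=2.25,
        cortisol_onset_min=15.0,  # marker application
        cortisol_sample_times=(0.0, 45.0, 52.0, 60.0, 75.0, 85.0),
        timepoints=("Q-pre", "Q-marker", "Q-post"),
        subscale_shifts={
            ("Q-marker", "PANAS", "negative"): 0.7,
            ("Q-marker", "PANAS", "positive"): -0.7,
            ("Q-marker", "SSSQ", "distress"): 0.2,
            ("Q-post", "PANAS", "negative"): -0.15,
            ("Q-post", "SSSQ", "self_evaluation"): -0.25,
            ("Q-post", "SSSQ", "distress"): -0.15,
        },
        armswing_extra_amp_sd=1.2,  # slightly reduced arm variability
    )


def default_control_group(n: int = 20) -> GroupSpec:
    return GroupSpec(
        name="control",
        n=n,
        subscale_shifts={
            ("Q-post", "PANAS", "negative"): -0.15,
            ("Q-post", "SSSQ", "self_evaluation"): -0.25,
            ("Q-post", "SSSQ", "distress"): -0.15,
        },
    )


@dataclass
class CohortSpec:
    """Full synthetic-study configuration."""

    omc: GroupSpec = field(default_factory=default_omc_group)
    control: GroupSpec = field(default_factory=default_control_group)
    duration_s: float = 240.0
    fps: float = 50.0
    item_sd: float = 0.9
    participant_sd: float = 0.3  # random intercept per participant/subscale
    seed: int = 0


@dataclass
class ParticipantData:
    participant_id: str
    group: str
    keypoints: dict[str, KeypointSeries]
    grf: dict[str, GrfSeries]
    cortisol: CortisolSeries
    questionnaires: list[QuestionnaireResponse]
    walker_truth: dict[str, WalkerTruth]
    cortisol_truth: dict
    questionnaire_truth: dict


@dataclass
class CohortData:
    spec: CohortSpec
    participants: list[ParticipantData]

    def by_group(self, group: str) -> list[ParticipantData]:
        return [p for p in self.participants if p.group == group]

    def write(self, out_dir: str | Path) -> None:
        """Write the dataset in the package's documented file formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cort, quest, truth = [], [], {}
        for p in self.participants:
            for bout, kp in p.keypoints.items():
                write_keypoints(kp, out / f"{p.participant_id}_{bout}_keypoints.csv")
                write_grf(p.grf[bout], out / f"{p.participant_id}_{bout}_grf.csv")
            cort.append(p.cortisol)
            quest.extend(p.questionnaires)
            truth[p.participant_id] = {
                "group": p.group,
                "walker": {b: t.to_jsonable() for b, t in p.walker_truth.items()},
                "cortisol": p.cortisol_truth,
                "questionnaire": p.questionnaire_truth,
            }
        write_cortisol(cort, out / "cortisol.csv")
        write_questionnaires(quest, out / "questionnaires.csv")
        (out / "truth.json").write_text(json.dumps(truth))


def _draw_items(
    rng: np.random.Generator,
    instrument: str,
    means: dict[str, float],
    item_sd: float,
) -> np.ndarray:
    key = DEFAULT_PANAS_KEY if instrument == "PANAS" else DEFAULT_SSSQ_KEY
    items = np.empty(key.n_items)
    for sub, idx in key.subscales.items():
        mu = means[sub]
        for i in idx:
            items[i - 1] = np.clip(np.round(rng.normal(mu, item_sd)), 1, 5)
    return items.astype(int)


def simulate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> CohortData:
    """Generate the full two-group study dataset with recorded truth.

    Per participant: two walker trials (slow/fast bouts via stride-time
    scaling) with keypoints and GRF, one cortisol series, and PANAS+SSSQ
    responses at the group's timepoints (the control group lacks Q-marker,
    matching the protocol). Identical seeds give bit-identical datasets.
    """
    if spec is None:
        spec = CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    participants: list[ParticipantData] = []
    counter = 0
    for gspec in (spec.omc, spec.control):
        if gspec.n < 2:
            raise ValueError("need at least 2 participants per group")
        for j in range(gspec.n):
            counter += 1
            pid = f"P{counter:03d}"
            # gait: two bouts with participant-specific stride times
            strides = {
                "slow": float(
                    np.clip(rng.normal(gspec.stride_time_slow_mean, gspec.stride_time_sd), 0.8, 1.9)
                ),
                "fast": float(
                    np.clip(rng.normal(gspec.stride_time_fast_mean, gspec.stride_time_sd), 0.7, 1.6)
                ),
            }
            # per-participant kinematic individuality: offsets to waveform
            # means and first-harmonic amplitudes, shared by both bouts
            def jitter(sd: float) -> float:
                return float(np.clip(rng.normal(0.0, sd), -2.0 * sd, 2.0 * sd))

            hip0, knee0, elb0 = (
                DEFAULT_WAVEFORMS["hip_flexion"],
                DEFAULT_WAVEFORMS["knee_flexion"],
                DEFAULT_WAVEFORMS["elbow_flexion"],
            )
            hip_w = FourierWaveform(
                hip0.mean + jitter(gspec.hip_mean_sd),
                (hip0.amps[0] + jitter(gspec.hip_amp_sd),),
                hip0.phases,
            )
            knee_w = FourierWaveform(
                knee0.mean + jitter(gspec.knee_mean_sd),
                (knee0.amps[0] + jitter(gspec.knee_amp_sd), knee0.amps[1]),
                knee0.phases,
            )
            elbow_w = FourierWaveform(
                elb0.mean + jitter(gspec.elbow_mean_sd), elb0.amps, elb0.phases
            )
            keypoints, grfs, truths = {}, {}, {}
            for bout, st in strides.items():
                waves = dict(DEFAULT_WAVEFORMS)
                waves["hip_flexion"] = hip_w
                waves["knee_flexion"] = knee_w
                waves["elbow_flexion"] = elbow_w
                amp_jitter = abs(rng.normal(0.0, gspec.armswing_extra_amp_sd))
                base = DEFAULT_WAVEFORMS["shoulder_flexion"]
                waves["shoulder_flexion"] = FourierWaveform(
                    base.mean, (base.amps[0] + amp_jitter,), base.phases
                )
                wp = WalkerParams(
                    stride_time=st,
                    fps=spec.fps,
                    duration=spec.duration_s,
                    waveforms=waves,
                    noise_sd=gspec.keypoint_noise_sd,
                    clothing_bias=dict(gspec.clothing_bias),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                kp, grf, truth = simulate_walker(wp, participant_id=pid, bout=bout)
                keypoints[bout], grfs[bout], truths[bout] = kp, grf, truth
            # cortisol
            baseline = float(
                np.exp(rng.normal(np.log(gspec.cortisol_baseline_mean), gspec.cortisol_baseline_sigma))
            )
            amplitude = float(rng.normal(gspec.cortisol_amplitude_mean, gspec.cortisol_amplitude_sd))
            onset = float(
                max(1.0, rng.normal(gspec.cortisol_onset_min, gspec.cortisol_onset_jitter_sd))
            )
            peak_delay = float(rng.uniform(*gspec.cortisol_peak_delay_range))
            cort, cort_truth = simulate_cortisol(
                baseline,
                amplitude,
                onset,
                gspec.cortisol_sample_times,
                peak_delay_min=peak_delay,
                noise_sd=gspec.cortisol_noise_sd,
                rng=rng,
                participant_id=pid,
                group=gspec.name,
            )
            # questionnaires
            q_truth: dict[str, dict[str, float]] = {}
            responses: list[QuestionnaireResponse] = []
            intercepts = {
                (instr, sub): float(rng.normal(0.0, spec.participant_sd))
                for (instr, sub) in DEFAULT_SUBSCALE_MEANS
            }
            for tp in gspec.timepoints:
                for instr, subs in (("PANAS", PANAS_SUBSCALES), ("SSSQ", SSSQ_DIMENSIONS)):
                    means = {}
                    for sub in subs:
                        mu = (
                            DEFAULT_SUBSCALE_MEANS[(instr, sub)]
                            + gspec.subscale_shifts.get((tp, instr, sub), 0.0)
                            + intercepts[(instr, sub)]
                        )
                        means[sub] = float(np.clip(mu, 1.0, 5.0))
                    q_truth[f"{tp}/{instr}"] = means
                    responses.append(
                        QuestionnaireResponse(
                            pid, gspec.name, tp, instr,
                            _draw_items(rng, instr, means, spec.item_sd),
                        )
                    )
            participants.append(
                ParticipantData(
                    pid,
                    gspec.name,
                    keypoints,
                    grfs,
                    cort,
                    responses,
                    truths,
                    cort_truth,
                    q_truth,
                )
            )
    return CohortData(spec, participants)
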