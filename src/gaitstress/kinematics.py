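"""Sagittal joint angles from keypoints and discrete gait features.

All angles are computed in the image plane (y axis pointing *down*, as in
video frames) for the left side. Segment vectors are drawn between
keypoints:

* trunk: hip -> shoulder, thigh: hip -> knee, shank: knee -> ankle,
* upper arm: shoulder -> elbow, forearm: elbow -> wrist,
* whole arm: shoulder -> wrist.

Segment inclinations are measured from the vertical, positive toward the
walking (facing) direction. Conventions (flexion positive, 0 deg at a
straight segment chain):

* ``hip_flexion``    = incl(thigh) - incl(trunk)
* ``knee_flexion``   = incl(thigh) - incl(shank); 0 at a straight leg
* ``shoulder_flexion`` = incl(upper arm) - incl(trunk)
* ``elbow_flexion``  = 180 deg minus the interior elbow angle (0 = fully
  extended, always >= 0)
* ``arm_swing``      = inclination of the whole-arm vector from the
  downward vertical, forward positive

The facing direction (``'+x'`` or ``'-x'``) selects which image direction
counts as forward; it is recorded in the convention metadata so results
under the opposite convention are a sign flip away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import N_NODES, StrideSet
from .keypoints import KeypointSeries

__all__ = [
    "JointAngleSet",
    "ARM_SIGNALS",
    "LEG_SIGNALS",
    "joint_angles",
    "nonfunctional_arm_strides",
    "exclude_nonfunctional_arm_strides",
    "coefficient_of_variation",
    "range_of_motion",
    "build_feature_table",
    "UndefinedCvError",
]

#: Signals affected by the non-functional arm-movement exclusion.
ARM_SIGNALS = ("shoulder_flexion", "elbow_flexion", "arm_swing")
LEG_SIGNALS = ("hip_flexion", "knee_flexion")
ANGLE_SIGNALS = LEG_SIGNALS + ARM_SIGNALS

#: Interior elbow angle below which a stride is treated as non-functional
#: arm movement (scratching the head, fixing hair) and excluded from arm
#: signals. A straight arm has interior angle 180 deg.
DEFAULT_ELBOW_INTERIOR_THRESHOLD_DEG = 80.0


class UndefinedCvError(ZeroDivisionError):
    """Coefficient of variation undefined: mean waveform level is zero."""


@dataclass
class JointAngleSet:
    """Per-frame left-side joint angles in degrees, plus convention flags.

    Frames with degenerate geometry (coincident keypoints) or missing
    keypoints carry NaN and cause the enclosing stride to be dropped
    downstream.
    """

    participant_id: str
    bout: str
    fps: float
    angles: dict[str, np.ndarray]
    convention: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.angles.values()}
        if len(lengths) != 1:
            raise ValueError("all angle channels must have equal length")
        for name in ("knee_flexion", "elbow_flexion"):
            a = self.angles.get(name)
            if a is None:
                continue
            finite = a[np.isfinite(a)]
            if finite.size and (finite.min() < -20.0 or finite.max() > 180.0):
                raise ValueError(
                    f"{name} outside the [-20, 180] deg sanity band "
                    f"(range {finite.min():.1f}..{finite.max():.1f})"
                )

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.angles.values())))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.angles[name]


def _inclination(v: np.ndarray, forward_sign: float, reference: str) -> np.ndarray:
    """Signed inclination (deg) of segment vectors from the vertical.

    ``reference='down'`` measures from the downward image vertical (for
    segments that hang down: thigh, shank, arm), ``'up'`` from the upward
    vertical (trunk). Positive is toward the facing direction. ``v`` is in
    image coordinates (y down), shape (n, 2).
    """
    vy = v[:, 1] if reference == "down" else -v[:, 1]
    return np.degrees(np.arctan2(forward_sign * v[:, 0], vy))


def joint_angles(series: KeypointSeries, forward: str = "+x") -> JointAngleSet:
    """Left-side sagittal joint angles for every frame.

    ``forward`` names the image direction the participant faces ('+x' or
    '-x'); it fixes the sign of all flexion angles. Frames with missing
    (confidence 0) or coincident keypoints yield NaN in every angle that
    depends on them.
    """
    if forward not in ("+x", "-x"):
        raise ValueError("forward must be '+x' or '-x'")
    f = 1.0 if forward == "+x" else -1.0

    pts = {
        name: series.xy(f"left_{name}")
        for name in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle")
    }
    missing = {
        name: series.missing_mask(f"left_{name}")
        for name in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle")
    }

    def seg(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        v = pts[b] - pts[a]
        bad = missing[a] | missing[b] | (np.linalg.norm(v, axis=1) < 1e-9)
        return v, bad

    trunk, bad_trunk = seg("hip", "shoulder")
    thigh, bad_thigh = seg("hip", "knee")
    shank, bad_shank = seg("knee", "ankle")
    upper_arm, bad_ua = seg("shoulder", "elbow")
    forearm, bad_fa = seg("elbow", "wrist")
    whole_arm, bad_wa = seg("shoulder", "wrist")

    incl_trunk = _inclination(trunk, f, "up")
    incl_thigh = _inclination(thigh, f, "down")
    incl_shank = _inclination(shank, f, "down")
    incl_ua = _inclination(upper_arm, f, "down")

    hip_flexion = incl_thigh - incl_trunk
    knee_flexion = incl_thigh - incl_shank
    shoulder_flexion = incl_ua - incl_trunk
    arm_swing = _inclination(whole_arm, f, "down")

    # interior elbow angle between elbow->shoulder and elbow->wrist
    u, w = -upper_arm, forearm
    cosang = np.einsum("ij,ij->i", u, w) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1) + 1e-300
    )
    interior = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    elbow_flexion = 180.0 - interior

    for arr, bad in (
        (hip_flexion, bad_thigh | bad_trunk),
        (knee_flexion, bad_thigh | bad_shank),
        (shoulder_flexion, bad_ua | bad_trunk),
        (elbow_flexion, bad_ua | bad_fa),
        (arm_swing, bad_wa),
    ):
        arr[bad] = np.nan

    return JointAngleSet(
        series.participant_id,
        series.bout,
        series.fps,
        {
            "hip_flexion": hip_flexion,
            "knee_flexion": knee_flexion,
            "shoulder_flexion": shoulder_flexion,
            "elbow_flexion": elbow_flexion,
            "arm_swing": arm_swing,
        },
        convention={
            "zero_reference": "straight segment alignment (0 deg)",
            "sign": "flexion/forward positive",
            "forward": forward,
            "elbow": "flexion = 180 deg - interior angle",
            "arm_swing": "whole-arm vector vs. downward vertical",
            "image_y": "down",
        },
    )


def nonfunctional_arm_strides(
    elbow: StrideSet,
    interior_threshold_deg: float = DEFAULT_ELBOW_INTERIOR_THRESHOLD_DEG,
) -> np.ndarray:
    """Boolean mask of strides with non-functional arm movement.

    A stride counts as non-functional when its minimal interior elbow
    angle drops below the threshold (default 80 deg), i.e. the arm is bent
    far beyond normal arm swing. ``elbow`` must hold elbow *flexion*
    strides (internal convention: flexion = 180 - interior), so the
    criterion is ``max flexion > 180 - threshold``. A threshold of 0
    disables the exclusion.
    """
    interior_min = 180.0 - elbow.strides.max(axis=1)
    return interior_min < interior_threshold_deg


def exclude_nonfunctional_arm_strides(
    stride_sets: dict[str, StrideSet],
    interior_threshold_deg: float = DEFAULT_ELBOW_INTERIOR_THRESHOLD_DEG,
    elbow_key: str = "elbow_flexion",
) -> tuple[dict[str, StrideSet], np.ndarray]:
    """Drop non-functional arm strides from every arm signal.

    The exclusion mask is derived from the elbow stride set and applied to
    all arm signals at the same stride indices; leg signals pass through
    untouched. Returns the updated mapping and the mask. If every stride
    is excluded the arm entries are removed (features become missing).
    """
    if elbow_key not in stride_sets:
        raise KeyError(f"stride sets carry no {elbow_key!r} signal")
    mask = nonfunctional_arm_strides(stride_sets[elbow_key], interior_threshold_deg)
    out: dict[str, StrideSet] = {}
    for name, ss in stride_sets.items():
        if name in ARM_SIGNALS:
            if mask.all():
                continue  # empty-feature case: arm features become missing
            if ss.n_strides != mask.size:
                raise ValueError(
                    f"{name}: {ss.n_strides} strides but elbow mask has {mask.size}"
                )
            out[name] = ss.select(~mask)
        else:
            out[name] = ss
    return out, mask


def coefficient_of_variation(strides: StrideSet) -> float:
    """Waveform variability index across strides.

    With ``sigma_i`` the across-stride sample standard deviation (ddof=1)
    and ``X_i`` the across-stride mean at node i of the 101-node cycle::

        cv = sqrt(mean_i sigma_i^2) / mean_i |X_i|

    The index is unitless, invariant to positive rescaling and sensitive
    to additive offsets (which change the denominator).
    """
    if strides.n_strides < 2:
        raise ValueError("coefficient of variation needs at least two strides")
    sigma = strides.strides.std(axis=0, ddof=1)
    # nodes where all strides coincide have exactly zero spread
    sigma[np.ptp(strides.strides, axis=0) == 0] = 0.0
    mean_abs = np.abs(strides.strides.mean(axis=0)).mean()
    if mean_abs == 0:
        raise UndefinedCvError(f"{strides.signal_name}: mean waveform level is zero")
    return float(np.sqrt(np.mean(sigma**2)) / mean_abs)


def range_of_motion(strides: StrideSet) -> float:
    """Mean over strides of the per-stride max - min, in signal units."""
    return float((strides.strides.max(axis=1) - strides.strides.min(axis=1)).mean())


#: Feature columns of the per-participant gait table.
FEATURE_COLUMNS = (
    "stride_time_s",
    "cv_hip",
    "cv_knee",
    "cv_elbow",
    "cv_shoulder",
    "cv_armswing",
    "rom_shoulder_deg",
    "rom_elbow_deg",
    "rom_armswing_deg",
)

_CV_KEYS = {
    "cv_hip": "hip_flexion",
    "cv_knee": "knee_flexion",
    "cv_elbow": "elbow_flexion",
    "cv_shoulder": "shoulder_flexion",
    "cv_armswing": "arm_swing",
}
_ROM_KEYS = {
    "rom_shoulder_deg": "shoulder_flexion",
    "rom_elbow_deg": "elbow_flexion",
    "rom_armswing_deg": "arm_swing",
}


def bout_features(stride_sets: dict[str, StrideSet]) -> dict[str, float]:
    """Discrete features for one walking bout from its stride sets.

    Arm-signal stride sets should already have non-functional strides
    excluded. Missing signals yield NaN features.
    """
    feats: dict[str, float] = {}
    any_ss = next(iter(stride_sets.values()))
    feats["stride_time_s"] = float(any_ss.stride_times.mean())
    for col, key in _CV_KEYS.items():
        feats[col] = (
            coefficient_of_variation(stride_sets[key]) if key in stride_sets else np.nan
        )
    for col, key in _ROM_KEYS.items():
        feats[col] = range_of_motion(stride_sets[key]) if key in stride_sets else np.nan
    return feats


def build_feature_table(
    per_bout: dict[str, dict[str, dict[str, float]]],
    groups: dict[str, str] | None = None,
    *,
    allow_single_bout: bool = False,
) -> pd.DataFrame:
    """Average per-bout features over both walking bouts per participant.

    ``per_bout`` maps participant -> bout ('slow'/'fast') -> feature dict,
    as produced by :func:`bout_features`. Each participant must have both
    bouts unless ``allow_single_bout`` is set. Returns one row per
    participant with the study's discrete gait features.
    """
    rows = []
    for pid, bouts in per_bout.items():
        if not allow_single_bout and set(bouts) != {"slow", "fast"}:
            raise ValueError(
                f"participant {pid} has bouts {sorted(bouts)}; expected both "
                "'slow' and 'fast' (pass allow_single_bout=True to override)"
            )
        frames = pd.DataFrame(list(bouts.values()))
        row: dict[str, object] = {"participant": pid}
        if groups is not None:
            row["group"] = groups.get(pid, "")
        row.update(frames.mean().to_dict())
        rows.append(row)
    cols = ["participant"] + (["group"] if groups is not None else []) + list(FEATURE_COLUMNS)
    return pd.DataFrame(rows).reindex(columns=cols)
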