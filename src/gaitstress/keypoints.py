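"""Keypoint, force, cortisol and questionnaire containers plus file I/O.

The raw gait signal is a sagittal-plane keypoint trajectory: 17 anatomical
keypoints per video frame (COCO layout, as emitted by 2D pose estimators),
each with pixel coordinates and a confidence value. Image coordinates follow
the computer-vision convention: x grows rightward, y grows *downward*.

Two file dialects are supported for keypoints:

* long-format CSV with columns ``frame,keypoint,x,y,confidence``;
* JSON: a list of frames, each a ``{name: [x, y, conf]}`` map.

Companion tables (vertical ground-reaction force, salivary cortisol samples,
questionnaire items) are plain CSV; see the ``read_*`` functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "KEYPOINT_NAMES",
    "KeypointSeries",
    "GrfSeries",
    "CortisolSeries",
    "QuestionnaireResponse",
    "SchemaError",
    "EmptyTrialError",
    "read_keypoints",
    "write_keypoints",
    "read_grf",
    "write_grf",
    "read_cortisol",
    "write_cortisol",
    "read_questionnaires",
    "write_questionnaires",
    "trim_familiarization",
    "filter_trajectories",
]

#: The 17-name controlled vocabulary (COCO order).
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

_KP_INDEX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

BOUTS = ("slow", "fast")


class SchemaError(ValueError):
    """A file does not match the documented column/keypoint schema."""


class EmptyTrialError(ValueError):
    """A trimming or segmentation step left no usable frames."""


@dataclass
class KeypointSeries:
    """Frames x 17 keypoints x (x, y, confidence) at a fixed frame rate.

    ``data`` has shape ``(n_frames, 17, 3)``; the last axis is
    ``(x_px, y_px, confidence)``. Keypoints with confidence 0 are treated
    as missing by downstream stages (the frames are retained; strides that
    depend on them are dropped rather than gap-filled).
    """

    participant_id: str
    bout: str
    fps: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.bout not in BOUTS:
            raise ValueError(f"bout must be one of {BOUTS}, got {self.bout!r}")
        if self.data.ndim != 3 or self.data.shape[1:] != (17, 3):
            raise SchemaError(
                f"keypoint data must have shape (frames, 17, 3), got {self.data.shape}"
            )
        if self.data.shape[0] == 0:
            raise EmptyTrialError("keypoint series contains no frames")
        if not np.isfinite(self.data[..., :2]).all():
            raise ValueError("keypoint coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def xy(self, name: str) -> np.ndarray:
        """(n_frames, 2) pixel trajectory of one named keypoint."""
        return self.data[:, _KP_INDEX[name], :2]

    def confidence(self, name: str) -> np.ndarray:
        return self.data[:, _KP_INDEX[name], 2]

    def missing_mask(self, name: str) -> np.ndarray:
        """Frames on which a keypoint is flagged missing (confidence == 0)."""
        return self.confidence(name) == 0.0


@dataclass
class GrfSeries:
    """Vertical ground-reaction force per treadmill belt, in newtons."""

    participant_id: str
    bout: str
    sample_rate: float
    force_left: np.ndarray
    force_right: np.ndarray

    def __post_init__(self) -> None:
        self.force_left = np.asarray(self.force_left, dtype=float)
        self.force_right = np.asarray(self.force_right, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.force_left.shape != self.force_right.shape:
            raise ValueError("belt force traces must have equal length")
        if not (np.isfinite(self.force_left).all() and np.isfinite(self.force_right).all()):
            raise ValueError("forces must be finite")

    @property
    def n_samples(self) -> int:
        return self.force_left.shape[0]


CORTISOL_SAMPLE_IDS = ("S0", "S1", "S2", "S3", "S4", "S5")


@dataclass
class CortisolSeries:
    """Six timed salivary cortisol samples (S0..S5) for one participant.

    ``clock_min`` are minutes since arrival and must be strictly increasing;
    concentrations are in nmol/L.
    """

    participant_id: str
    group: str
    clock_min: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.clock_min = np.asarray(self.clock_min, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.clock_min.shape != (6,) or self.concentration.shape != (6,):
            raise ValueError("cortisol series needs exactly six samples S0..S5")
        if not np.all(np.diff(self.clock_min) > 0):
            raise ValueError("sample clock times must be strictly increasing")
        if np.any(self.concentration < 0) or not np.isfinite(self.concentration).all():
            raise ValueError("concentrations must be finite and non-negative")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return CORTISOL_SAMPLE_IDS


TIMEPOINTS = ("Q-pre", "Q-marker", "Q-post")
INSTRUMENT_SIZES = {"PANAS": 20, "SSSQ": 24}


@dataclass
class QuestionnaireResponse:
    """One questionnaire filled at one timepoint: ordered Likert items (1-5)."""

    participant_id: str
    group: str
    timepoint: str
    instrument: str
    items: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=int)
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.instrument not in INSTRUMENT_SIZES:
            raise ValueError(f"instrument must be one of {tuple(INSTRUMENT_SIZES)}")
        expected = INSTRUMENT_SIZES[self.instrument]
        if self.items.shape != (expected,):
            raise ValueError(
                f"{self.instrument} requires {expected} items, got {self.items.shape}"
            )
        if self.items.min() < 1 or self.items.max() > 5:
            raise ValueError("item responses must lie in [1, 5]")


# ---------------------------------------------------------------------------
# keypoint I/O


def read_keypoints(
    path: str | Path,
    format: str | None = None,
    *,
    participant_id: str = "",
    bout: str = "slow",
    fps: float = 50.0,
) -> KeypointSeries:
    """Read a keypoint trajectory file (long CSV or per-frame JSON).

    Missing keypoints must be encoded with confidence 0 (coordinates may be
    repeated or arbitrary finite values); they are flagged, never
    interpolated.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return _read_keypoints_csv(path, participant_id, bout, fps)
    if format == "json":
        return _read_keypoints_json(path, participant_id, bout, fps)
    raise ValueError(f"unknown keypoint format {format!r}")


def _read_keypoints_csv(path: Path, participant_id: str, bout: str, fps: float) -> KeypointSeries:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise SchemaError(f"cannot parse keypoint CSV {path}: {exc}") from exc
    required = {"frame", "keypoint", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: keypoint CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    names = set(df["keypoint"].unique())
    if names != set(KEYPOINT_NAMES):
        missing = set(KEYPOINT_NAMES) - names
        extra = names - set(KEYPOINT_NAMES)
        raise SchemaError(
            f"{path}: keypoint set mismatch (missing={sorted(missing)}, extra={sorted(extra)})"
        )
    frames = np.sort(df["frame"].unique())
    n = len(frames)
    if not np.array_equal(frames, np.arange(n)):
        raise SchemaError(f"{path}: frame indices must be contiguous from 0")
    data = np.full((n, 17, 3), np.nan)
    rows = df["frame"].to_numpy()
    cols = df["keypoint"].map(_KP_INDEX).to_numpy()
    data[rows, cols, 0] = df["x"].to_numpy()
    data[rows, cols, 1] = df["y"].to_numpy()
    data[rows, cols, 2] = df["confidence"].to_numpy()
    if np.isnan(data).any():
        bad = int(np.argwhere(np.isnan(data[..., 0]))[0, 0])
        raise SchemaError(f"{path}: frame {bad} is missing keypoint records")
    return KeypointSeries(participant_id, bout, fps, data)


def _read_keypoints_json(path: Path, participant_id: str, bout: str, fps: float) -> KeypointSeries:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"cannot parse keypoint JSON {path}: line {exc.lineno}") from exc
    meta = {}
    if isinstance(payload, dict):  # optional wrapper with metadata
        meta = {k: payload[k] for k in ("participant_id", "bout", "fps") if k in payload}
        payload = payload.get("frames", [])
    data = np.empty((len(payload), 17, 3))
    for t, frame in enumerate(payload):
        if set(frame) != set(KEYPOINT_NAMES):
            raise SchemaError(f"{path}: frame {t} keypoint set mismatch")
        for name, triple in frame.items():
            data[t, _KP_INDEX[name]] = triple
    return KeypointSeries(
        str(meta.get("participant_id", participant_id)),
        str(meta.get("bout", bout)),
        float(meta.get("fps", fps)),
        data,
    )


def write_keypoints(series: KeypointSeries, path: str | Path, format: str | None = None) -> None:
    """Write a keypoint trajectory in either supported dialect."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        n = series.n_frames
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n), 17),
                "keypoint": np.tile(np.array(KEYPOINT_NAMES), n),
                "x": series.data[..., 0].ravel(),
                "y": series.data[..., 1].ravel(),
                "confidence": series.data[..., 2].ravel(),
            }
        )
        df.to_csv(path, index=False)
    elif format == "json":
        frames = [
            {name: [float(v) for v in series.data[t, i]] for i, name in enumerate(KEYPOINT_NAMES)}
            for t in range(series.n_frames)
        ]
        payload = {
            "participant_id": series.participant_id,
            "bout": series.bout,
            "fps": series.fps,
            "frames": frames,
        }
        Path(path).write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown keypoint format {format!r}")


# ---------------------------------------------------------------------------
# companion-table I/O


def read_grf(
    path: str | Path, *, participant_id: str = "", bout: str = "slow"
) -> GrfSeries:
    """Read a GRF CSV with columns ``time_s,f_left_n,f_right_n``."""
    df = pd.read_csv(path)
    required = {"time_s", "f_left_n", "f_right_n"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: GRF CSV needs columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: GRF trace too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise SchemaError(f"{path}: GRF samples must be uniformly spaced")
    return GrfSeries(
        participant_id,
        bout,
        1.0 / dt[0],
        df["f_left_n"].to_numpy(dtype=float),
        df["f_right_n"].to_numpy(dtype=float),
    )


def write_grf(grf: GrfSeries, path: str | Path) -> None:
    t = np.arange(grf.n_samples) / grf.sample_rate
    pd.DataFrame(
        {"time_s": t, "f_left_n": grf.force_left, "f_right_n": grf.force_right}
    ).to_csv(path, index=False)


def read_cortisol(path: str | Path) -> list[CortisolSeries]:
    """Read a cortisol CSV (``participant,group,sample_id,clock_min,nmol_per_l``)."""
    df = pd.read_csv(path)
    required = {"participant", "group", "sample_id", "clock_min", "nmol_per_l"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: cortisol CSV needs columns {sorted(required)}")
    out = []
    for (pid, group), sub in df.groupby(["participant", "group"], sort=True):
        sub = sub.set_index("sample_id").loc[list(CORTISOL_SAMPLE_IDS)]
        out.append(
            CortisolSeries(
                str(pid),
                str(group),
                sub["clock_min"].to_numpy(),
                sub["nmol_per_l"].to_numpy(),
            )
        )
    return out


def write_cortisol(series: Sequence[CortisolSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for sid, t, c in zip(CORTISOL_SAMPLE_IDS, s.clock_min, s.concentration):
            rows.append((s.participant_id, s.group, sid, t, c))
    pd.DataFrame(
        rows, columns=["participant", "group", "sample_id", "clock_min", "nmol_per_l"]
    ).to_csv(path, index=False)


def read_questionnaires(path: str | Path) -> list[QuestionnaireResponse]:
    """Read a questionnaire CSV (one row per item, ``item_index`` 1-based)."""
    df = pd.read_csv(path)
    required = {"participant", "group", "timepoint", "instrument", "item_index", "response"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: questionnaire CSV needs columns {sorted(required)}")
    out = []
    keys = ["participant", "group", "timepoint", "instrument"]
    for (pid, group, tp, instr), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("item_index")
        expected = INSTRUMENT_SIZES.get(str(instr), -1)
        if not np.array_equal(sub["item_index"].to_numpy(), np.arange(1, expected + 1)):
            raise SchemaError(
                f"{path}: {pid}/{tp}/{instr} must carry item_index 1..{expected}"
            )
        out.append(
            QuestionnaireResponse(str(pid), str(group), str(tp), str(instr), sub["response"].to_numpy())
        )
    return out


def write_questionnaires(responses: Sequence[QuestionnaireResponse], path: str | Path) -> None:
    rows = []
    for r in responses:
        for i, v in enumerate(r.items, start=1):
            rows.append((r.participant_id, r.group, r.timepoint, r.instrument, i, int(v)))
    pd.DataFrame(
        rows,
        columns=["participant", "group", "timepoint", "instrument", "item_index", "response"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def trim_familiarization(series: KeypointSeries, trim_seconds: float = 30.0) -> KeypointSeries:
    """Drop the initial treadmill-familiarization window.

    Removes the first ``round(trim_seconds * fps)`` frames (default 30 s).
    """
    if trim_seconds < 0:
        raise ValueError("trim_seconds must be non-negative")
    n_drop = int(round(trim_seconds * series.fps))
    if n_drop >= series.n_frames:
        raise EmptyTrialError(
            f"trial of {series.duration_s:.1f} s shorter than trim window {trim_seconds} s"
        )
    return replace(series, data=series.data[n_drop:].copy())


def filter_trajectories(
    series: KeypointSeries, cutoff_hz: float = 10.0, order: int = 2
) -> KeypointSeries:
    """Low-pass the x/y channels with a zero-phase Butterworth filter.

    The filter is designed at the given order (default 2) and cutoff
    (default 10 Hz) and applied forward-backward (:func:`scipy.signal.filtfilt`),
    so the effective magnitude response is squared (effective order doubled)
    and the phase is zero — gait-event timing is not lagged. The confidence
    channel is left untouched.
    """
    nyq = series.fps / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff_hz}")
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=series.fps, output="sos")
    data = series.data.copy()
    flat = data[..., :2].reshape(series.n_frames, -1)
    data[..., :2] = _sig.sosfiltfilt(sos, flat, axis=0).reshape(series.n_frames, 17, 2)
    return replace(series, data=data)
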