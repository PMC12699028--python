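"""Heel-strike detection, stride segmentation and time-normalization.

Left heel strikes are detected from keypoint geometry: the per-frame
Euclidean distance between the left ankle and left hip peaks at terminal
swing, and initial contact is taken as the frame *after* each peak
(a one-frame offset, 0.02 s at 50 Hz). Vertical ground-reaction force,
when available, provides an independent event oracle via threshold
crossings. Strides (consecutive heel-strike pairs) are resampled to 101
nodes, i.e. 0-100% of the gait cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .keypoints import GrfSeries, KeypointSeries

__all__ = [
    "GaitEvents",
    "StrideSet",
    "InsufficientStridesError",
    "DataQualityError",
    "ankle_hip_distance",
    "detect_heel_strikes",
    "detect_heel_strikes_grf",
    "segment_strides",
    "N_NODES",
]

log = logging.getLogger(__name__)

#: Nodes per time-normalized stride (0..100% of the gait cycle).
N_NODES = 101

#: Physiologically plausible stride-duration window in seconds; strides
#: outside it are treated as detection glitches and dropped.
DEFAULT_STRIDE_TIME_BOUNDS = (0.4, 2.5)


class InsufficientStridesError(ValueError):
    """Fewer than the minimum number of gait events/strides were found."""


class DataQualityError(ValueError):
    """Too many frames with missing keypoints for a reliable signal."""


@dataclass
class GaitEvents:
    """Strictly increasing heel-strike frame indices for one trial."""

    participant_id: str
    bout: str
    heel_strike_frames: np.ndarray
    source: str  # "keypoint" or "grf"
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.heel_strike_frames = np.asarray(self.heel_strike_frames, dtype=int)
        if self.heel_strike_frames.size and not np.all(np.diff(self.heel_strike_frames) > 0):
            raise ValueError("heel-strike frames must be strictly increasing")
        if self.source not in ("keypoint", "grf"):
            raise ValueError("source must be 'keypoint' or 'grf'")

    @property
    def n_events(self) -> int:
        return int(self.heel_strike_frames.size)

    @property
    def stride_times_s(self) -> np.ndarray:
        return np.diff(self.heel_strike_frames) / self.fps


@dataclass
class StrideSet:
    """M strides of one signal, each time-normalized to 101 nodes.

    ``strides`` is an (M, 101) matrix; row k covers stride k from 0% to
    100% of the gait cycle. ``stride_times`` holds the raw durations in
    seconds. All waveform statistics (coefficient of variation, range of
    motion, SPM) operate on this container.
    """

    participant_id: str
    bout: str
    signal_name: str
    strides: np.ndarray
    stride_times: np.ndarray
    node_count: int = N_NODES
    dropped: int = 0  # strides discarded (implausible duration / missing data)

    def __post_init__(self) -> None:
        self.strides = np.atleast_2d(np.asarray(self.strides, dtype=float))
        self.stride_times = np.asarray(self.stride_times, dtype=float)
        if self.strides.shape[1] != self.node_count:
            raise ValueError(
                f"strides must have {self.node_count} nodes, got {self.strides.shape[1]}"
            )
        if self.strides.shape[0] < 1:
            raise InsufficientStridesError("stride set is empty")
        if self.stride_times.shape[0] != self.strides.shape[0]:
            raise ValueError("stride_times length must match stride count")
        if np.any(self.stride_times <= 0):
            raise ValueError("stride times must be positive")
        if not np.isfinite(self.strides).all():
            raise ValueError("stride rows must be finite")

    @property
    def n_strides(self) -> int:
        return self.strides.shape[0]

    def mean_waveform(self) -> np.ndarray:
        return self.strides.mean(axis=0)

    def select(self, mask: np.ndarray) -> "StrideSet":
        """Return a copy keeping only strides where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return StrideSet(
            self.participant_id,
            self.bout,
            self.signal_name,
            self.strides[mask],
            self.stride_times[mask],
            self.node_count,
            self.dropped + int((~mask).sum()),
        )


def ankle_hip_distance(series: KeypointSeries, side: str = "left") -> np.ndarray:
    """Per-frame Euclidean image-plane distance between ankle and hip.

    Frames on which either keypoint is flagged missing yield NaN. If more
    than half the frames are missing the signal is unusable and a
    :class:`DataQualityError` is raised.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    ankle = series.xy(f"{side}_ankle")
    hip = series.xy(f"{side}_hip")
    d = np.linalg.norm(ankle - hip, axis=1)
    missing = series.missing_mask(f"{side}_ankle") | series.missing_mask(f"{side}_hip")
    if missing.mean() > 0.5:
        raise DataQualityError(
            f"{side} ankle/hip missing on {missing.mean():.0%} of frames"
        )
    d = d.astype(float)
    d[missing] = np.nan
    return d


def _dominant_period_frames(x: np.ndarray, fps: float) -> float:
    """Period (frames) of the dominant non-DC frequency, via periodogram."""
    x = np.asarray(x, dtype=float)
    x = np.where(np.isfinite(x), x, np.nanmean(x))
    f, p = _sig.periodogram(x - x.mean(), fs=fps)
    if len(f) < 2 or not np.any(p[1:] > 0):
        raise InsufficientStridesError("signal has no dominant periodicity")
    f_dom = f[1:][np.argmax(p[1:])]
    if f_dom <= 0:
        raise InsufficientStridesError("signal has no dominant periodicity")
    return fps / f_dom


def detect_heel_strikes(
    distance: np.ndarray,
    fps: float,
    min_period_s: float | None = None,
    offset_frames: int = 1,
    *,
    min_prominence_frac: float = 0.25,
    participant_id: str = "",
    bout: str = "slow",
) -> GaitEvents:
    """Heel strikes = local maxima of the ankle-hip distance, plus an offset.

    Each detected peak is shifted by ``offset_frames`` (default +1 frame,
    0.02 s at 50 Hz) because initial contact follows the peak ankle-hip
    distance by about one frame. Peaks closer than ``min_period_s`` are
    suppressed; when not given, the separation defaults to half the
    dominant period of the distance signal. Peaks must additionally rise
    by ``min_prominence_frac`` of the signal's peak-to-peak range, which
    rejects noise ripples near the mid-swing distance minimum. Plateau
    maxima resolve to the first frame of the plateau. Events shifted
    beyond the trial end are discarded.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.size
    if min_period_s is None:
        min_period_s = 0.5 * _dominant_period_frames(distance, fps) / fps
    if n <= 2 * min_period_s * fps:
        raise InsufficientStridesError(
            f"series of {n} frames too short for min period {min_period_s:.2f} s"
        )
    filled = np.where(np.isfinite(distance), distance, np.nanmin(distance))
    min_dist = max(1, int(round(min_period_s * fps)))
    ptp = float(np.ptp(filled))
    prominence = min_prominence_frac * ptp if ptp > 0 else None
    peaks, props = _sig.find_peaks(
        filled, distance=min_dist, plateau_size=(1, None), prominence=prominence
    )
    # deterministic tie-break: first frame of a flat maximum
    peaks = props["left_edges"]
    events = peaks + offset_frames
    events = events[(events >= 0) & (events < n)]
    if events.size < 2:
        raise InsufficientStridesError(f"found {events.size} heel strikes, need >= 2")
    return GaitEvents(participant_id, bout, events, "keypoint", fps)


def detect_heel_strikes_grf(
    grf: GrfSeries,
    threshold_n: float = 20.0,
    min_period_s: float = 0.5,
    belt: str = "left",
    keypoint_fps: float = 50.0,
) -> GaitEvents:
    """Heel strikes from vertical GRF: rising-edge threshold crossings.

    Crossings of ``threshold_n`` (default 20 N) on the chosen belt are
    debounced so that two events are at least ``min_period_s`` apart, then
    converted from force samples to keypoint frame indices. Belt-crossover
    artifacts (simultaneous force on both belts from one leg) are not
    corrected here.
    """
    force = grf.force_left if belt == "left" else grf.force_right
    above = force >= threshold_n
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if rising.size:
        keep = [rising[0]]
        min_gap = min_period_s * grf.sample_rate
        for idx in rising[1:]:
            if idx - keep[-1] >= min_gap:
                keep.append(idx)
        rising = np.asarray(keep)
    if rising.size < 2:
        raise InsufficientStridesError(
            f"found {rising.size} GRF contacts above {threshold_n} N, need >= 2"
        )
    frames = np.round(rising / grf.sample_rate * keypoint_fps).astype(int)
    frames = np.unique(frames)
    return GaitEvents(grf.participant_id, grf.bout, frames, "grf", keypoint_fps)


def segment_strides(
    signal: np.ndarray,
    events: GaitEvents,
    *,
    signal_name: str = "",
    stride_time_bounds: tuple[float, float] = DEFAULT_STRIDE_TIME_BOUNDS,
) -> StrideSet:
    """Cut a per-frame signal into strides and resample each to 101 nodes.

    Stride k spans ``[e_k, e_{k+1}]`` (frames); its duration is
    ``(e_{k+1} - e_k)/fps``. Each stride is linearly interpolated onto 101
    equally spaced points of normalized time. Strides with implausible
    durations (outside ``stride_time_bounds``) or non-finite samples
    (missing keypoints) are dropped and logged, never gap-filled.
    """
    signal = np.asarray(signal, dtype=float)
    if events.n_events < 2:
        raise InsufficientStridesError("need at least two events to form a stride")
    ev = events.heel_strike_frames
    if ev[0] < 0 or ev[-1] >= signal.size:
        raise ValueError("events lie outside the signal")
    lo, hi = stride_time_bounds
    rows, times, dropped = [], [], 0
    nodes = np.linspace(0.0, 1.0, N_NODES)
    for e0, e1 in zip(ev[:-1], ev[1:]):
        stride_time = (e1 - e0) / events.fps
        if not lo <= stride_time <= hi:
            dropped += 1
            log.info(
                "dropping stride %d-%d (%.2f s outside [%.2f, %.2f] s)",
                e0, e1, stride_time, lo, hi,
            )
            continue
        frames = e0 + nodes * (e1 - e0)
        row = np.interp(frames, np.arange(signal.size), signal)
        if not np.isfinite(row).all():
            dropped += 1
            log.info("dropping stride %d-%d (missing keypoint data)", e0, e1)
            continue
        rows.append(row)
        times.append(stride_time)
    if not rows:
        raise InsufficientStridesError("all strides dropped during segmentation")
    return StrideSet(
        events.participant_id,
        events.bout,
        signal_name,
        np.asarray(rows),
        np.asarray(times),
        dropped=dropped,
    )
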