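"""Speed series, freezing detection, speed-class ethogram, day/night sessions.

Swimming activity is scaled into four classes on speed: large (> 15 cm/s),
moderate (1-15 cm/s), small (0-1 cm/s) and freezing. The printed class
intervals overlap at their endpoints; here the boundary at exactly 1 cm/s
belongs to "moderate" and 15 cm/s to "moderate" (large is strictly > 15).
Freezing is operationalized as sub-threshold speed sustained for a minimum
duration (defaults 0.5 cm/s, 1.0 s) and takes precedence over "small".

Whole sessions are additionally pooled into 1-minute time bins, and paired
morning (M) vs night (N) sessions of the same fish are compared to detect
day-night activity reversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "SPEED_CLASSES",
    "FREEZE_SPEED_MAX",
    "FREEZE_MIN_DURATION",
    "SpeedSeries",
    "EthogramSummary",
    "SessionComparison",
    "compute_speed",
    "classify_speed",
    "detect_freezing",
    "summarize_ethogram",
    "compare_sessions",
]

SPEED_CLASSES = ("freezing", "small", "moderate", "large")

#: Default freezing criterion: speed below this for at least the minimum duration.
FREEZE_SPEED_MAX = 0.5  # cm/s
FREEZE_MIN_DURATION = 1.0  # s

BIN_SECONDS = 60.0


@dataclass(frozen=True)
class SpeedSeries:
    """Per-frame instantaneous speeds (cm/s) over a trajectory.

    ``speeds[i]`` covers the interval between retained samples ``i`` and
    ``i + window``; with the default 1-frame window the series has length
    n - 1. ``t0`` and ``dt`` give each interval's start time and duration.
    """

    speeds: np.ndarray
    t0: np.ndarray
    dt: np.ndarray
    window: int
    fps: float

    def __post_init__(self) -> None:
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be >= 0")


def compute_speed(traj: Trajectory, smoothing_window: int = 1) -> SpeedSeries:
    """Instantaneous speed: Euclidean displacement over ``window`` frames / elapsed time."""
    w = int(smoothing_window)
    if w < 1:
        raise ValueError("smoothing_window must be >= 1 frame")
    if traj.n <= w:
        raise ValueError("trajectory too short for the requested window")
    disp = np.linalg.norm(traj.xy[w:] - traj.xy[:-w], axis=1)
    t = traj.t
    dt = t[w:] - t[:-w]
    return SpeedSeries(speeds=disp / dt, t0=t[:-w], dt=dt, window=w, fps=traj.fps)


def classify_speed(v: float) -> str:
    """Movement class of a single speed: small [0, 1), moderate [1, 15], large (15, inf).

    "freezing" is never returned here; it is assigned by
    :func:`detect_freezing`, which requires a sustained sub-threshold run
    and overrides "small" frames.
    """
    if v < 0:
        raise ValueError("speed must be >= 0")
    if v < 1.0:
        return "small"
    if v <= 15.0:
        return "moderate"
    return "large"


def classify_speeds(v: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_speed`."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be >= 0")
    out = np.where(v < 1.0, "small", np.where(v <= 15.0, "moderate", "large"))
    return out.astype(object)


def detect_freezing(
    speeds: SpeedSeries,
    freeze_speed_max: float = FREEZE_SPEED_MAX,
    min_duration: float = FREEZE_MIN_DURATION,
) -> tuple[list[tuple[float, float]], float]:
    """Freezing bouts: maximal runs of sub-threshold speed lasting >= ``min_duration``.

    Returns ``(intervals, total_time)`` where each interval is a
    ``(t_start, t_end)`` pair in seconds and ``total_time`` is the summed
    bout duration.
    """
    if min_duration < 1.0 / speeds.fps:
        raise ValueError("min_duration must be at least one frame")
    below = speeds.speeds < freeze_speed_max
    intervals: list[tuple[float, float]] = []
    total = 0.0
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            t_start = float(speeds.t0[i])
            t_end = float(speeds.t0[j - 1] + speeds.dt[j - 1])
            if t_end - t_start >= min_duration:
                intervals.append((t_start, t_end))
                total += t_end - t_start
            i = j
        else:
            i += 1
    return intervals, total


def frame_labels(
    speeds: SpeedSeries,
    freeze_speed_max: float = FREEZE_SPEED_MAX,
    min_duration: float = FREEZE_MIN_DURATION,
) -> np.ndarray:
    """Per-interval movement class with freezing overriding 'small'."""
    labels = classify_speeds(speeds.speeds)
    intervals, _ = detect_freezing(speeds, freeze_speed_max, min_duration)
    for t_start, t_end in intervals:
        mask = (speeds.t0 >= t_start - 1e-12) & (speeds.t0 < t_end - 1e-12)
        labels[mask] = "freezing"
    return labels


@dataclass(frozen=True)
class EthogramSummary:
    """Session-level locomotor endpoints with a 1-minute-bin breakdown.

    ``time_ratio`` maps each movement class to the fraction of session time
    spent in it (ratios sum to 1); ``bins`` is a long-format DataFrame with
    one row per (bin, class) plus per-bin distance.
    """

    video_id: str
    fish_id: str
    duration: float  # s
    total_distance: float  # cm
    average_velocity: float  # cm/s
    total_freezing_time: float  # s
    freezing_intervals: tuple[tuple[float, float], ...]
    time_ratio: dict[str, float]
    bins: pd.DataFrame

    def __post_init__(self) -> None:
        s = sum(self.time_ratio.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class time ratios must sum to 1, got {s}")
        if self.total_freezing_time > self.duration + 1e-9:
            raise ValueError("freezing time exceeds session duration")


def summarize_ethogram(
    traj: Trajectory,
    freeze_speed_max: float = FREEZE_SPEED_MAX,
    freeze_min_duration: float = FREEZE_MIN_DURATION,
    bin_seconds: float = BIN_SECONDS,
) -> EthogramSummary:
    """Ethogram endpoints for one session.

    Average velocity is total distance over total elapsed time (not moving
    time). Each inter-frame interval is assigned to the 1-minute bin
    containing its start time.
    """
    sp = compute_speed(traj, smoothing_window=1)
    labels = frame_labels(sp, freeze_speed_max, freeze_min_duration)
    intervals, total_freeze = detect_freezing(sp, freeze_speed_max, freeze_min_duration)
    seg_dist = sp.speeds * sp.dt
    duration = float(np.sum(sp.dt))
    total_distance = float(np.sum(seg_dist))

    time_ratio = {
        cls: float(np.sum(sp.dt[labels == cls]) / duration) for cls in SPEED_CLASSES
    }
    # renormalize away float dust so the partition property holds exactly
    s = sum(time_ratio.values())
    time_ratio = {k: v / s for k, v in time_ratio.items()}

    bin_idx = np.floor(sp.t0 / bin_seconds).astype(int)
    bin_idx -= bin_idx.min()
    rows = []
    for b in np.unique(bin_idx):
        in_bin = bin_idx == b
        bin_time = float(np.sum(sp.dt[in_bin]))
        for cls in SPEED_CLASSES:
            m = in_bin & (labels == cls)
            rows.append(
                {
                    "bin": int(b),
                    "class": cls,
                    "time_s": float(np.sum(sp.dt[m])),
                    "time_ratio": float(np.sum(sp.dt[m]) / bin_time) if bin_time else 0.0,
                    "distance_cm": float(np.sum(seg_dist[m])),
                }
            )
    bins = pd.DataFrame(rows)
    return EthogramSummary(
        video_id=traj.video_id,
        fish_id=traj.fish_id,
        duration=duration,
        total_distance=total_distance,
        average_velocity=total_distance / duration,
        total_freezing_time=total_freeze,
        freezing_intervals=tuple(intervals),
        time_ratio=time_ratio,
        bins=bins,
    )


ENDPOINTS = ("total_distance", "average_velocity", "total_freezing_time")


@dataclass(frozen=True)
class SessionComparison:
    """Morning (M) vs night (N) endpoints for one fish.

    ``night_dominant`` flags a reversed diurnal activity pattern: night
    total distance exceeding morning total distance. Wild-type zebrafish
    are day-active, so this flag marks the mutant-like inverted rhythm.
    """

    fish_id: str
    morning: EthogramSummary
    night: EthogramSummary
    difference: dict[str, float]  # night - morning
    ratio: dict[str, float]  # night / morning
    night_dominant: bool


def compare_sessions(
    morning: EthogramSummary, night: EthogramSummary, duration_tol: float = 0.5
) -> SessionComparison:
    """Compare equal-length M and N sessions of the same fish."""
    if morning.fish_id != night.fish_id:
        raise ValueError("sessions must come from the same fish")
    if abs(morning.duration - night.duration) > duration_tol:
        raise ValueError(
            f"session durations differ: {morning.duration} vs {night.duration} s"
        )
    diff = {}
    ratio = {}
    for ep in ENDPOINTS:
        m = getattr(morning, ep)
        n = getattr(night, ep)
        diff[ep] = n - m
        ratio[ep] = n / m if m else float("inf") if n else float("nan")
    return SessionComparison(
        fish_id=morning.fish_id,
        morning=morning,
        night=night,
        difference=diff,
        ratio=ratio,
        night_dominant=night.total_distance > morning.total_distance,
    )


def endpoint_table(summaries: Sequence[EthogramSummary], session: str | None = None) -> pd.DataFrame:
    """One row per fish x session with the scalar ethogram endpoints."""
    rows = []
    for s in summaries:
        row = {
            "video_id": s.video_id,
            "fish_id": s.fish_id,
            "session": session or "",
            "duration_s": s.duration,
            "total_distance_cm": s.total_distance,
            "average_velocity_cm_s": s.average_velocity,
            "total_freezing_time_s": s.total_freezing_time,
        }
        for cls in SPEED_CLASSES:
            row[f"ratio_{cls}"] = s.time_ratio[cls]
        rows.append(row)
    return pd.DataFrame(rows)
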