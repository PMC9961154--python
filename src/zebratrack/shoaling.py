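"""Group geometry for the shoaling test.

Five fish swim in a shallow 35 x 35 cm arena viewed from above. Per frame
the module reports pairwise-distance statistics, the shoal polygon area
(convex hull of the fish centroids), a shoal-existence flag (some subset of
at least 3 fish whose pairwise distances are all below the 12 cm
threshold), an excursion flag (some fish farther than the threshold from
its nearest neighbor), and the polarization order parameter (length of the
mean unit heading vector; 1 = perfectly aligned, 0 = disordered).

Session endpoints mirror the two acquisition pipelines of the assay:
distance statistics are averaged over all frames (continuous tracking)
while hull area and excursion frequency are evaluated on frames sampled
once per minute (20 extracted shots per 20-min video).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .trajectory import Trajectory

__all__ = [
    "SHOAL_THRESHOLD_CM",
    "HEADING_MIN_DISP_CM",
    "GroupFrame",
    "ShoalFrameMetrics",
    "ShoalSessionSummary",
    "group_frames",
    "frame_metrics",
    "session_summary",
]

SHOAL_THRESHOLD_CM = 12.0

#: Minimum 1-frame displacement for a defined heading; slower fish are
#: excluded from polarization (their direction is tracking noise).
HEADING_MIN_DISP_CM = 0.1


@dataclass(frozen=True)
class GroupFrame:
    """Positions (and optional headings) of all group members at one instant.

    ``headings`` holds unit vectors computed from each fish's displacement
    to the next retained frame; rows are NaN-masked for fish that moved
    less than :data:`HEADING_MIN_DISP_CM`.
    """

    t: float
    positions: np.ndarray  # (n_fish, 2) cm
    headings: np.ndarray | None = None  # (n_fish, 2) unit vectors, NaN where masked

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must be (n_fish >= 2, 2)")
        if self.headings is not None:
            h = np.asarray(self.headings, dtype=float)
            object.__setattr__(self, "headings", h)
            if h.shape != pos.shape:
                raise ValueError("headings must match positions shape")

    @property
    def n_fish(self) -> int:
        return int(self.positions.shape[0])


@dataclass(frozen=True)
class ShoalFrameMetrics:
    t: float
    mean_interfish_distance: float  # cm, mean over all pairs
    mean_nearest_neighbor_distance: float  # cm
    farthest_distance: float  # cm, max over pairs
    hull_area: float  # cm^2, 0 for collinear configurations
    shoal_present: bool | None  # None when < 3 fish
    excursion_present: bool | None
    polarization: float | None  # None when no fish has a defined heading

    def __post_init__(self) -> None:
        if not (
            self.mean_nearest_neighbor_distance
            <= self.mean_interfish_distance + 1e-9
            <= self.farthest_distance + 2e-9
        ):
            raise ValueError("distance ordering violated (NND <= mean <= farthest)")
        if self.polarization is not None and not -1e-12 <= self.polarization <= 1 + 1e-12:
            raise ValueError("polarization must lie in [0, 1]")


def _hull_area(points: np.ndarray) -> float:
    """Convex-hull area; 0 when the points are (near-)collinear."""
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0


def polarization(headings: np.ndarray) -> float | None:
    """Polar order parameter: length of the mean unit heading vector.

    NaN rows (masked/stationary fish) are excluded; returns None if no
    heading is defined.
    """
    h = np.asarray(headings, dtype=float)
    valid = ~np.isnan(h).any(axis=1)
    if not valid.any():
        return None
    return float(np.linalg.norm(h[valid].mean(axis=0)))


def frame_metrics(
    frame: GroupFrame, shoal_threshold: float = SHOAL_THRESHOLD_CM
) -> ShoalFrameMetrics:
    """Per-frame shoal geometry.

    Shoal existence uses the diameter criterion: there must be a subset of
    at least 3 fish with all pairwise distances strictly below the
    threshold (equivalently, some 3-fish subset qualifies). An excursion is
    any fish whose nearest-neighbor distance strictly exceeds the
    threshold. Both flags are None for groups of fewer than 3 fish.
    """
    pos = frame.positions
    n = frame.n_fish
    dvec = pdist(pos)
    dmat = squareform(dvec)
    np.fill_diagonal(dmat, np.inf)
    nnd = dmat.min(axis=1)

    if n >= 3:
        shoal = any(
            all(dmat[i, j] < shoal_threshold for i, j in combinations(trio, 2))
            for trio in combinations(range(n), 3)
        )
        excursion = bool(np.any(nnd > shoal_threshold))
    else:
        shoal = None
        excursion = None

    pol = polarization(frame.headings) if frame.headings is not None else None
    return ShoalFrameMetrics(
        t=frame.t,
        mean_interfish_distance=float(dvec.mean()),
        mean_nearest_neighbor_distance=float(nnd.mean()),
        farthest_distance=float(dvec.max()),
        hull_area=_hull_area(pos),
        shoal_present=shoal,
        excursion_present=excursion,
        polarization=pol,
    )


def group_frames(trajs: Sequence[Trajectory], with_headings: bool = True) -> list[GroupFrame]:
    """Assemble per-frame group snapshots from co-recorded trajectories.

    Only frames present in every trajectory are kept. Headings are unit
    displacement vectors to the next retained frame (NaN below the minimum
    displacement); the last frame inherits the previous heading.
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 fish")
    fps = trajs[0].fps
    common = trajs[0].frames
    for tr in trajs[1:]:
        if tr.fps != fps:
            raise ValueError("all trajectories must share the frame rate")
        common = np.intersect1d(common, tr.frames)
    if common.size < 2:
        raise ValueError("trajectories share fewer than 2 frames")
    pos = np.stack(
        [tr.xy[np.searchsorted(tr.frames, common)] for tr in trajs], axis=1
    )  # (n_frames, n_fish, 2)

    headings = None
    if with_headings:
        disp = np.diff(pos, axis=0)
        norm = np.linalg.norm(disp, axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(norm >= HEADING_MIN_DISP_CM, disp / norm, np.nan)
        headings = np.concatenate([unit, unit[-1:]], axis=0)

    t = common / fps
    return [
        GroupFrame(
            t=float(t[k]),
            positions=pos[k],
            headings=headings[k] if headings is not None else None,
        )
        for k in range(len(common))
    ]


@dataclass(frozen=True)
class ShoalSessionSummary:
    """Session endpoints for one group.

    Distance endpoints and polarization are means over all frames;
    ``hull_area`` means, ``shoal_frequency`` and ``excursion_frequency``
    counts refer to the sampled shots only.
    """

    n_frames: int
    n_sampled_frames: int
    mean_interfish_distance: float
    mean_nearest_neighbor_distance: float
    mean_farthest_distance: float
    mean_polarization: float | None
    mean_hull_area: float
    shoal_frequency: int
    excursion_frequency: int

    def __post_init__(self) -> None:
        if self.excursion_frequency > self.n_sampled_frames:
            raise ValueError("excursion count exceeds sampled frames")


def session_summary(
    frames: Sequence[GroupFrame],
    shoal_threshold: float = SHOAL_THRESHOLD_CM,
    shots: int = 20,
    shot_interval_s: float = 60.0,
) -> ShoalSessionSummary:
    """Summarize a shoaling session.

    Shots are the frames nearest to t = 0, interval, 2*interval, ... If the
    session is shorter than ``shots * shot_interval_s`` the shot spacing is
    shrunk to cover the session evenly (with a warning via ``warnings``).
    """
    if not frames:
        raise ValueError("empty frame list")
    per_frame = [frame_metrics(f, shoal_threshold) for f in frames]
    t = np.array([f.t for f in frames])
    span = t[-1] - t[0]
    if span < (shots - 1) * shot_interval_s:
        import warnings

        shot_interval_s = span / max(shots - 1, 1)
        warnings.warn(
            f"session shorter than requested sampling; shot interval shrunk to {shot_interval_s:.3g} s",
            stacklevel=2,
        )
    shot_times = t[0] + shot_interval_s * np.arange(shots)
    shot_idx = np.unique(np.searchsorted(t, shot_times).clip(0, len(t) - 1))
    sampled = [per_frame[i] for i in shot_idx]

    pols = [m.polarization for m in per_frame if m.polarization is not None]
    return ShoalSessionSummary(
        n_frames=len(frames),
        n_sampled_frames=len(sampled),
        mean_interfish_distance=float(np.mean([m.mean_interfish_distance for m in per_frame])),
        mean_nearest_neighbor_distance=float(
            np.mean([m.mean_nearest_neighbor_distance for m in per_frame])
        ),
        mean_farthest_distance=float(np.mean([m.farthest_distance for m in per_frame])),
        mean_polarization=float(np.mean(pols)) if pols else None,
        mean_hull_area=float(np.mean([m.hull_area for m in sampled])),
        shoal_frequency=sum(1 for m in sampled if m.shoal_present),
        excursion_frequency=sum(1 for m in sampled if m.excursion_present),
    )


def frame_table(metrics: Sequence[ShoalFrameMetrics]) -> pd.DataFrame:
    """Per-frame metric table (one row per frame)."""
    return pd.DataFrame(
        [
            {
                "t_s": m.t,
                "mean_interfish_cm": m.mean_interfish_distance,
                "mean_nnd_cm": m.mean_nearest_neighbor_distance,
                "farthest_cm": m.farthest_distance,
                "hull_area_cm2": m.hull_area,
                "shoal_present": m.shoal_present,
                "excursion_present": m.excursion_present,
                "polarization": m.polarization,
            }
            for m in metrics
        ]
    )
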