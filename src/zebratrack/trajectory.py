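"""Calibrated 2-D fish trajectories, arena geometry, and zone assignment.

A :class:`Trajectory` is the time-ordered path of one fish in arena
coordinates (cm), sampled at a fixed frame rate (25 fps in the standard
assays). Arenas are described by :class:`ArenaSpec`; virtual zones used for
occupancy endpoints (top/bottom band of the novel tank, mirror-contact and
approach strips, conspecific/empty halves) are axis-aligned distance bands
collected in a :class:`ZonePartition`.

Coordinate convention: origin at the bottom-left of the camera view,
x rightward, y upward, units cm after calibration.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaSpec",
    "Zone",
    "ZonePartition",
    "Trajectory",
    "TrajectoryError",
    "read_trajectories",
    "write_trajectories",
    "calibrate",
    "assign_zone",
    "arena_preset",
    "zone_preset",
    "load_arena_config",
]

DEFAULT_FPS = 25.0

#: Coordinate precision (cm) used when writing trajectory tables.
WRITE_DECIMALS = 6


class TrajectoryError(ValueError):
    """Raised for malformed trajectory tables or invalid geometry."""


@dataclass(frozen=True)
class ArenaSpec:
    """Physical arena dimensions in cm, with optional pixel calibration.

    ``width``/``height`` describe the camera-facing plane used for
    analysis. For side-view tanks ``height`` is the vertical extent and
    ``water_depth`` the filled depth; for top-view arenas ``height`` is the
    second horizontal dimension and ``water_depth`` is the (shallow) fill.
    """

    name: str
    width: float
    height: float
    water_depth: float
    px_per_cm: float | None = None

    def __post_init__(self) -> None:
        for attr in ("width", "height", "water_depth"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")


@dataclass(frozen=True)
class Zone:
    """Half-open axis-aligned distance band: ``lo <= d < hi``.

    ``d`` is the distance of a point from a reference wall along ``axis``
    ("x" or "y"). ``origin`` selects the wall: "min" measures from the
    low-coordinate wall (d = coordinate), "max" from the high-coordinate
    wall (d = wall - coordinate). ``hi`` may be ``inf`` for an unbounded
    band. The half-open rule makes every boundary point belong to exactly
    one zone.
    """

    axis: str
    lo: float
    hi: float
    origin: str = "min"

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if self.origin not in ("min", "max"):
            raise ValueError("origin must be 'min' or 'max'")
        if not self.lo < self.hi:
            raise ValueError("zone interval must satisfy lo < hi")

    def distance(self, x: float, y: float, arena: ArenaSpec) -> float:
        coord = x if self.axis == "x" else y
        if self.origin == "min":
            return coord
        wall = arena.width if self.axis == "x" else arena.height
        return wall - coord

    def contains(self, x: float, y: float, arena: ArenaSpec) -> bool:
        d = self.distance(x, y, arena)
        return self.lo <= d < self.hi


@dataclass(frozen=True)
class ZonePartition:
    """Named, pairwise-disjoint zones over an arena.

    Partial partitions are allowed: points matching no zone are labelled
    ``"outside"``. Disjointness is validated for zones sharing an axis and
    origin (interval overlap); zones on different axes are the caller's
    responsibility and are rejected here to keep membership unambiguous.
    """

    arena: ArenaSpec
    zones: Mapping[str, Zone]

    def __post_init__(self) -> None:
        items = list(self.zones.items())
        if not items:
            raise ValueError("partition needs at least one zone")
        axes = {(z.axis, z.origin) for _, z in items}
        if len(axes) > 1:
            raise ValueError("all zones in a partition must share axis and origin")
        ivals = sorted((z.lo, z.hi, name) for name, z in items)
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ivals, ivals[1:]):
            if lo2 < hi1:
                raise ValueError(f"zones {n1!r} and {n2!r} overlap")

    def names(self) -> list[str]:
        return list(self.zones)


def assign_zone(point: tuple[float, float], partition: ZonePartition) -> str:
    """Label a point with the single zone containing it, else ``"outside"``.

    Boundary points are resolved by the half-open rule: a zone includes its
    lower distance bound and excludes its upper.
    """
    x, y = point
    for name, zone in partition.zones.items():
        if zone.contains(x, y, partition.arena):
            return name
    return "outside"


def assign_zones(xy: np.ndarray, partition: ZonePartition) -> np.ndarray:
    """Vectorized :func:`assign_zone` over an (n, 2) array -> array of labels."""
    xy = np.asarray(xy, dtype=float)
    out = np.full(len(xy), "outside", dtype=object)
    arena = partition.arena
    for name, zone in partition.zones.items():
        coord = xy[:, 0] if zone.axis == "x" else xy[:, 1]
        if zone.origin == "max":
            wall = arena.width if zone.axis == "x" else arena.height
            d = wall - coord
        else:
            d = coord
        out[(d >= zone.lo) & (d < zone.hi)] = name
    return out.astype(str)


@dataclass(frozen=True)
class Trajectory:
    """Path of one fish: strictly increasing frames with positions in cm.

    ``t`` always equals ``frame / fps``; positions must be finite. Units
    are cm once calibrated (see :func:`calibrate`); uncalibrated pixel
    trajectories use the same container with ``units="px"``.
    """

    video_id: str
    fish_id: str
    fps: float
    frames: np.ndarray  # (n,) int
    xy: np.ndarray  # (n, 2) float, cm
    units: str = "cm"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)
        if frames.ndim != 1 or xy.shape != (frames.size, 2):
            raise TrajectoryError("frames must be (n,), xy must be (n, 2)")
        if frames.size < 2:
            raise TrajectoryError("a trajectory needs at least 2 samples")
        if np.any(np.diff(frames) <= 0):
            raise TrajectoryError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(xy)):
            raise TrajectoryError("non-finite coordinates")
        if self.fps <= 0:
            raise TrajectoryError("fps must be > 0")

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, ``frame / fps``."""
        return self.frames / self.fps

    @property
    def n(self) -> int:
        return int(self.frames.size)

    @property
    def duration(self) -> float:
        """Elapsed time first-to-last sample, s."""
        return float((self.frames[-1] - self.frames[0]) / self.fps)

    def is_contiguous(self) -> bool:
        return bool(np.all(np.diff(self.frames) == 1))

    def interpolate_gaps(self, max_gap: int = 5) -> "Trajectory":
        """Fill dropped frames up to ``max_gap`` by linear interpolation.

        Gaps longer than ``max_gap`` missing frames are left in place; use
        :meth:`split_on_gaps` afterwards to separate them.
        """
        steps = np.diff(self.frames)
        if np.all(steps == 1):
            return self
        frames_out: list[int] = []
        xy_out: list[np.ndarray] = []
        for i in range(self.n - 1):
            f0, f1 = int(self.frames[i]), int(self.frames[i + 1])
            frames_out.append(f0)
            xy_out.append(self.xy[i])
            missing = f1 - f0 - 1
            if 0 < missing <= max_gap:
                for f in range(f0 + 1, f1):
                    w = (f - f0) / (f1 - f0)
                    frames_out.append(f)
                    xy_out.append((1 - w) * self.xy[i] + w * self.xy[i + 1])
        frames_out.append(int(self.frames[-1]))
        xy_out.append(self.xy[-1])
        return replace(self, frames=np.array(frames_out), xy=np.array(xy_out))

    def split_on_gaps(self, max_gap: int = 5) -> list["Trajectory"]:
        """Split into contiguous-enough segments at gaps > ``max_gap`` frames."""
        breaks = np.where(np.diff(self.frames) > max_gap + 1)[0]
        if breaks.size == 0:
            return [self]
        segs = []
        start = 0
        for b in list(breaks) + [self.n - 1]:
            stop = b + 1
            if stop - start >= 2:
                segs.append(
                    replace(self, frames=self.frames[start:stop], xy=self.xy[start:stop])
                )
            start = stop
        return segs


# ---------------------------------------------------------------------------
# I/O


def read_trajectories(
    source: str | Path | io.IOBase,
    fps: float = DEFAULT_FPS,
    sep: str | None = None,
    units: str = "cm",
) -> list[Trajectory]:
    """Read a delimited trajectory table into one Trajectory per (video, fish).

    Expected columns: ``video_id, fish_id, frame, x, y`` with optional
    ``t_s``; the delimiter is sniffed when ``sep`` is None. Rows are sorted
    by frame within each fish. Duplicate (video_id, fish_id, frame) rows and
    non-finite coordinates are rejected with the offending row numbers.
    """
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")
    required = {"video_id", "fish_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryError(f"missing columns: {sorted(missing)}")
    bad = df.index[~np.isfinite(df["x"]) | ~np.isfinite(df["y"])]
    if len(bad):
        raise TrajectoryError(
            f"non-finite coordinates at table rows {list(bad[:10])}"
        )
    dup = df.duplicated(subset=["video_id", "fish_id", "frame"], keep=False)
    if dup.any():
        raise TrajectoryError(
            f"duplicate (video_id, fish_id, frame) at table rows {list(df.index[dup][:10])}"
        )
    if "t_s" in df.columns:
        expected = df["frame"] / fps
        if np.max(np.abs(df["t_s"] - expected)) > 1e-6:
            raise TrajectoryError("t_s column inconsistent with frame/fps")
    out = []
    for (vid, fid), grp in df.groupby(["video_id", "fish_id"], sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                video_id=str(vid),
                fish_id=str(fid),
                fps=fps,
                frames=grp["frame"].to_numpy(np.int64),
                xy=grp[["x", "y"]].to_numpy(float),
                units=units,
            )
        )
    return out


def write_trajectories(
    trajs: Iterable[Trajectory], dest: str | Path | io.IOBase, sep: str = ","
) -> None:
    """Write trajectories to the standard table (positions rounded to 1e-6 cm)."""
    parts = []
    for tr in trajs:
        parts.append(
            pd.DataFrame(
                {
                    "video_id": tr.video_id,
                    "fish_id": tr.fish_id,
                    "frame": tr.frames,
                    "t_s": np.round(tr.t, WRITE_DECIMALS),
                    "x": np.round(tr.xy[:, 0], WRITE_DECIMALS),
                    "y": np.round(tr.xy[:, 1], WRITE_DECIMALS),
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(dest, sep=sep, index=False)


def calibrate(
    traj: Trajectory, arena: ArenaSpec, tolerance_cm: float = 0.5
) -> tuple[Trajectory, list[dict]]:
    """Convert a pixel trajectory to cm using ``arena.px_per_cm``.

    Returns the calibrated trajectory and a list of out-of-bounds reports
    (points beyond the arena plus ``tolerance_cm``); such points are kept,
    not clipped, so the caller can decide.
    """
    if arena.px_per_cm is None:
        raise TrajectoryError(f"arena {arena.name!r} has no px_per_cm calibration")
    xy = traj.xy / arena.px_per_cm
    oob = []
    for i, (x, y) in enumerate(xy):
        if (
            x < -tolerance_cm
            or y < -tolerance_cm
            or x > arena.width + tolerance_cm
            or y > arena.height + tolerance_cm
        ):
            oob.append({"index": i, "frame": int(traj.frames[i]), "x": float(x), "y": float(y)})
    return replace(traj, xy=xy, units="cm"), oob


# ---------------------------------------------------------------------------
# Presets for the standard assays


def arena_preset(name: str) -> ArenaSpec:
    """Standard arenas.

    * ``novel_tank`` — side view of the trapezoid tank, modeled as its
      30 x 15 cm camera-facing rectangle, water depth 10 cm.
    * ``mirror`` — 24 x 10 cm top view, water depth 2 cm; mirror on one
      10 cm wall (at x = 0).
    * ``social_preference`` — 16 x 8 cm middle chamber of the three-chamber
      tank (48 cm split in three), conspecific side at x = 0.
    * ``shoaling`` — 35 x 35 cm top view, water depth 2 cm.
    """
    presets = {
        "novel_tank": ArenaSpec("novel_tank", width=30.0, height=15.0, water_depth=10.0),
        "mirror": ArenaSpec("mirror", width=24.0, height=10.0, water_depth=2.0),
        "social_preference": ArenaSpec(
            "social_preference", width=16.0, height=8.0, water_depth=10.0
        ),
        "shoaling": ArenaSpec("shoaling", width=35.0, height=35.0, water_depth=2.0),
    }
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown arena preset {name!r}; choose from {sorted(presets)}")


def zone_preset(name: str) -> ZonePartition:
    """Standard zone partitions matching :func:`arena_preset`.

    * ``novel_tank`` — full vertical split of the water column into
      ``bottom`` [0, 5) cm and ``top`` [5, inf) cm from the tank floor.
    * ``mirror`` — partial partition by distance from the mirror wall:
      ``contact`` [0, 1.5) cm (mirror biting) and ``approach`` [1.5, 5) cm;
      farther points are "outside".
    * ``social_preference`` — full split of the middle chamber at its
      midline: ``CS`` [0, 8) cm from the conspecific-side wall, ``ES``
      [8, inf) cm.
    """
    arena = arena_preset(name if name != "social_preference" else "social_preference")
    if name == "novel_tank":
        zones = {"bottom": Zone("y", 0.0, 5.0), "top": Zone("y", 5.0, math.inf)}
    elif name == "mirror":
        zones = {"contact": Zone("x", 0.0, 1.5), "approach": Zone("x", 1.5, 5.0)}
    elif name == "social_preference":
        zones = {"CS": Zone("x", 0.0, 8.0), "ES": Zone("x", 8.0, math.inf)}
    else:
        raise KeyError(f"no zone preset for {name!r}")
    return ZonePartition(arena=arena, zones=zones)


def load_arena_config(path: str | Path) -> tuple[ArenaSpec, ZonePartition]:
    """Load an arena + zone partition from a YAML or JSON config file.

    Schema::

        arena: {name, width, height, water_depth, px_per_cm?}
        zones: {<name>: {axis, lo, hi, origin?}, ...}

    ``hi`` may be the string ``"inf"``.
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    arena = ArenaSpec(**cfg["arena"])
    zones = {}
    for name, z in cfg["zones"].items():
        hi = z["hi"]
        zones[name] = Zone(
            axis=z["axis"],
            lo=float(z["lo"]),
            hi=math.inf if hi in ("inf", ".inf", None) else float(hi),
            origin=z.get("origin", "min"),
        )
    return arena, ZonePartition(arena=arena, zones=zones)
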