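"""Seeded synthetic fish trajectories with known ground truth.

Two stochastic generators and one deterministic script builder:

* :func:`simulate_fish` — a state-switching correlated random walk for a
  single fish. Hidden states are the four speed classes of the ethogram
  (freeze / small / moderate / large) with a per-step Markov transition
  matrix; within a state the speed is drawn from that class's range, the
  heading accumulates wrapped-Gaussian noise, and an optional downward
  drift (bottom bias) produces the bottom-dwelling, anxiety-like profile.
* :func:`simulate_shoal` — n fish steered by a weighted sum of heading
  persistence, cohesion toward the group centroid, and alignment with the
  mean neighbor heading, plus angular noise, at a constant cruise speed.
* :func:`scripted_trajectory` — an exact piecewise path (hold / move
  segments) for planted-ground-truth tests of the endpoint modules.

All walls are reflective (tanks have walls); the step is 1/25 s to match
the 25 fps recordings. Identical (model, seed) pairs give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trajectory import ArenaSpec, DEFAULT_FPS, Trajectory

__all__ = [
    "FishStateModel",
    "GroupModel",
    "GroundTruth",
    "simulate_fish",
    "simulate_shoal",
    "scripted_trajectory",
    "Hold",
    "MoveTo",
]

STATES = ("freeze", "small", "moderate", "large")

#: Speed range (cm/s) sampled within each state; consistent with the
#: ethogram class boundaries (small < 1, moderate 1-15, large > 15).
STATE_SPEED_RANGES = {
    "freeze": (0.0, 0.0),
    "small": (0.1, 0.9),
    "moderate": (1.5, 12.0),
    "large": (16.0, 28.0),
}


@dataclass(frozen=True)
class FishStateModel:
    """Single-fish movement model.

    ``transition`` is the per-step (dt = 1/fps) Markov matrix over the
    states (freeze, small, moderate, large), rows summing to 1.
    ``heading_noise`` gives the per-step wrapped-Gaussian heading s.d.
    (radians) per state; ``bottom_bias`` is a constant downward drift
    velocity (cm/s), 0 for an unbiased swimmer.
    """

    transition: np.ndarray
    heading_noise: dict[str, float] = field(
        default_factory=lambda: {"freeze": 0.0, "small": 0.8, "moderate": 0.3, "large": 0.15}
    )
    bottom_bias: float = 0.0
    speed_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(STATE_SPEED_RANGES)
    )

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "transition", T)
        if T.shape != (4, 4):
            raise ValueError("transition must be 4x4 over (freeze, small, moderate, large)")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be nonnegative and sum to 1")
        if self.bottom_bias < 0:
            raise ValueError("bottom_bias must be >= 0")
        for s, (lo, hi) in self.speed_ranges.items():
            if not 0 <= lo <= hi:
                raise ValueError(f"bad speed range for {s}")

    @classmethod
    def default(
        cls,
        bottom_bias: float = 0.0,
        dwell_s: dict[str, float] | None = None,
        stationary: Sequence[float] = (0.1, 0.15, 0.65, 0.1),
        fps: float = DEFAULT_FPS,
    ) -> "FishStateModel":
        """Build a model from mean state dwell times and target occupancy.

        Each state exits with per-step probability dt/dwell and the exit is
        distributed over the other states proportionally to the requested
        stationary occupancy — a simple, adequate approximation for test
        fixtures.
        """
        dwell = dwell_s or {"freeze": 2.0, "small": 1.0, "moderate": 4.0, "large": 0.8}
        pi = np.asarray(stationary, dtype=float)
        pi = pi / pi.sum()
        dt = 1.0 / fps
        T = np.zeros((4, 4))
        for i, s in enumerate(STATES):
            p_exit = min(dt / dwell[s], 1.0)
            others = [j for j in range(4) if j != i]
            w = pi[others] / pi[others].sum()
            T[i, i] = 1.0 - p_exit
            T[i, others] = p_exit * w
        return cls(transition=T, bottom_bias=bottom_bias)


@dataclass(frozen=True)
class GroupModel:
    """Shoal steering model: persistence / cohesion / alignment weights."""

    arena: ArenaSpec
    n_fish: int = 5
    w_persistence: float = 1.0
    w_cohesion: float = 0.5
    w_alignment: float = 0.5
    noise_rad: float = 0.3
    cruise_speed: float = 5.0  # cm/s, within the moderate class
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        if self.n_fish < 2:
            raise ValueError("n_fish must be >= 2")
        w = (self.w_persistence, self.w_cohesion, self.w_alignment)
        if any(x < 0 or not math.isfinite(x) for x in w):
            raise ValueError("weights must be finite and >= 0")
        if all(x == 0 for x in w):
            raise ValueError("at least one steering weight must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth: per-frame state labels and parameters used."""

    seed: int
    params: dict
    states: np.ndarray | None = None  # (n_frames,) or (n_frames, n_fish) labels


def _reflect(val: float, lo: float, hi: float) -> tuple[float, bool]:
    """Reflect a coordinate into [lo, hi]; second value reports a bounce."""
    bounced = False
    # at most a few bounces for realistic step sizes
    while val < lo or val > hi:
        bounced = True
        if val < lo:
            val = 2 * lo - val
        else:
            val = 2 * hi - val
    return val, bounced


def simulate_fish(
    model: FishStateModel,
    arena: ArenaSpec,
    duration: float,
    seed: int,
    video_id: str = "sim",
    fish_id: str = "f1",
    vertical_extent: float | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one fish for ``duration`` seconds at 25 fps.

    The vertical range is the water column (``arena.water_depth`` for
    side-view arenas) unless ``vertical_extent`` overrides it. The fish
    starts at the horizontal center, slightly below mid-water (released
    fish dive initially, and this keeps the start off the top/bottom
    split).
    """
    if duration < 1.0:
        raise ValueError("duration must be >= 1 s")
    fps = DEFAULT_FPS
    dt = 1.0 / fps
    n = int(round(duration * fps)) + 1
    rng = np.random.default_rng(seed)
    y_max = vertical_extent if vertical_extent is not None else arena.water_depth

    T_cum = np.cumsum(model.transition, axis=1)
    state = 2  # start cruising (moderate)
    theta = rng.uniform(0, 2 * np.pi)
    pos = np.array([arena.width / 2, 0.4 * y_max])
    xy = np.empty((n, 2))
    states = np.empty(n, dtype=object)
    xy[0] = pos
    states[0] = STATES[state]
    for k in range(1, n):
        state = int(np.searchsorted(T_cum[state], rng.random(), side="right"))
        name = STATES[state]
        lo, hi = model.speed_ranges[name]
        speed = lo if hi == lo else rng.uniform(lo, hi)
        theta = (theta + rng.normal(0.0, model.heading_noise[name])) % (2 * np.pi)
        step = np.array(
            [
                speed * dt * math.cos(theta),
                speed * dt * math.sin(theta) - model.bottom_bias * dt,
            ]
        )
        nxt = pos + step
        x, bx = _reflect(nxt[0], 0.0, arena.width)
        y, by = _reflect(nxt[1], 0.0, y_max)
        if (bx or by) and (x != pos[0] or y != pos[1]):
            theta = math.atan2(y - pos[1], x - pos[0])
        pos = np.array([x, y])
        xy[k] = pos
        states[k] = name
    traj = Trajectory(
        video_id=video_id,
        fish_id=fish_id,
        fps=fps,
        frames=np.arange(n),
        xy=np.round(xy, 6),
    )
    truth = GroundTruth(
        seed=seed,
        params={"bottom_bias": model.bottom_bias, "duration": duration},
        states=states,
    )
    return traj, truth


def simulate_shoal(
    model: GroupModel, duration: float, seed: int, video_id: str = "sim_shoal"
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate a fish group for ``duration`` seconds.

    Per step each fish's desired direction is the normalized weighted sum
    of its current heading (persistence), the unit vector toward the group
    centroid (cohesion), and the mean heading of the others (alignment),
    perturbed by wrapped-Gaussian noise; fish cruise at constant speed and
    reflect off walls.
    """
    fps = model.fps
    dt = 1.0 / fps
    n_steps = int(round(duration * fps)) + 1
    rng = np.random.default_rng(seed)
    nf = model.n_fish
    W, H = model.arena.width, model.arena.height

    # start clustered near the center, random headings
    pos = np.column_stack(
        [
            rng.uniform(W / 2 - 3, W / 2 + 3, nf),
            rng.uniform(H / 2 - 3, H / 2 + 3, nf),
        ]
    )
    theta = rng.uniform(0, 2 * np.pi, nf)
    out = np.empty((n_steps, nf, 2))
    out[0] = pos
    for k in range(1, n_steps):
        head = np.column_stack([np.cos(theta), np.sin(theta)])
        centroid = pos.mean(axis=0)
        to_c = centroid - pos
        norm = np.linalg.norm(to_c, axis=1, keepdims=True)
        to_c = np.divide(to_c, norm, out=np.zeros_like(to_c), where=norm > 1e-12)
        mean_head = (head.sum(axis=0) - head) / (nf - 1)
        desired = (
            model.w_persistence * head
            + model.w_cohesion * to_c
            + model.w_alignment * mean_head
        )
        dn = np.linalg.norm(desired, axis=1)
        # fall back to the current heading when the steering sum cancels
        weak = dn < 1e-9
        new_theta = np.where(weak, theta, np.arctan2(desired[:, 1], desired[:, 0]))
        theta = (new_theta + rng.normal(0.0, model.noise_rad, nf)) % (2 * np.pi)
        step = model.cruise_speed * dt
        nxt = pos + step * np.column_stack([np.cos(theta), np.sin(theta)])
        for i in range(nf):
            x, bx = _reflect(nxt[i, 0], 0.0, W)
            y, by = _reflect(nxt[i, 1], 0.0, H)
            if bx or by:
                theta[i] = math.atan2(y - pos[i, 1], x - pos[i, 0])
            nxt[i] = (x, y)
        pos = nxt
        out[k] = pos
    frames = np.arange(n_steps)
    trajs = [
        Trajectory(
            video_id=video_id,
            fish_id=f"f{i + 1}",
            fps=fps,
            frames=frames,
            xy=np.round(out[:, i, :], 6),
        )
        for i in range(nf)
    ]
    truth = GroundTruth(
        seed=seed,
        params={
            "n_fish": nf,
            "w_persistence": model.w_persistence,
            "w_cohesion": model.w_cohesion,
            "w_alignment": model.w_alignment,
            "noise_rad": model.noise_rad,
            "cruise_speed": model.cruise_speed,
            "duration": duration,
        },
    )
    return trajs, truth


# ---------------------------------------------------------------------------
# Deterministic scripted paths


@dataclass(frozen=True)
class Hold:
    """Stay at the current position for ``duration`` seconds."""

    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class MoveTo:
    """Move in a straight line to ``target`` at constant ``speed`` (cm/s)."""

    target: tuple[float, float]
    speed: float

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be > 0")


def scripted_trajectory(
    start: tuple[float, float],
    steps: Sequence[Hold | MoveTo],
    arena: ArenaSpec | None = None,
    fps: float = DEFAULT_FPS,
    video_id: str = "script",
    fish_id: str = "f1",
    vertical_extent: float | None = None,
) -> Trajectory:
    """Exact piecewise-linear trajectory realizing a hold/move script.

    Positions are sampled at frame times with no noise, so endpoint modules
    can be tested against exactly planted boundaries. Waypoints outside the
    arena (when given) are rejected.
    """
    if not steps:
        raise ValueError("empty script")

    def check(p: tuple[float, float]) -> None:
        if arena is None:
            return
        y_max = vertical_extent if vertical_extent is not None else arena.height
        if not (0 <= p[0] <= arena.width and 0 <= p[1] <= y_max):
            raise ValueError(f"waypoint {p} outside arena {arena.name!r}")

    check(start)
    knots_t = [0.0]
    knots_xy = [np.asarray(start, dtype=float)]
    for step in steps:
        here = knots_xy[-1]
        if isinstance(step, Hold):
            knots_t.append(knots_t[-1] + step.duration)
            knots_xy.append(here)
        elif isinstance(step, MoveTo):
            check(step.target)
            tgt = np.asarray(step.target, dtype=float)
            dist = float(np.linalg.norm(tgt - here))
            knots_t.append(knots_t[-1] + dist / step.speed)
            knots_xy.append(tgt)
        else:
            raise TypeError(f"unknown script step {step!r}")
    total = knots_t[-1]
    n = int(math.floor(total * fps + 1e-9)) + 1
    t = np.arange(n) / fps
    kt = np.array(knots_t)
    kxy = np.array(knots_xy)
    x = np.interp(t, kt, kxy[:, 0])
    y = np.interp(t, kt, kxy[:, 1])
    return Trajectory(
        video_id=video_id,
        fish_id=fish_id,
        fps=fps,
        frames=np.arange(n),
        xy=np.column_stack([x, y]),
    )
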