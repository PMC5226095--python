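"""Milling-swarm stimulus simulator.

Simulates 1-50 square "prey" items moving inside a central containment
region of the screen. Each item follows an uncoordinated correlated random
walk: per frame its heading receives a wrapped-normal increment, and in the
variable-speed condition its speed receives a normal increment (SD 40 px/s
per frame) clamped into [100, 300] px/s around a 200 px/s mean. In the
constant-speed condition every item moves at exactly 200 px/s. One item per
trial is the designated target; its centre (and later the cursor centre)
is recorded every 10 ms over a 5000 ms trial.

Coordinates are continuous pixels with the origin at the arena centre,
x rightward, y upward. The containment region constrains square *centres*;
headings reflect specularly at its edges.
"""

from __future__ import annotations

import gc
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@contextmanager
def _gc_paused():
    """Pause the cyclic GC inside allocation-heavy numeric loops.

    The frame loops allocate many small temporaries per iteration; with
    a large interpreter heap the collector otherwise dominates runtime.
    No reference cycles are created inside the guarded kernels.
    """
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()

PAPER_GROUP_SIZES = (1, 10, 30, 50)
COLORATIONS = ("orthogonal", "parallel", "trinary")

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SpeedProcess:
    """Per-frame speed process of one square.

    ``constant``: speed pinned at ``mean_speed``. ``variable``: bounded
    random walk — each frame adds a N(0, increment_sd^2) draw to the
    previous frame's speed, hard-clamped into [min_speed, max_speed].
    The initial speed is ``mean_speed`` plus one such draw (clamped).
    """

    kind: str = "constant"
    mean_speed: float = 200.0
    increment_sd: float = 40.0
    min_speed: float = 100.0
    max_speed: float = 300.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "variable"):
            raise ValueError(f"unknown speed process kind: {self.kind!r}")
        if not (self.min_speed < self.mean_speed < self.max_speed):
            raise ValueError("require min_speed < mean_speed < max_speed")
        if self.increment_sd <= 0:
            raise ValueError("increment_sd must be positive")

    @classmethod
    def constant(cls, speed: float = 200.0) -> "SpeedProcess":
        return cls(kind="constant", mean_speed=speed)

    @classmethod
    def variable(cls, **kw) -> "SpeedProcess":
        return cls(kind="variable", **kw)


@dataclass(frozen=True)
class TrialConfig:
    """Full specification of one stimulus trial.

    Defaults reproduce the study conditions: a 268 x 268 px containment
    region, 32 x 32 px squares, 5000 ms trials sampled every 10 ms, and a
    100 Hz frame rate (one frame per recorded sample).

    ``turn_sd`` is the SD (radians/frame) of the wrapped-normal heading
    increment of the correlated random walk; ``allow_any_n`` lifts the
    restriction of ``n_agents`` to the study's levels {1, 10, 30, 50}.
    """

    n_agents: int = 10
    coloration: str = "trinary"
    speed_process: SpeedProcess = field(default_factory=SpeedProcess)
    duration_ms: int = 5000
    arena_side: float = 268.0
    square_side: float = 32.0
    frame_rate: float = 100.0
    sample_interval_ms: int = 10
    turn_sd: float = 0.35
    seed: int = 0
    allow_any_n: bool = False

    def __post_init__(self) -> None:
        if self.n_agents not in PAPER_GROUP_SIZES and not self.allow_any_n:
            raise ValueError(
                f"n_agents={self.n_agents} outside the study levels "
                f"{PAPER_GROUP_SIZES}; pass allow_any_n=True to override"
            )
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.coloration not in COLORATIONS:
            raise ValueError(f"unknown coloration: {self.coloration!r}")
        if self.duration_ms % self.sample_interval_ms != 0:
            raise ValueError("duration_ms must be divisible by sample_interval_ms")
        frames_per_sample = self.sample_interval_ms * self.frame_rate / 1000.0
        if abs(frames_per_sample - round(frames_per_sample)) > 1e-9 or frames_per_sample < 1:
            raise ValueError(
                "sample interval must be an integer number of frames "
                f"(got {frames_per_sample} frames/sample)"
            )
        if self.turn_sd < 0:
            raise ValueError("turn_sd must be >= 0")

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms * self.frame_rate / 1000.0))

    @property
    def frames_per_sample(self) -> int:
        return int(round(self.sample_interval_ms * self.frame_rate / 1000.0))

    @property
    def half_side(self) -> float:
        """Half-width of the containment region for square centres."""
        return self.arena_side / 2.0


@dataclass(frozen=True)
class AgentState:
    """One square's kinematic state at one frame."""

    x: float
    y: float
    heading: float
    speed: float


@dataclass
class Trajectory:
    """Per-frame states of every agent in one trial.

    Arrays are shaped ``(n_frames, n_agents)``. Recorded frames are the
    post-step states at t = dt, 2 dt, ..., duration (500 frames at the
    defaults); the t = 0 initial state is kept in the ``*0`` fields.
    """

    config: TrialConfig
    target_index: int
    times_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    x0: np.ndarray
    y0: np.ndarray
    heading0: np.ndarray
    speed0: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_agents(self) -> int:
        return self.x.shape[1]

    def state(self, frame: int, agent: int) -> AgentState:
        return AgentState(
            self.x[frame, agent],
            self.y[frame, agent],
            self.heading[frame, agent],
            self.speed[frame, agent],
        )

    def sample_indices(self) -> np.ndarray:
        """Frame indices of the 10 ms recording grid."""
        k = self.config.frames_per_sample
        return np.arange(k - 1, self.n_frames, k)

    def target_series(self) -> tuple[np.ndarray, np.ndarray]:
        """Target-centre positions on the recording grid.

        Returns ``(times_ms, xy)`` with ``xy`` shaped (n_samples, 2).
        """
        idx = self.sample_indices()
        xy = np.stack(
            [self.x[idx, self.target_index], self.y[idx, self.target_index]], axis=1
        )
        return self.times_ms[idx], xy

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(frame, agent) table."""
        n_f, n_a = self.x.shape
        frames = np.repeat(np.arange(1, n_f + 1), n_a)
        agents = np.tile(np.arange(n_a), n_f)
        return pd.DataFrame(
            {
                "frame": frames,
                "time_ms": np.repeat(self.times_ms, n_a),
                "agent_id": agents,
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "heading": self.heading.ravel(),
                "speed": self.speed.ravel(),
                "is_target": agents == self.target_index,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> str:
        """JSON manifest (config + seed) sufficient to regenerate the trial."""
        cfg = self.config
        d = {
            "n_agents": cfg.n_agents,
            "coloration": cfg.coloration,
            "speed_kind": cfg.speed_process.kind,
            "mean_speed": cfg.speed_process.mean_speed,
            "increment_sd": cfg.speed_process.increment_sd,
            "min_speed": cfg.speed_process.min_speed,
            "max_speed": cfg.speed_process.max_speed,
            "duration_ms": cfg.duration_ms,
            "arena_side": cfg.arena_side,
            "square_side": cfg.square_side,
            "frame_rate": cfg.frame_rate,
            "sample_interval_ms": cfg.sample_interval_ms,
            "turn_sd": cfg.turn_sd,
            "seed": cfg.seed,
            "target_index": int(self.target_index),
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# elementary kinematic steps (scalar/array; the batch engine re-uses them)
# ---------------------------------------------------------------------------


def step_speed(speed, process: SpeedProcess, rng: np.random.Generator):
    """Advance a speed (scalar or array) one frame under ``process``."""
    if process.kind == "constant":
        return np.broadcast_to(np.asarray(process.mean_speed), np.shape(speed)).copy() \
            if np.ndim(speed) else process.mean_speed
    draw = rng.normal(0.0, process.increment_sd, size=np.shape(speed) or None)
    return np.clip(speed + draw, process.min_speed, process.max_speed)


def step_heading(heading, turn_sd: float, rng: np.random.Generator):
    """Wrapped-normal heading increment with SD ``turn_sd`` (radians)."""
    if turn_sd < 0:
        raise ValueError("turn_sd must be >= 0")
    draw = rng.normal(0.0, turn_sd, size=np.shape(heading) or None) if turn_sd > 0 else 0.0
    return np.mod(heading + draw, _TWO_PI)


def step_position(state: AgentState, dt: float, half_side: float) -> tuple[float, float, float]:
    """Euler position update with specular boundary reflection.

    Returns ``(x, y, heading)`` — the heading may flip at an edge.
    """
    x = state.x + state.speed * dt * np.cos(state.heading)
    y = state.y + state.speed * dt * np.sin(state.heading)
    x, y, heading = _reflect(
        np.asarray(x), np.asarray(y), np.asarray(state.heading, dtype=float), half_side
    )
    return float(x), float(y), float(heading)


def _reflect(x: np.ndarray, y: np.ndarray, heading: np.ndarray, half: float,
             inplace: bool = False):
    """Specular reflection of positions/headings at the containment edges.

    Per-frame displacements (<= 3 px at the study speeds) are far smaller
    than the region, so a single fold per axis suffices. With
    ``inplace=True`` the input arrays are mutated and returned (the batch
    kernel relies on this to avoid per-frame reallocation).
    """
    if not inplace:
        heading = np.array(heading, dtype=float, copy=True)
        x = np.array(x, dtype=float, copy=True)
        y = np.array(y, dtype=float, copy=True)

    over = x > half
    under = x < -half
    if np.any(over):
        x[over] = 2.0 * half - x[over]
        heading[over] = np.pi - heading[over]
    if np.any(under):
        x[under] = -2.0 * half - x[under]
        heading[under] = np.pi - heading[under]

    over = y > half
    under = y < -half
    if np.any(over):
        y[over] = 2.0 * half - y[over]
        heading[over] = -heading[over]
    if np.any(under):
        y[under] = -2.0 * half - y[under]
        heading[under] = -heading[under]

    np.mod(heading, _TWO_PI, out=heading)
    return x, y, heading


# ---------------------------------------------------------------------------
# trial initialisation and simulation
# ---------------------------------------------------------------------------


def init_swarm(config: TrialConfig, rng: np.random.Generator) -> list[AgentState]:
    """Initial agent states: positions uniform in the containment region,
    headings uniform on [0, 2pi), speeds per the speed process."""
    x, y, heading, speed = _draw_initial(config, rng)
    return [AgentState(float(x[i]), float(y[i]), float(heading[i]), float(speed[i]))
            for i in range(config.n_agents)]


def _draw_initial(config: TrialConfig, rng: np.random.Generator):
    n = config.n_agents
    half = config.half_side
    x = rng.uniform(-half, half, size=n)
    y = rng.uniform(-half, half, size=n)
    heading = rng.uniform(0.0, _TWO_PI, size=n)
    sp = config.speed_process
    if sp.kind == "constant":
        speed = np.full(n, sp.mean_speed)
    else:
        speed = np.clip(
            sp.mean_speed + rng.normal(0.0, sp.increment_sd, size=n),
            sp.min_speed,
            sp.max_speed,
        )
    return x, y, heading, speed


def _draw_trial_noise(config: TrialConfig, rng: np.random.Generator):
    """Pre-draw one trial's full randomness stream.

    Draw order (fixed for reproducibility): initial states, target index,
    per-frame turn increments, per-frame speed increments (variable only).
    """
    n, n_f = config.n_agents, config.n_frames
    init = _draw_initial(config, rng)
    target = int(rng.integers(config.n_agents))
    turns = (
        rng.normal(0.0, config.turn_sd, size=(n_f, n))
        if config.turn_sd > 0
        else np.zeros((n_f, n))
    )
    sp = config.speed_process
    dspeed = (
        rng.normal(0.0, sp.increment_sd, size=(n_f, n))
        if sp.kind == "variable"
        else None
    )
    return init, target, turns, dspeed


def simulate_trial(config: TrialConfig, rng: np.random.Generator | None = None) -> Trajectory:
    """Simulate one full trial; deterministic under ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _simulate_batch(config, [rng])[0]


def simulate_trials(config: TrialConfig, seeds: Sequence[int]) -> list[Trajectory]:
    """Simulate many same-shape trials in one vectorized pass.

    Each trial's randomness comes from its own seed, so the result for a
    given seed is identical to ``simulate_trial(replace(config, seed=s))``.
    """
    rngs = [np.random.default_rng(s) for s in seeds]
    return _simulate_batch(config, rngs)


#: largest number of trials simulated in one vectorized pass (memory cap)
MAX_BATCH = 128


def _simulate_batch(config: TrialConfig, rngs: Sequence[np.random.Generator]) -> list[Trajectory]:
    if len(rngs) > MAX_BATCH:
        out: list[Trajectory] = []
        for i in range(0, len(rngs), MAX_BATCH):
            out.extend(_simulate_batch(config, rngs[i : i + MAX_BATCH]))
        return out

    B, n, n_f = len(rngs), config.n_agents, config.n_frames
    sp = config.speed_process
    dt, half = config.dt, config.half_side

    x = np.empty((B, n))
    y = np.empty((B, n))
    heading = np.empty((B, n))
    speed = np.empty((B, n))
    targets = np.empty(B, dtype=int)
    # frame-major noise/state arrays: per-frame slices are contiguous,
    # which is what keeps the 500-iteration loop memory-friendly
    turns = np.empty((n_f, B, n))
    dspeed = np.empty((n_f, B, n)) if sp.kind == "variable" else None

    for b, rng in enumerate(rngs):
        (x[b], y[b], heading[b], speed[b]), targets[b], t_b, ds_b = _draw_trial_noise(
            config, rng
        )
        turns[:, b] = t_b
        if dspeed is not None:
            dspeed[:, b] = ds_b

    X = np.empty((n_f, B, n))
    Y = np.empty((n_f, B, n))
    H = np.empty((n_f, B, n))
    S = np.empty((n_f, B, n))
    x0, y0, h0, s0 = x.copy(), y.copy(), heading.copy(), speed.copy()

    step = np.empty_like(x)
    with _gc_paused():
        for k in range(n_f):
            if dspeed is not None:
                np.add(speed, dspeed[k], out=speed)
                np.clip(speed, sp.min_speed, sp.max_speed, out=speed)
            np.add(heading, turns[k], out=heading)
            np.cos(heading, out=step)
            step *= speed
            step *= dt
            x += step
            np.sin(heading, out=step)
            step *= speed
            step *= dt
            y += step
            _reflect(x, y, heading, half, inplace=True)
            X[k] = x
            Y[k] = y
            H[k] = heading
            S[k] = speed

    times = np.arange(1, n_f + 1) * (1000.0 / config.frame_rate)
    # one-shot transposes back to (trial, frame, agent); per-trial arrays
    # are contiguous views into these
    Xc = np.ascontiguousarray(X.transpose(1, 0, 2))
    Yc = np.ascontiguousarray(Y.transpose(1, 0, 2))
    Hc = np.ascontiguousarray(H.transpose(1, 0, 2))
    Sc = np.ascontiguousarray(S.transpose(1, 0, 2))
    return [
        Trajectory(
            config=config,
            target_index=int(targets[b]),
            times_ms=times,
            x=Xc[b],
            y=Yc[b],
            heading=Hc[b],
            speed=Sc[b],
            x0=x0[b],
            y0=y0[b],
            heading0=h0[b],
            speed0=s0[b],
        )
        for b in range(B)
    ]


def trial_config_for(
    n_agents: int,
    coloration: str,
    speed_cond: str,
    seed: int = 0,
    **overrides,
) -> TrialConfig:
    """Convenience constructor from the three factor levels."""
    sp = SpeedProcess.constant() if speed_cond == "constant" else SpeedProcess.variable()
    return TrialConfig(
        n_agents=n_agents, coloration=coloration, speed_process=sp, seed=seed, **overrides
    )
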