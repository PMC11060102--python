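"""Continuous-pursuit (CP) task dynamics and session scheduling.

The CP task asks a user to steer a cursor around a square arena to track a
target that drifts under random per-tick accelerations. Both objects live in
continuous coordinates on ``[0, arena_side]^2`` (origin bottom-left, x
rightward, y upward), are updated every control tick (40 ms under all study
presets), and are clamped at the arena boundary — no wrap-around, consistent
with controlling a physical object. A repulsion acceleration pushes the
target back toward the interior when it nears an edge so it does not loiter
on the boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "KinematicState",
    "TrialRecord",
    "step_target",
    "step_cursor",
    "make_schedule",
    "get_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class TaskConfig:
    """All CP task dynamics constants plus the trial/run/session schedule.

    Speeds and accelerations are in arena units (arena side = 1) per second;
    the slow preset applies the study's printed reductions relative to the
    fast preset: cursor speed x0.75, target acceleration variance x(2/3).
    """

    tick_s: float = 0.040
    trial_s: float = 60.0
    trials_per_run: int = 5
    runs_per_session: int = 13
    arena_side: float = 1.0
    cursor_speed: float = 0.20
    target_accel_sd: float = 0.5
    target_vmax: float = 0.25
    repulsion_zone: float = 0.1
    repulsion_accel: float = 1.0
    speed_preset: str = "fast"

    def __post_init__(self) -> None:
        if self.tick_s <= 0 or self.trial_s <= 0:
            raise ValueError("tick_s and trial_s must be positive")
        if self.arena_side <= 0:
            raise ValueError("arena_side must be positive")

    @property
    def n_ticks(self) -> int:
        """Control updates per trial (positions are recorded at n_ticks+1 times)."""
        return int(round(self.trial_s / self.tick_s))

    def replace(self, **kw) -> "TaskConfig":
        return dataclasses.replace(self, **kw)


def _slow_from_fast(fast: TaskConfig) -> TaskConfig:
    # cursor speed reduced 25%, acceleration *variance* reduced 33%
    return fast.replace(
        cursor_speed=0.75 * fast.cursor_speed,
        target_accel_sd=float(np.sqrt(2.0 / 3.0)) * fast.target_accel_sd,
        speed_preset="slow",
    )


_FAST = TaskConfig()
PRESETS: dict[str, TaskConfig] = {
    "substudy1_fast": _FAST,
    # intro session: same reductions as the slow preset, used only for session T
    "substudy1_intro": _slow_from_fast(_FAST).replace(speed_preset="intro"),
    "substudy2_slow": _slow_from_fast(_FAST),
    # reduced-size preset for smoke runs and continuous integration
    "smoke": _FAST.replace(trial_s=10.0, trials_per_run=1),
}


def get_preset(name: str) -> TaskConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass
class KinematicState:
    """Position/velocity of the cursor or target, arena units."""

    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(2)

    @classmethod
    def at(cls, x: float, y: float) -> "KinematicState":
        return cls(np.array([x, y]), np.zeros(2))


@dataclass
class TrialRecord:
    """One 60 s CP trial: tick-aligned trajectories plus the EEG segment."""

    cursor_xy: np.ndarray  # (n_ticks+1, 2)
    target_xy: np.ndarray  # (n_ticks+1, 2)
    eeg: np.ndarray | None  # (channels, samples) µV, or None for EEG-free runs
    fs: float
    channel_names: list[str]
    channel_xyz: np.ndarray | None
    decoder_id: str
    condition: str  # chance | AR | EEGNet | PointNet | TL | CL | DL | oracle
    seed: int
    session_id: str = ""
    trial_id: str = ""


def _clamp_position(pos: np.ndarray, vel: np.ndarray, side: float) -> None:
    """Clamp in place; zero the normal velocity component on boundary contact."""
    for ax in range(2):
        if pos[ax] < 0.0:
            pos[ax] = 0.0
            vel[ax] = 0.0
        elif pos[ax] > side:
            pos[ax] = side
            vel[ax] = 0.0


def step_target(state: KinematicState, cfg: TaskConfig, noise: np.ndarray) -> KinematicState:
    """Advance the target one tick under random acceleration + edge repulsion.

    ``noise`` is a standard-normal 2-vector; the applied acceleration is
    ``target_accel_sd * noise`` per axis (Euler-integrated over one tick).
    Within ``repulsion_zone`` of an edge an extra acceleration of magnitude
    ``repulsion_accel`` pushes back toward the interior on that axis. Speed is
    clamped to ``target_vmax`` and the position to the arena.
    """
    noise = np.asarray(noise, dtype=float).reshape(2)
    if not np.all(np.isfinite(noise)):
        raise ValueError("non-finite acceleration noise")
    accel = cfg.target_accel_sd * noise
    pos, vel = state.position.copy(), state.velocity.copy()
    for ax in range(2):
        if pos[ax] < cfg.repulsion_zone:
            accel[ax] += cfg.repulsion_accel
        elif pos[ax] > cfg.arena_side - cfg.repulsion_zone:
            accel[ax] -= cfg.repulsion_accel
    vel = vel + accel * cfg.tick_s
    speed = float(np.hypot(*vel))
    if speed > cfg.target_vmax:
        vel *= cfg.target_vmax / speed
    pos = pos + vel * cfg.tick_s
    _clamp_position(pos, vel, cfg.arena_side)
    return KinematicState(pos, vel)


def step_cursor(state: KinematicState, control: np.ndarray, cfg: TaskConfig) -> KinematicState:
    """Advance the cursor one tick: velocity = cursor_speed * control.

    ``control`` is the decoder output, a 2-vector of magnitude <= 1 by the
    decoder normalization contract.
    """
    control = np.asarray(control, dtype=float).reshape(2)
    if not np.all(np.isfinite(control)):
        raise ValueError("non-finite control vector")
    vel = cfg.cursor_speed * control
    pos = state.position + vel * cfg.tick_s
    vel = vel.copy()
    _clamp_position(pos, vel, cfg.arena_side)
    return KinematicState(pos, vel)


# ---------------------------------------------------------------------------
# session schedules

_SUBSTUDY1_SESSIONS = ["T"] + [str(i) for i in range(1, 8)]
_SUBSTUDY2_SESSIONS = [str(i) for i in range(1, 5)]


def make_schedule(substudy: int, session_index: str | int, seed: int = 0) -> list[tuple[str, int]]:
    """Run plan for one session: an ordered list of (condition, n_runs) blocks.

    Substudy 1: sessions "T" and "1" are 12 traditional-decoder (AR) runs;
    sessions 2-7 are three 4-run blocks (AR, EEGNet, PointNet) in a seeded
    random block order. Substudy 2: session 1 is 4 AR + 4 TL + 4 CL; sessions
    2-4 are 4-run blocks of DL, TL, CL. Every session appends one chance run.
    """
    key = str(session_index)
    if substudy == 1:
        if key not in _SUBSTUDY1_SESSIONS:
            raise ValueError(f"substudy 1 has sessions {_SUBSTUDY1_SESSIONS}, got {key!r}")
        if key in ("T", "1"):
            plan = [("AR", 12)]
        else:
            blocks = [("AR", 4), ("EEGNet", 4), ("PointNet", 4)]
            order = np.random.default_rng(seed).permutation(len(blocks))
            plan = [blocks[i] for i in order]
    elif substudy == 2:
        if key not in _SUBSTUDY2_SESSIONS:
            raise ValueError(f"substudy 2 has sessions {_SUBSTUDY2_SESSIONS}, got {key!r}")
        if key == "1":
            blocks = [("AR", 4), ("TL", 4), ("CL", 4)]
        else:
            blocks = [("DL", 4), ("TL", 4), ("CL", 4)]
        order = np.random.default_rng(seed).permutation(len(blocks))
        plan = [blocks[i] for i in order]
    else:
        raise ValueError(f"unknown substudy {substudy!r}")
    plan.append(("chance", 1))
    return plan
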