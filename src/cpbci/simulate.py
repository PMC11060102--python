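"""Closed-loop trial and session simulation.

A trial couples the synthetic subject to a decoder through the task loop: at
every 40 ms tick the subject observes cursor and target, forms the intent to
move along the cursor->target direction (or rests, in chance runs), its
lagged MI activations shape the next EEG chunk, the decoder maps the chunk
to a control vector, and the cursor and target advance one tick. EEG emitted
at tick k depends only on intents up to tick k, so every decoder is causal
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labeling import DEFAULT_MIN_DISTANCE, LabeledWindow, WindowingConfig, window_dataset
from .montage import Montage
from .subject import SubjectModel, SubjectSimulator
from .task import KinematicState, TaskConfig, TrialRecord, make_schedule, step_cursor, step_target

__all__ = [
    "OracleDecoder",
    "run_trial",
    "run_run",
    "SessionRecord",
    "SessionStore",
    "simulate_session",
]


class OracleDecoder:
    """Reads the subject's lagged MI activations and inverts the control model.

    An upper bound on decoder performance: the only remaining imperfections
    are the subject's reaction lag and activation smoothing.
    """

    decoder_id = "oracle"
    kind = "oracle"
    needs_eeg = False

    def reset(self) -> None:
        pass

    def reset_trial(self) -> None:
        pass

    def step(self, chunk, aux=None) -> np.ndarray:
        a_left, a_right = aux
        return np.array([a_right - a_left, a_right + a_left - 1.0])


def run_trial(
    subject: SubjectModel,
    decoder,
    task_cfg: TaskConfig,
    montage: Montage,
    seed: int,
    fs: float = 1000.0,
    chance: bool = False,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    record_eeg: bool = True,
    condition: str | None = None,
) -> TrialRecord:
    """Simulate one closed-loop trial; returns the full TrialRecord.

    In a chance trial the subject emits rest-state EEG regardless of the
    cursor and target — the no-control baseline. ``record_eeg=False`` skips
    EEG synthesis for decoders that do not read it (the oracle).
    """
    rng = np.random.default_rng(seed)
    needs_eeg = getattr(decoder, "needs_eeg", True) or record_eeg
    sim = SubjectSimulator(subject, montage, fs=fs, tick_s=task_cfg.tick_s) if needs_eeg else None
    if sim is not None:
        sim.start_trial(task_cfg.trial_s, rng)

    cursor = KinematicState.at(task_cfg.arena_side / 2, task_cfg.arena_side / 2)
    lo, hi = 0.25 * task_cfg.arena_side, 0.75 * task_cfg.arena_side
    target = KinematicState(rng.uniform(lo, hi, 2), np.zeros(2))

    n_ticks = task_cfg.n_ticks
    cursor_xy = np.empty((n_ticks + 1, 2))
    target_xy = np.empty((n_ticks + 1, 2))
    chunks: list[np.ndarray] = []
    decoder.reset_trial()

    # lag chain for the oracle when EEG synthesis is skipped
    if sim is None:
        from .subject import mi_activations

        delay = int(round(subject.reaction_lag_s / task_cfg.tick_s))
        queue: list[np.ndarray] = [np.zeros(2)] * delay
        if subject.activation_smoothing_s > 0:
            alpha = 1.0 - np.exp(-task_cfg.tick_s / subject.activation_smoothing_s)
        else:
            alpha = 1.0
        lp = np.zeros(2)

    for k in range(n_ticks):
        cursor_xy[k] = cursor.position
        target_xy[k] = target.position
        if chance:
            intent = None
        else:
            delta = target.position - cursor.position
            dist = float(np.hypot(*delta))
            intent = delta / dist if dist >= min_distance else np.zeros(2)

        if sim is not None:
            lagged, chunk = sim.step(intent)
            chunks.append(chunk)
        else:
            act = np.zeros(2) if intent is None else mi_activations(intent).as_array()
            queue.append(act)
            delayed = queue.pop(0)
            lp = lp + alpha * (delayed - lp)
            lagged, chunk = lp, None

        control = decoder.step(chunk, aux=lagged)
        cursor = step_cursor(cursor, control, task_cfg)
        target = step_target(target, task_cfg, rng.standard_normal(2))

    cursor_xy[n_ticks] = cursor.position
    target_xy[n_ticks] = target.position
    eeg = np.concatenate(chunks, axis=1) if (chunks and record_eeg) else None
    return TrialRecord(
        cursor_xy=cursor_xy,
        target_xy=target_xy,
        eeg=eeg,
        fs=fs,
        channel_names=list(montage.names),
        channel_xyz=montage.xyz,
        decoder_id=getattr(decoder, "decoder_id", "unknown"),
        condition=condition or ("chance" if chance else getattr(decoder, "decoder_id", "run")),
        seed=seed,
    )


def run_run(
    subject: SubjectModel,
    decoder,
    task_cfg: TaskConfig,
    montage: Montage,
    seed: int,
    fs: float = 1000.0,
    chance: bool = False,
    condition: str | None = None,
    record_eeg: bool = True,
) -> list[TrialRecord]:
    """One run = trials_per_run consecutive trials with a shared decoder state."""
    decoder.reset()
    seeds = np.random.SeedSequence(seed).generate_state(task_cfg.trials_per_run)
    out = []
    for i, s in enumerate(seeds):
        rec = run_trial(
            subject, decoder, task_cfg, montage, int(s % (2**31)), fs=fs, chance=chance,
            condition=condition, record_eeg=record_eeg,
        )
        rec.trial_id = f"t{i}"
        out.append(rec)
    return out


@dataclass
class SessionRecord:
    """All trials of one session plus the realized schedule."""

    session_id: str
    schedule: list[tuple[str, int]]
    trials: list[TrialRecord] = field(default_factory=list)

    def labeled_windows(self, cfg: WindowingConfig) -> list[LabeledWindow]:
        """Windows from all decoder-controlled (non-chance) trials with EEG."""
        out: list[LabeledWindow] = []
        for t in self.trials:
            if t.condition == "chance" or t.eeg is None:
                continue
            for w in window_dataset(t, cfg):
                w.session_id = self.session_id
                out.append(w)
        return out


@dataclass
class SessionStore:
    """Per-subject collection of recorded sessions, in temporal order."""

    subject_id: str = "S1"
    sessions: list[SessionRecord] = field(default_factory=list)

    def add(self, session: SessionRecord) -> None:
        self.sessions.append(session)


def simulate_session(
    subject: SubjectModel,
    decoders: dict[str, object],
    task_cfg: TaskConfig,
    montage: Montage,
    substudy: int,
    session_index: str | int,
    seed: int,
    fs: float = 1000.0,
    chance_decoder_key: str | None = None,
) -> SessionRecord:
    """Run one session following the study schedule.

    ``decoders`` maps condition labels ("AR", "EEGNet", ...) to streaming
    decoder objects; the chance run reuses ``chance_decoder_key`` (default:
    the first scheduled condition) with the subject at rest.
    """
    schedule = make_schedule(substudy, session_index, seed=seed)
    rec = SessionRecord(session_id=str(session_index), schedule=schedule)
    ss = np.random.SeedSequence(seed)
    run_seeds = iter(ss.generate_state(sum(n for _, n in schedule)).tolist())
    for condition, n_runs in schedule:
        for _ in range(n_runs):
            rseed = int(next(run_seeds) % (2**31))
            if condition == "chance":
                key = chance_decoder_key or schedule[0][0]
                trials = run_run(
                    subject, decoders[key], task_cfg, montage, rseed, fs=fs,
                    chance=True, condition="chance",
                )
            else:
                trials = run_run(
                    subject, decoders[condition], task_cfg, montage, rseed, fs=fs,
                    condition=condition,
                )
            for t in trials:
                t.session_id = rec.session_id
            rec.trials.extend(trials)
    return rec
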