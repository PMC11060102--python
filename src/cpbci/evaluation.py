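"""Performance metrics and analyses for continuous-pursuit trials.

NMSE: mean squared cursor-target distance normalized by the squared arena
diagonal, so 0 means the cursor sits on the target all trial and 1 means
they occupy opposite corners. Axis correlation: Pearson r between cursor and
target coordinates per axis. ADA (average difference angle): mean angle in
degrees between predicted direction vectors and cursor->target labels; 90
degrees is the uniform-random chance level. The lag-scan shifts the cursor
trajectory forward in time against the target to estimate the closed-loop
response delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrialMetrics",
    "LagProfile",
    "nmse",
    "axis_correlation",
    "ada",
    "lag_scan",
    "trial_metrics",
    "chance_runs",
    "metric_relationship",
]


@dataclass
class TrialMetrics:
    nmse: float
    r_horizontal: float | None
    r_vertical: float | None
    ada_deg: float | None = None
    best_lag_s: float | None = None
    nmse_at_best_lag: float | None = None
    condition: str = ""
    trial_id: str = ""
    session_id: str = ""


@dataclass
class LagProfile:
    lags_s: np.ndarray
    nmse_per_lag: np.ndarray
    best_lag_s: float
    nmse_at_best_lag: float


def nmse(cursor_xy: np.ndarray, target_xy: np.ndarray, arena_side: float = 1.0) -> float:
    """Normalized mean squared cursor-target error in [0, 1]."""
    c = np.asarray(cursor_xy, dtype=float)
    t = np.asarray(target_xy, dtype=float)
    if c.shape != t.shape:
        raise ValueError("trajectory length mismatch")
    sq = ((c - t) ** 2).sum(axis=1)
    return float(sq.mean() / (2.0 * arena_side**2))


def axis_correlation(
    cursor_xy: np.ndarray, target_xy: np.ndarray
) -> tuple[float | None, float | None]:
    """Per-axis Pearson r between cursor and target positions.

    A constant trajectory on an axis makes the coefficient undefined; it is
    reported as None (missing), never as 0.
    """
    c = np.asarray(cursor_xy, dtype=float)
    t = np.asarray(target_xy, dtype=float)
    out = []
    for ax in range(2):
        if np.std(c[:, ax]) < 1e-12 or np.std(t[:, ax]) < 1e-12:
            out.append(None)
        else:
            out.append(float(stats.pearsonr(c[:, ax], t[:, ax]).statistic))
    return out[0], out[1]


def ada(
    predictions: np.ndarray, labels: np.ndarray, return_excluded: bool = False
) -> float | tuple[float, int]:
    """Average difference angle (degrees) between predictions and unit labels.

    Zero-norm predictions are excluded; their count is available via
    ``return_excluded``. Raises if every prediction is zero.
    """
    p = np.asarray(predictions, dtype=float)
    l = np.asarray(labels, dtype=float)
    if p.shape != l.shape:
        raise ValueError("predictions and labels must be paired")
    norms = np.sqrt((p**2).sum(axis=1))
    keep = norms > 1e-12
    n_excluded = int((~keep).sum())
    if not np.any(keep):
        raise ValueError("all predictions have zero norm")
    phat = p[keep] / norms[keep, None]
    cos = np.clip((phat * l[keep]).sum(axis=1), -1.0, 1.0)
    value = float(np.degrees(np.arccos(cos)).mean())
    return (value, n_excluded) if return_excluded else value


def lag_scan(
    cursor_xy: np.ndarray,
    target_xy: np.ndarray,
    max_lag_s: float = 4.0,
    arena_side: float = 1.0,
    tick_s: float = 0.040,
) -> LagProfile:
    """NMSE as a function of forward cursor time shift; argmin = best lag.

    At lag L the cursor at time t+L is compared with the target at time t
    over the overlapping part of the trial; ties go to the smallest lag.
    """
    c = np.asarray(cursor_xy, dtype=float)
    t = np.asarray(target_xy, dtype=float)
    n = c.shape[0]
    max_shift = int(round(max_lag_s / tick_s))
    if max_shift >= n // 2:
        raise ValueError("max_lag_s must be below half the trial length")
    lags = np.arange(max_shift + 1) * tick_s
    values = np.empty(max_shift + 1)
    for s in range(max_shift + 1):
        values[s] = nmse(c[s:], t[: n - s], arena_side)
    best = int(np.argmin(values))
    return LagProfile(
        lags_s=lags,
        nmse_per_lag=values,
        best_lag_s=float(lags[best]),
        nmse_at_best_lag=float(values[best]),
    )


def trial_metrics(
    trial,
    arena_side: float = 1.0,
    max_lag_s: float = 4.0,
    with_lag: bool = True,
) -> TrialMetrics:
    """All trajectory metrics of one TrialRecord."""
    value = nmse(trial.cursor_xy, trial.target_xy, arena_side)
    r_h, r_v = axis_correlation(trial.cursor_xy, trial.target_xy)
    best_lag = nmse_best = None
    if with_lag:
        prof = lag_scan(trial.cursor_xy, trial.target_xy, max_lag_s, arena_side)
        best_lag, nmse_best = prof.best_lag_s, prof.nmse_at_best_lag
    return TrialMetrics(
        nmse=value,
        r_horizontal=r_h,
        r_vertical=r_v,
        best_lag_s=best_lag,
        nmse_at_best_lag=nmse_best,
        condition=trial.condition,
        trial_id=trial.trial_id,
        session_id=trial.session_id,
    )


def chance_runs(
    decoder,
    subject,
    task_cfg,
    montage,
    n_trials: int,
    seed: int,
    fs: float = 1000.0,
    with_lag: bool = False,
) -> list[TrialMetrics]:
    """Closed-loop no-intent trials: the chance-level baseline distribution."""
    from .simulate import run_trial

    seeds = np.random.SeedSequence(seed).generate_state(n_trials)
    out = []
    for s in seeds:
        decoder.reset()
        rec = run_trial(
            subject, decoder, task_cfg, montage, int(s % (2**31)), fs=fs,
            chance=True, record_eeg=False, condition="chance",
        )
        out.append(trial_metrics(rec, task_cfg.arena_side, with_lag=with_lag))
    return out


@dataclass
class MetricRelationship:
    r: float
    slope: float
    intercept: float
    n: int
    reliable: bool


def metric_relationship(trials: list[TrialMetrics]) -> MetricRelationship:
    """Trial-level correlation and linear fit of ADA against NMSE."""
    pairs = [(t.ada_deg, t.nmse) for t in trials if t.ada_deg is not None]
    if len(pairs) < 2:
        raise ValueError("need at least two trials with both metrics")
    x = np.array([p[1] for p in pairs])  # nmse
    y = np.array([p[0] for p in pairs])  # ada
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise ValueError("degenerate variance in metric values")
    fit = stats.linregress(x, y)
    return MetricRelationship(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(pairs),
        reliable=len(pairs) >= 10,
    )
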