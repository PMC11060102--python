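"""Generative model of a motor-imagery (MI) EEG user.

The simulated user follows the four-command MI paradigm: imagine the left
hand to go left, the right hand to go right, both hands to go up, rest to go
down. Intended 2D directions are blended continuously through the additive
control model

    h = a_R - a_L,    v = a_R + a_L - 1,

where ``a_L, a_R`` in [0, 1] are left/right-hand MI intensities. The
intensities pass through a reaction delay and a first-order low-pass
(modeling how quickly the user can change their imagery), and then drive
event-related desynchronization (ERD): a multiplicative suppression of the
alpha-band (8-13 Hz) oscillation over the contralateral sensorimotor cortex
(right-hand MI suppresses around C3, left-hand around C4), on top of
additive 1/f background noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .montage import Montage

__all__ = [
    "SubjectModel",
    "MIActivation",
    "mi_activations",
    "apply_reaction_lag",
    "erd_gain_profile",
    "generate_eeg",
    "pink_noise",
    "SubjectSimulator",
    "session_variant",
]


@dataclass(frozen=True)
class SubjectModel:
    """Parameters of the synthetic MI user.

    reaction_lag_s: pure delay between a change in intent and the MI response.
    activation_smoothing_s: first-order low-pass time constant on activations.
    erd_depth: fractional alpha suppression at full MI (0 = none, 1 = total).
    spatial_sigma: Gaussian spread (radians of arc) of ERD around C3/C4.
    """

    reaction_lag_s: float = 0.6
    activation_smoothing_s: float = 0.3
    erd_depth: float = 0.5
    alpha_freq_hz: float = 10.0
    alpha_amp_uV: float = 10.0
    noise_exponent: float = 1.0
    noise_amp_uV: float = 8.0
    spatial_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.reaction_lag_s < 0:
            raise ValueError("reaction_lag_s must be >= 0")

    def replace(self, **kw) -> "SubjectModel":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MIActivation:
    a_left: float
    a_right: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_left", float(np.clip(self.a_left, 0.0, 1.0)))
        object.__setattr__(self, "a_right", float(np.clip(self.a_right, 0.0, 1.0)))

    def as_array(self) -> np.ndarray:
        return np.array([self.a_left, self.a_right])


def mi_activations(direction: np.ndarray) -> MIActivation:
    """Invert the additive control model for an intended unit direction.

    ``a_R = clip((h + v + 1)/2)``, ``a_L = clip((v - h + 1)/2)``: pure right
    maps to right-hand MI only, up to both hands, down to rest. The zero
    vector (cursor on target) maps to the neutral hover (0.5, 0.5).
    """
    d = np.asarray(direction, dtype=float).reshape(2)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite direction")
    h, v = d
    return MIActivation(a_left=(v - h + 1.0) / 2.0, a_right=(h + v + 1.0) / 2.0)


def apply_reaction_lag(
    activations: np.ndarray, model: SubjectModel, tick_s: float = 0.040
) -> np.ndarray:
    """Delay + first-order smoothing of an (n, 2) activation series.

    The first ``reaction_lag_s`` seconds hold the rest state (0, 0); the
    low-pass uses the exact exponential step response for the tick length.
    """
    x = np.asarray(activations, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0 or x.shape[1] != 2:
        raise ValueError("activations must be a non-empty (n, 2) series")
    delay = int(round(model.reaction_lag_s / tick_s))
    delayed = np.zeros_like(x)
    if delay < x.shape[0]:
        delayed[delay:] = x[: x.shape[0] - delay]
    if model.activation_smoothing_s <= 0:
        return delayed
    alpha = 1.0 - np.exp(-tick_s / model.activation_smoothing_s)
    out = np.empty_like(delayed)
    state = np.zeros(2)
    for i in range(delayed.shape[0]):
        state = state + alpha * (delayed[i] - state)
        out[i] = state
    return out


def erd_gain_profile(montage: Montage, model: SubjectModel) -> np.ndarray:
    """Per-channel ERD gains, one column per seed electrode: (n_channels, 2).

    Column 0 is the C3-centered kernel (driven by right-hand MI), column 1
    the C4-centered kernel (left-hand MI); Gaussian in great-circle distance
    with peak 1 at the seed electrode.
    """
    d3 = montage.great_circle_to("C3")
    d4 = montage.great_circle_to("C4")
    s2 = 2.0 * model.spatial_sigma**2
    return np.stack([np.exp(-d3**2 / s2), np.exp(-d4**2 / s2)], axis=1)


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _alpha_envelope(
    lagged: np.ndarray, gains: np.ndarray, erd_depth: float, samples_per_tick: int, n_samples: int
) -> np.ndarray:
    """(channels, samples) multiplicative envelope from lagged activations."""
    a_left = np.repeat(lagged[:, 0], samples_per_tick)[:n_samples]
    a_right = np.repeat(lagged[:, 1], samples_per_tick)[:n_samples]
    # gains[:, 0] is C3-seeded (right hand), gains[:, 1] C4-seeded (left hand)
    suppression = gains[:, [0]] * a_right[None, :] + gains[:, [1]] * a_left[None, :]
    return 1.0 - erd_depth * np.clip(suppression, 0.0, 1.0)


def generate_eeg(
    lagged_activations: np.ndarray,
    model: SubjectModel,
    montage: Montage,
    fs: float,
    duration_s: float,
    rng: np.random.Generator | None = None,
    tick_s: float = 0.040,
) -> np.ndarray:
    """Synthesize (channels, samples) EEG in µV from lagged MI activations.

    Per channel: ``alpha_amp * A_c(t) * sin(2*pi*f*t + phi_c)`` plus pink
    noise of std ``noise_amp``; the envelope ``A_c`` applies the ERD gains to
    the activations, held piecewise-constant over each control tick.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n_samples = int(round(duration_s * fs))
    spt = int(round(tick_s * fs))
    lagged = np.asarray(lagged_activations, dtype=float)
    if lagged.shape[0] * spt < n_samples:
        raise ValueError("activation series does not cover the requested duration")
    gains = erd_gain_profile(montage, model)
    env = _alpha_envelope(lagged, gains, model.erd_depth, spt, n_samples)
    t = np.arange(n_samples) / fs
    phases = rng.uniform(0.0, 2.0 * np.pi, montage.n_channels)
    carrier = np.sin(2.0 * np.pi * model.alpha_freq_hz * t[None, :] + phases[:, None])
    noise = np.stack(
        [pink_noise(n_samples, model.noise_exponent, rng) for _ in range(montage.n_channels)]
    )
    return model.alpha_amp_uV * env * carrier + model.noise_amp_uV * noise


def session_variant(
    model: SubjectModel,
    rng: np.random.Generator,
    depth_shift_sd: float = 0.15,
    freq_jitter_sd_hz: float = 0.75,
) -> SubjectModel:
    """Session-specific perturbation of the subject: intersession variability.

    The ERD depth receives an additive Gaussian shift (clipped to [0.05, 1])
    and the alpha peak frequency a small jitter — day-to-day changes in
    responsiveness and rhythm frequency that decoders trained on earlier
    sessions must cope with.
    """
    depth = float(np.clip(model.erd_depth + depth_shift_sd * rng.standard_normal(), 0.05, 1.0))
    freq = float(model.alpha_freq_hz + freq_jitter_sd_hz * rng.standard_normal())
    return model.replace(erd_depth=depth, alpha_freq_hz=freq)


class SubjectSimulator:
    """Tick-by-tick subject for closed-loop trials.

    The alpha carrier and the pink-noise background for a whole trial are
    precomputed at ``start_trial``; intent arrives one tick at a time, passes
    through the delay/low-pass chain, and shapes the alpha envelope of the
    next 40 ms EEG chunk. This keeps the loop causal: the EEG emitted at tick
    k depends only on intents at ticks <= k.
    """

    def __init__(
        self,
        model: SubjectModel,
        montage: Montage,
        fs: float = 1000.0,
        tick_s: float = 0.040,
    ) -> None:
        self.model = model
        self.montage = montage
        self.fs = float(fs)
        self.tick_s = float(tick_s)
        self.samples_per_tick = int(round(tick_s * fs))
        if abs(self.samples_per_tick - tick_s * fs) > 1e-9:
            raise ValueError("tick_s must be an integer number of samples")
        self.gains = erd_gain_profile(montage, model)
        self._delay_ticks = int(round(model.reaction_lag_s / tick_s))
        if model.activation_smoothing_s > 0:
            self._alpha = 1.0 - np.exp(-tick_s / model.activation_smoothing_s)
        else:
            self._alpha = 1.0

    def start_trial(self, duration_s: float, rng: np.random.Generator) -> None:
        n = int(round(duration_s * self.fs))
        t = np.arange(n) / self.fs
        phases = rng.uniform(0.0, 2.0 * np.pi, self.montage.n_channels)
        self._carrier = np.sin(
            2.0 * np.pi * self.model.alpha_freq_hz * t[None, :] + phases[:, None]
        )
        self._noise = self.model.noise_amp_uV * np.stack(
            [pink_noise(n, self.model.noise_exponent, rng) for _ in range(self.montage.n_channels)]
        )
        self._tick = 0
        self._queue: list[np.ndarray] = [np.zeros(2)] * self._delay_ticks
        self._lp = np.zeros(2)

    def step(self, intent: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Advance one tick; returns (lagged activation (2,), EEG chunk).

        ``intent`` is the desired unit direction, or None for a no-intent
        (chance) tick in which the subject rests.
        """
        if intent is None:
            act = np.zeros(2)
        else:
            act = mi_activations(intent).as_array()
        self._queue.append(act)
        delayed = self._queue.pop(0)
        self._lp = self._lp + self._alpha * (delayed - self._lp)
        lagged = self._lp.copy()

        s0 = self._tick * self.samples_per_tick
        s1 = s0 + self.samples_per_tick
        suppression = self.gains[:, 0] * lagged[1] + self.gains[:, 1] * lagged[0]
        env = 1.0 - self.model.erd_depth * np.clip(suppression, 0.0, 1.0)
        chunk = (
            self.model.alpha_amp_uV * env[:, None] * self._carrier[:, s0:s1]
            + self._noise[:, s0:s1]
        )
        self._tick += 1
        return lagged, chunk
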