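"""Traditional autoregressive-spectral baseline decoder.

Alpha-band (8-13 Hz) power at the lateralized sensorimotor electrodes C3 and
C4 is estimated every control tick from a short trailing buffer with a Burg
maximum-entropy AR model, mapped linearly to two axes —

    raw_h = P(C4) - P(C3)        (right-hand MI suppresses C3 -> move right)
    raw_v = -(P(C3) + P(C4))     (bimanual MI suppresses both -> move up)

— and normalized to zero mean / unit variance per axis by exponentially
weighted running statistics, so the decoder needs no training data. The
output is clipped to the unit disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ARConfig",
    "NormalizerState",
    "burg",
    "ar_psd",
    "ar_band_power",
    "ar_control",
    "ARDecoder",
]


@dataclass(frozen=True)
class ARConfig:
    model_order: int = 16
    buffer_s: float = 0.5
    band: tuple[float, float] = (8.0, 13.0)
    control_channels: tuple[str, str] = ("C3", "C4")
    normalizer_halflife_s: float = 30.0
    warmup_s: float = 2.0
    tick_s: float = 0.040
    gain: float = 1.0


def burg(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg AR fit: returns (a, sigma2) with model x[n] = -sum a_k x[n-k] + e.

    ``a`` has length ``order``; ``sigma2`` is the driving-noise variance.
    Degenerate (near-constant) input returns zero coefficients and variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * order:
        raise ValueError("window must be at least twice the model order")
    e = float(np.dot(x, x)) / n
    if e < 1e-30:
        return np.zeros(order), 0.0
    a = np.zeros(0)
    f = x[1:].copy()  # forward errors f_k[n]
    b = x[:-1].copy()  # backward errors b_k[n-1]
    for _ in range(order):
        denom = float(np.dot(f, f) + np.dot(b, b))
        if denom < 1e-30:
            a = np.concatenate([a, np.zeros(order - a.size)])
            break
        k = -2.0 * float(np.dot(b, f)) / denom
        a = np.concatenate([a + k * a[::-1], [k]])
        e *= 1.0 - k * k
        f, b = f + k * b, b + k * f
        # shrink: the recursion loses one lag each stage
        f, b = f[1:], b[:-1]
    if a.size < order:
        a = np.concatenate([a, np.zeros(order - a.size)])
    return a, max(e, 0.0)


def ar_psd(a: np.ndarray, sigma2: float, fs: float, freqs: np.ndarray) -> np.ndarray:
    """One-sided AR power spectral density (µV²/Hz) at the given frequencies."""
    k = np.arange(1, a.size + 1)
    z = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    denom = np.abs(1.0 + z @ a) ** 2
    denom[denom < 1e-30] = 1e-30
    return 2.0 * sigma2 / (fs * denom)


def ar_band_power(
    window: np.ndarray,
    fs: float,
    order: int = 16,
    band: tuple[float, float] = (8.0, 13.0),
    df: float = 0.25,
) -> float:
    """Band-integrated AR spectral power (µV²) of one channel window."""
    if band[1] >= fs / 2:
        raise ValueError("band must lie below the Nyquist frequency")
    a, sigma2 = burg(window, order)
    if sigma2 == 0.0:
        return 0.0
    freqs = np.arange(band[0], band[1] + df / 2, df)
    return float(np.trapezoid(ar_psd(a, sigma2, fs, freqs), freqs))


@dataclass
class NormalizerState:
    """Exponentially weighted running mean/variance per output axis."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    var: np.ndarray = field(default_factory=lambda: np.ones(2))
    n_updates: int = 0

    def update(self, raw: np.ndarray, decay: float) -> None:
        if self.n_updates == 0:
            self.mean = raw.astype(float).copy()
            self.var = np.ones(2)
        else:
            self.mean = decay * self.mean + (1.0 - decay) * raw
            dev = raw - self.mean
            self.var = decay * self.var + (1.0 - decay) * dev * dev
        self.n_updates += 1

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        sd = np.sqrt(np.maximum(self.var, 1e-12))
        return (raw - self.mean) / sd


def ar_control(
    p_c3: float, p_c4: float, state: NormalizerState, cfg: ARConfig
) -> tuple[np.ndarray, NormalizerState]:
    """Map C3/C4 band powers to a clipped 2D control vector; update normalizer.

    Powers enter on a log scale: band power is heavily right-skewed, and
    z-scoring the raw values biases the vertical axis (most samples sit
    below the running mean); log power is close to Gaussian.
    """
    l3 = np.log(max(p_c3, 0.0) + 1e-12)
    l4 = np.log(max(p_c4, 0.0) + 1e-12)
    raw = np.array([l4 - l3, -(l3 + l4)])
    decay = 0.5 ** (cfg.tick_s / cfg.normalizer_halflife_s)
    state.update(raw, decay)
    warm_ticks = int(round(cfg.warmup_s / cfg.tick_s))
    if state.n_updates <= warm_ticks:
        return np.zeros(2), state
    out = cfg.gain * state.normalize(raw)
    norm = float(np.hypot(*out))
    if norm > 1.0:
        out = out / norm
    return out, state


class ARDecoder:
    """Streaming AR decoder: feed 40 ms chunks, get a control vector per tick."""

    decoder_id = "AR"
    kind = "ar"

    def __init__(self, channel_names: list[str], fs: float, cfg: ARConfig | None = None):
        self.cfg = cfg or ARConfig()
        self.fs = float(fs)
        self.channel_names = list(channel_names)
        self._idx = [self.channel_names.index(c) for c in self.cfg.control_channels]
        self._buf_n = int(round(self.cfg.buffer_s * fs))
        self.reset()

    def reset(self) -> None:
        self.state = NormalizerState()
        self._last = np.zeros(2)
        self.reset_trial()

    def reset_trial(self) -> None:
        """Start a new trial: clear the signal buffer and hold zeros briefly.

        The adaptive normalizer persists across trials within a run, but the
        output is held at zero for the first ``warmup_s`` of every trial
        while the buffer and the running statistics settle.
        """
        self._buffer = np.zeros((len(self.channel_names), 0))
        self._warm_hold = int(round(self.cfg.warmup_s / self.cfg.tick_s))

    def step(self, chunk: np.ndarray, aux=None) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=float)
        if chunk.size == 0 or not np.all(np.isfinite(chunk)):
            return self._last  # stream gap: hold the previous output
        self._buffer = np.concatenate([self._buffer, chunk], axis=1)[:, -self._buf_n :]
        if self._buffer.shape[1] < max(2 * self.cfg.model_order, self._buf_n):
            return np.zeros(2)
        i3, i4 = self._idx
        p3 = ar_band_power(self._buffer[i3], self.fs, self.cfg.model_order, self.cfg.band)
        p4 = ar_band_power(self._buffer[i4], self.fs, self.cfg.model_order, self.cfg.band)
        out, self.state = ar_control(p3, p4, self.state, self.cfg)
        if self._warm_hold > 0:
            self._warm_hold -= 1
            out = np.zeros(2)
        self._last = out
        return out
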