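"""Cursor->target labeling of continuous-pursuit EEG for supervised learning.

A continuous tracking trial has no single per-trial target, so supervised
learning needs a per-moment label: the unit vector from the cursor position
to the target position — the optimal instantaneous movement direction.
Continuous EEG is cut into fixed-length windows ending on control ticks, each
paired with the label at its end tick (causal: only past EEG enters a
window). Windows where cursor and target nearly coincide are excluded (the
direction is numerically undefined at contact), as are windows overlapping
the reaction-lag warm-up at the start of the trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .task import TrialRecord

__all__ = [
    "LabeledWindow",
    "WindowingConfig",
    "compute_label",
    "window_dataset",
    "preprocess_for",
    "spectrum_freqs",
]

DEFAULT_MIN_DISTANCE = 0.02


@dataclass
class LabeledWindow:
    eeg_window: np.ndarray  # (channels, window_samples)
    label: np.ndarray  # unit 2-vector
    t_end: float
    trial_id: str = ""
    session_id: str = ""
    subject_id: str = ""


@dataclass(frozen=True)
class WindowingConfig:
    window_s: float = 1.0
    stride_s: float = 0.2
    min_distance: float = DEFAULT_MIN_DISTANCE
    warmup_s: float = 1.0
    preprocessing: str = "raw_downsampled"  # or "band_spectrum"
    tick_s: float = 0.040

    def __post_init__(self) -> None:
        ratio = self.stride_s / self.tick_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("stride_s must be a multiple of tick_s")


def compute_label(
    cursor: np.ndarray, target: np.ndarray, min_distance: float = DEFAULT_MIN_DISTANCE
) -> np.ndarray | None:
    """Unit cursor->target vector, or None (excluded) when nearly coincident."""
    cursor = np.asarray(cursor, dtype=float).reshape(2)
    target = np.asarray(target, dtype=float).reshape(2)
    delta = target - cursor
    dist = float(np.hypot(*delta))
    if dist < min_distance:
        return None
    return delta / dist


def window_dataset(trial: TrialRecord, cfg: WindowingConfig) -> list[LabeledWindow]:
    """Cut one trial into labeled windows, one per stride, ending on ticks."""
    if trial.eeg is None:
        raise ValueError("trial has no EEG; cannot window")
    fs = trial.fs
    n_samples = trial.eeg.shape[1]
    trial_s = n_samples / fs
    if cfg.window_s > trial_s:
        raise ValueError("window longer than trial")
    win_n = int(round(cfg.window_s * fs))
    out: list[LabeledWindow] = []
    # windows start at or after warmup_s and end at or before trial end
    first_end = cfg.warmup_s + cfg.window_s
    n_windows = int(np.floor((trial_s - first_end) / cfg.stride_s + 1e-9)) + 1
    for k in range(max(n_windows, 0)):
        t_end = first_end + k * cfg.stride_s
        end_sample = int(round(t_end * fs))
        tick_idx = int(round(t_end / cfg.tick_s))
        label = compute_label(
            trial.cursor_xy[tick_idx], trial.target_xy[tick_idx], cfg.min_distance
        )
        if label is not None:
            out.append(
                LabeledWindow(
                    eeg_window=trial.eeg[:, end_sample - win_n : end_sample],
                    label=label,
                    t_end=round(t_end, 9),
                    trial_id=trial.trial_id,
                    session_id=trial.session_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# per-decoder preprocessing

_BAND = (4.0, 40.0)
_TARGET_FS = 125.0
_SPEC_RES_HZ = 1.0


def spectrum_freqs(fs: float, window_n: int) -> np.ndarray:
    """Frequency bins of the band_spectrum features for a given window."""
    nperseg = min(window_n, int(round(fs / _SPEC_RES_HZ)))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    mask = (freqs >= _BAND[0]) & (freqs <= _BAND[1])
    return freqs[mask]


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(4, _BAND, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def preprocess_for(decoder_kind: str, eeg_window: np.ndarray, fs: float, montage_xyz=None):
    """Turn one raw EEG window into the feature tensor a decoder consumes.

    ``raw_downsampled`` (EEGNet-style): band-pass 4-40 Hz, decimate to
    125 Hz, per-channel z-score over the window -> (channels, samples).
    ``band_spectrum`` (PointNet-style): per-channel log amplitude spectrum on
    4-40 Hz (Welch, ~1 Hz resolution), concatenated with the electrode xyz ->
    (n_points, 3 + n_freq) point cloud.
    """
    x = np.asarray(eeg_window, dtype=float)
    if x.ndim != 2:
        raise ValueError("eeg_window must be (channels, samples)")
    if decoder_kind == "raw_downsampled":
        factor = fs / _TARGET_FS
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(f"fs={fs} is not an integer multiple of {_TARGET_FS} Hz")
        y = _bandpass(x, fs)[:, :: int(round(factor))]
        mu = y.mean(axis=1, keepdims=True)
        sd = y.std(axis=1, keepdims=True)
        sd[sd < 1e-12] = 1.0
        return (y - mu) / sd
    if decoder_kind == "band_spectrum":
        nperseg = min(x.shape[1], int(round(fs / _SPEC_RES_HZ)))
        freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg, axis=-1)
        mask = (freqs >= _BAND[0]) & (freqs <= _BAND[1])
        spec = np.log10(np.sqrt(psd[:, mask]) + 1e-12)
        if montage_xyz is None:
            raise ValueError("band_spectrum features need montage_xyz")
        xyz = np.asarray(montage_xyz, dtype=float)
        if xyz.shape != (x.shape[0], 3):
            raise ValueError("montage_xyz must be (channels, 3)")
        return np.concatenate([xyz, spec], axis=1)
    raise ValueError(f"unknown decoder_kind {decoder_kind!r}")
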