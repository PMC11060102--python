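"""Electrode montages: names plus unit-sphere 3D coordinates.

The default 64-channel montage is the standard extended 10/20 layout (via
mne's ``biosemi64`` template), with every electrode position projected onto
the unit sphere so great-circle distances are plain arc angles. A plain-text
loader accepts user montages as whitespace-delimited ``name x y z`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "default_montage", "load_montage", "reduced_montage"]


@dataclass(frozen=True)
class Montage:
    names: tuple[str, ...]
    xyz: np.ndarray  # (n_channels, 3), unit norm rows

    def __post_init__(self) -> None:
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        if self.xyz.shape != (len(self.names), 3):
            raise ValueError("xyz must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def great_circle_to(self, name: str) -> np.ndarray:
        """Arc distance (radians) from every electrode to the named one."""
        ref = self.xyz[self.index(name)]
        cosang = np.clip(self.xyz @ ref, -1.0, 1.0)
        return np.arccos(cosang)

    def subset(self, names: list[str]) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(names), self.xyz[idx])

    def permuted(self, order: np.ndarray) -> "Montage":
        order = np.asarray(order)
        return Montage(tuple(self.names[i] for i in order), self.xyz[order])


_DEFAULT: Montage | None = None


def default_montage() -> Montage:
    """The packaged 64-channel extended 10/20 montage (unit sphere)."""
    global _DEFAULT
    if _DEFAULT is None:
        import mne

        std = mne.channels.make_standard_montage("biosemi64")
        pos = std.get_positions()["ch_pos"]
        names = tuple(std.ch_names)
        xyz = np.array([pos[n] for n in names], dtype=float)
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        _DEFAULT = Montage(names, xyz)
    return _DEFAULT


# A left/right-balanced 16-channel subset covering the sensorimotor strip,
# used by the reduced-size presets.
_REDUCED_16 = [
    "F3", "Fz", "F4",
    "FC3", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP4",
    "P3", "P4",
]


def reduced_montage(n: int = 16) -> Montage:
    """A small sensorimotor-centered montage subset for fast simulations."""
    if n == 16:
        return default_montage().subset(_REDUCED_16)
    if n == 64:
        return default_montage()
    raise ValueError("reduced montages are defined for n in {16, 64}")


def load_montage(path) -> Montage:
    """Read a plain-text montage: one ``name x y z`` row per electrode."""
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"montage rows need 4 fields, got {line!r}")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    xyz = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(xyz, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm electrode position")
    return Montage(tuple(names), xyz / norms)
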