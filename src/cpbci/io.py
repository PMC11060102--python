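"""Session containers (HDF5) and plain-text configuration files.

One file per session: ``/meta`` holds the config snapshot, seed and realized
schedule; ``/montage`` the channel names and unit-sphere coordinates (stored
once); ``/trials/<k>`` each trial's EEG, trajectories and, optionally, the
cursor->target labels at every tick.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import yaml

from .labeling import compute_label
from .montage import Montage
from .simulate import SessionRecord
from .task import TaskConfig, TrialRecord

__all__ = ["save_session", "load_session", "load_config", "dump_config"]


def save_session(
    session: SessionRecord,
    montage: Montage,
    task_cfg: TaskConfig,
    path,
    seed: int | None = None,
    with_labels: bool = True,
) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["config"] = json.dumps(dataclasses.asdict(task_cfg))
        meta.attrs["schedule"] = json.dumps(session.schedule)
        meta.attrs["session_id"] = session.session_id
        if seed is not None:
            meta.attrs["seed"] = seed
        mg = f.create_group("montage")
        mg.create_dataset("names", data=np.array(montage.names, dtype="S"))
        mg.create_dataset("xyz", data=montage.xyz)
        trials = f.create_group("trials")
        for k, t in enumerate(session.trials):
            g = trials.create_group(f"{k:03d}")
            g.create_dataset("cursor_xy", data=t.cursor_xy)
            g.create_dataset("target_xy", data=t.target_xy)
            if t.eeg is not None:
                g.create_dataset("eeg", data=t.eeg.astype(np.float32))
            g.attrs["fs"] = t.fs
            g.attrs["condition"] = t.condition
            g.attrs["decoder_id"] = t.decoder_id
            g.attrs["seed"] = t.seed
            g.attrs["trial_id"] = t.trial_id
            if with_labels:
                labels = np.full((t.cursor_xy.shape[0], 2), np.nan)
                for i in range(t.cursor_xy.shape[0]):
                    lab = compute_label(t.cursor_xy[i], t.target_xy[i])
                    if lab is not None:
                        labels[i] = lab
                g.create_dataset("labels", data=labels)


def load_session(path) -> tuple[SessionRecord, Montage, TaskConfig]:
    with h5py.File(path, "r") as f:
        cfg = TaskConfig(**json.loads(f["meta"].attrs["config"]))
        schedule = [tuple(x) for x in json.loads(f["meta"].attrs["schedule"])]
        session = SessionRecord(
            session_id=str(f["meta"].attrs["session_id"]), schedule=schedule
        )
        names = tuple(n.decode() for n in f["montage/names"][()])
        montage = Montage(names, f["montage/xyz"][()])
        for key in sorted(f["trials"]):
            g = f["trials"][key]
            session.trials.append(
                TrialRecord(
                    cursor_xy=g["cursor_xy"][()],
                    target_xy=g["target_xy"][()],
                    eeg=g["eeg"][()].astype(float) if "eeg" in g else None,
                    fs=float(g.attrs["fs"]),
                    channel_names=list(names),
                    channel_xyz=montage.xyz,
                    decoder_id=str(g.attrs["decoder_id"]),
                    condition=str(g.attrs["condition"]),
                    seed=int(g.attrs["seed"]),
                    session_id=session.session_id,
                    trial_id=str(g.attrs["trial_id"]),
                )
            )
    return session, montage, cfg


def load_config(path) -> dict:
    """Plain-text (YAML) experiment configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
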