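"""Supervised training of the deep decoders with ADA-based model selection,
plus the transfer-learning (pretrain/fine-tune) and midsession recalibration
paradigms.

Training minimizes 1 - cosine(prediction, label), a differentiable surrogate
whose minimizer also minimizes the average difference angle (ADA). After
each epoch ADA is computed on a held-out split (the most recent 20% of
windows by time, honoring temporal structure) and the checkpoint with the
lowest held-out ADA is returned. Midsession recalibration deliberately runs
a fixed small number of epochs with no selection: only the first four runs
of the current session are available and there is no validation set to pick
weights with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoders import DecoderModel
from .evaluation import ada
from .labeling import LabeledWindow, WindowingConfig, preprocess_for
from .nn import Adam, cosine_loss
from .simulate import SessionStore

__all__ = [
    "TrainConfig",
    "RecalConfig",
    "featurize",
    "train_supervised",
    "accumulate_sessions",
    "pretrain_pool",
    "fine_tune",
    "recalibrate_midsession",
]


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "cosine"
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    split_fraction: float = 0.2
    patience: int = 10  # early stop after this many epochs without improvement
    freeze_features: bool = False  # fine-tune only the head when True


@dataclass(frozen=True)
class RecalConfig:
    n_runs: int = 4
    epochs: int = 5
    learning_rate: float = 3e-4
    select_on_validation: bool = False  # extension; default mirrors the study


def featurize(
    model: DecoderModel, windows: list[LabeledWindow], fs: float, montage_xyz=None
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every window for the model's input and stack labels."""
    if not windows:
        raise ValueError("empty window list")
    feats = np.stack(
        [
            preprocess_for(model.preprocessing, w.eeg_window, fs, montage_xyz=montage_xyz)
            for w in windows
        ]
    )
    labels = np.stack([w.label for w in windows])
    return feats, labels


def _temporal_split(n: int, frac: float) -> tuple[np.ndarray, np.ndarray]:
    n_val = max(1, int(round(frac * n)))
    idx = np.arange(n)
    return idx[: n - n_val], idx[n - n_val :]


def _head_params(model: DecoderModel):
    if model.kind == "eegnet":
        return model.net.layers[-1].params()
    return model.net.head.params()


def _run_epochs(
    model: DecoderModel,
    feats: np.ndarray,
    labels: np.ndarray,
    val: tuple[np.ndarray, np.ndarray] | None,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
    patience: int | None,
    select: bool,
    head_only: bool = False,
) -> tuple[DecoderModel, list[float]]:
    params = _head_params(model) if head_only else model.params()
    opt = Adam(params, lr=lr)
    n = feats.shape[0]
    curve: list[float] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    stale = 0
    for _ in range(epochs):
        model.set_train(True)
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            if batch.size < 2:
                continue  # batch norm needs more than one example
            opt.zero_grad()
            pred = model.forward(feats[batch])
            _, dpred = cosine_loss(pred, labels[batch])
            model.backward(dpred)
            opt.step()
        if val is not None:
            val_ada = float(ada(model.predict(val[0]), val[1]))
            curve.append(val_ada)
            if select:
                if val_ada < best_val - 1e-12:
                    best_val = val_ada
                    best_state = model.state_arrays()
                    stale = 0
                else:
                    stale += 1
                    if patience is not None and stale >= patience:
                        break
    if select and best_state is not None:
        model.load_state_arrays(best_state)
    return model, curve


def train_supervised(
    model: DecoderModel,
    windows: list[LabeledWindow],
    cfg: TrainConfig,
    fs: float,
    montage_xyz=None,
) -> tuple[DecoderModel, list[float]]:
    """Train on labeled windows; return (best-ADA checkpoint, per-epoch ADA).

    The held-out split is disjoint from the gradient updates; the returned
    parameters are the epoch checkpoint with minimal held-out ADA.
    """
    if not windows:
        raise ValueError("cannot train on an empty dataset")
    feats, labels = featurize(model, windows, fs, montage_xyz=montage_xyz)
    tr, va = _temporal_split(len(windows), cfg.split_fraction)
    rng = np.random.default_rng(cfg.seed)
    model, curve = _run_epochs(
        model,
        feats[tr],
        labels[tr],
        (feats[va], labels[va]),
        cfg.epochs,
        cfg.learning_rate,
        cfg.batch_size,
        rng,
        cfg.patience,
        select=True,
        head_only=cfg.freeze_features,
    )
    model.provenance.setdefault("paradigm", "DL")
    model.provenance["n_windows"] = len(windows)
    return model, curve


def accumulate_sessions(store: SessionStore, upto_session: int, wcfg: WindowingConfig
                        ) -> list[LabeledWindow]:
    """Union of labeled windows from all non-chance runs of sessions 1..upto."""
    out: list[LabeledWindow] = []
    for session in store.sessions[:upto_session]:
        ws = session.labeled_windows(wcfg)
        for w in ws:
            w.subject_id = store.subject_id
        out.extend(ws)
    return out


def pretrain_pool(
    model: DecoderModel,
    stores: list[SessionStore],
    cfg: TrainConfig,
    wcfg: WindowingConfig,
    fs: float,
    montage_xyz=None,
) -> tuple[DecoderModel, list[float]]:
    """Train one base model on the pooled windows of several source subjects.

    Windows are interleaved subject-by-subject so each epoch sees a balanced
    mix; selection uses the pooled held-out ADA. A single-subject "pool"
    degenerates to plain supervised training on that subject.
    """
    if not stores:
        raise ValueError("need at least one source subject")
    per_subject = [
        accumulate_sessions(s, len(s.sessions), wcfg) for s in stores
    ]
    if any(not ws for ws in per_subject):
        raise ValueError("every source subject needs labeled windows")
    # round-robin interleave so the temporal split is balanced across subjects
    pooled: list[LabeledWindow] = []
    longest = max(len(ws) for ws in per_subject)
    for i in range(longest):
        for ws in per_subject:
            if i < len(ws):
                pooled.append(ws[i])
    model, curve = train_supervised(model, pooled, cfg, fs, montage_xyz=montage_xyz)
    model.provenance["paradigm"] = "TL-base"
    model.provenance["n_source_subjects"] = len(stores)
    return model, curve


def fine_tune(
    base: DecoderModel,
    windows: list[LabeledWindow],
    cfg: TrainConfig,
    fs: float,
    montage_xyz=None,
) -> tuple[DecoderModel, list[float]]:
    """Continue training a pretrained base model on new-subject windows."""
    model = base.copy()
    if cfg.epochs == 0:
        return model, []
    model, curve = train_supervised(model, windows, cfg, fs, montage_xyz=montage_xyz)
    model.provenance["paradigm"] = "TL"
    return model, curve


def recalibrate_midsession(
    model: DecoderModel,
    windows: list[LabeledWindow],
    cfg: RecalConfig,
    fs: float,
    montage_xyz=None,
    seed: int = 0,
) -> DecoderModel:
    """Midsession update from the current session's first runs.

    Runs exactly ``cfg.epochs`` gradient epochs over all the recalibration
    windows and returns the final-epoch parameters — no checkpoint selection,
    reflecting that no validation data exists midsession. Setting
    ``select_on_validation`` carves a 20% split and selects by ADA instead.
    """
    updated = model.copy()
    if cfg.epochs == 0 or not windows:
        return updated
    feats, labels = featurize(updated, windows, fs, montage_xyz=montage_xyz)
    rng = np.random.default_rng(seed)
    if cfg.select_on_validation:
        tr, va = _temporal_split(len(windows), 0.2)
        updated, _ = _run_epochs(
            updated, feats[tr], labels[tr], (feats[va], labels[va]),
            cfg.epochs, cfg.learning_rate, 64, rng, None, select=True,
        )
    else:
        updated, _ = _run_epochs(
            updated, feats, labels, None,
            cfg.epochs, cfg.learning_rate, 64, rng, None, select=False,
        )
    updated.provenance["paradigm"] = "CL"
    return updated
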