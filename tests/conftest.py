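"""Shared fixtures: reduced-size study conditions used across the suite.

Simulations run on a 16-channel sensorimotor montage subset at 250 Hz with
shortened trials; these are the package's smoke-scale presets, exercising
the identical code paths as the full 64-channel / 1 kHz configuration.
"""

import numpy as np
import pytest

from cpbci import (
    ARDecoder,
    EEGNetSpec,
    PointNetSpec,
    SessionRecord,
    SessionStore,
    SubjectModel,
    WindowingConfig,
    reduced_montage,
    run_run,
)
from cpbci.task import get_preset

FS = 250.0

SMOKE_EEGNET = dict(f1=4, depth=2, f2=8, kernel_t=33, kernel_sep=9)
SMOKE_POINTNET = dict(
    centroids=(8, 4, 1),
    radii=(0.6, 1.2, float("inf")),
    group_k=(8, 4, 16),
    widths=((16, 32), (32, 64), (64, 64)),
    head_width=32,
)


@pytest.fixture(scope="session")
def montage16():
    return reduced_montage(16)


@pytest.fixture(scope="session")
def subject():
    """A responsive synthetic user with clear lateralized ERD."""
    return SubjectModel(erd_depth=0.6, seed=1)


@pytest.fixture(scope="session")
def smoke_cfg():
    return get_preset("substudy1_fast").replace(trial_s=20.0, trials_per_run=2)


@pytest.fixture(scope="session")
def wcfg():
    return WindowingConfig()


@pytest.fixture(scope="session")
def eegnet_spec(montage16):
    return EEGNetSpec(n_channels=montage16.n_channels, n_samples=125, **SMOKE_EEGNET)


@pytest.fixture(scope="session")
def pointnet_spec(montage16):
    return PointNetSpec(n_points=montage16.n_channels, n_freq_bins=37, **SMOKE_POINTNET)


def make_store(subject, montage, cfg, fs, n_sessions, seed0):
    """AR-decoder-controlled sessions providing labeled training data."""
    store = SessionStore()
    ar = ARDecoder(list(montage.names), fs)
    for s in range(n_sessions):
        rec = SessionRecord(session_id=str(s + 1), schedule=[("AR", 1)])
        rec.trials = run_run(
            subject, ar, cfg, montage, seed=seed0 + s, fs=fs, condition="AR"
        )
        store.add(rec)
    return store


@pytest.fixture(scope="session")
def store5(subject, montage16, smoke_cfg):
    """Five accumulated smoke-scale sessions of AR-controlled CP runs."""
    return make_store(subject, montage16, smoke_cfg, FS, 5, seed0=1000)
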