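"""Training paradigms: supervised fitting, session accumulation, transfer
learning and midsession recalibration contracts."""

import numpy as np
import pytest

from cpbci import (
    EEGNetSpec,
    LabeledWindow,
    RecalConfig,
    TrainConfig,
    build_eegnet,
    fine_tune,
    pretrain_pool,
    recalibrate_midsession,
    train_supervised,
)
from cpbci.training import accumulate_sessions, featurize
from conftest import FS, make_store


def toy_windows(n, seed, n_channels=4, fs=250.0):
    """Noiseless realizable windows: the label angle is encoded in the
    mixing ratio of two tones per channel, a feature invariant to the
    per-window z-scoring applied by the preprocessing."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs)) / fs
    tones = [np.sin(2 * np.pi * f * t) for f in (8, 16, 24, 32)]
    out = []
    for i in range(n):
        theta = rng.uniform(0, 2 * np.pi)
        label = np.array([np.cos(theta), np.sin(theta)])
        eeg = np.zeros((n_channels, t.size))
        eeg[0] = (1 + np.cos(theta)) / 2 * tones[0] + (1 - np.cos(theta)) / 2 * tones[1]
        eeg[1] = (1 + np.sin(theta)) / 2 * tones[2] + (1 - np.sin(theta)) / 2 * tones[3]
        eeg[2] = tones[0]
        eeg[3] = tones[2]
        out.append(LabeledWindow(eeg_window=eeg, label=label, t_end=1.0 + 0.2 * i))
    return out


def small_spec(n_channels=4):
    return EEGNetSpec(n_channels=n_channels, n_samples=125, f1=4, depth=2, f2=8,
                      kernel_t=33, kernel_sep=9)


class TestTrainSupervised:
    def test_realizable_targets_reach_low_ada(self):
        windows = toy_windows(400, 0)
        cfg = TrainConfig(epochs=40, patience=15, seed=0)
        _, curve = train_supervised(build_eegnet(small_spec(), seed=0), windows, cfg, FS)
        assert min(curve) < 25.0

    def test_training_is_reproducible_bitwise(self):
        windows = toy_windows(120, 1)
        cfg = TrainConfig(epochs=4, seed=5)
        m1, c1 = train_supervised(build_eegnet(small_spec(), seed=5), windows, cfg, FS)
        m2, c2 = train_supervised(build_eegnet(small_spec(), seed=5), windows, cfg, FS)
        assert c1 == c2
        for p, q in zip(m1.params(), m2.params()):
            assert np.array_equal(p.value, q.value)

    def test_selection_returns_best_epoch_checkpoint(self):
        windows = toy_windows(200, 2)
        cfg = TrainConfig(epochs=12, patience=12, seed=0)
        model, curve = train_supervised(build_eegnet(small_spec(), seed=0), windows, cfg, FS)
        feats, labels = featurize(model, windows, FS)
        n_val = len(windows) - int(round(0.8 * len(windows)))
        from cpbci.evaluation import ada

        final = ada(model.predict(feats[-n_val:]), labels[-n_val:])
        assert final == pytest.approx(min(curve), abs=1e-6)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_supervised(build_eegnet(small_spec(), seed=0), [], TrainConfig(), FS)


class TestAccumulateSessions:
    def test_monotone_accumulation(self, store5, wcfg):
        w3 = accumulate_sessions(store5, 3, wcfg)
        w5 = accumulate_sessions(store5, 5, wcfg)
        assert len(w5) > len(w3) > 0
        ids3 = {(w.session_id, w.trial_id, w.t_end) for w in w3}
        ids5 = {(w.session_id, w.trial_id, w.t_end) for w in w5}
        assert ids3 <= ids5

    def test_first_session_only_uses_its_runs(self, store5, wcfg):
        w1 = accumulate_sessions(store5, 1, wcfg)
        assert {w.session_id for w in w1} == {"1"}

    def test_chance_runs_contribute_nothing(self, subject, montage16, smoke_cfg, wcfg):
        from cpbci import ARDecoder, SessionRecord, SessionStore, run_run

        ar = ARDecoder(list(montage16.names), FS)
        rec = SessionRecord(session_id="1", schedule=[("chance", 1)])
        rec.trials = run_run(subject, ar, smoke_cfg, montage16, seed=1, fs=FS,
                             chance=True, condition="chance")
        store = SessionStore(sessions=[rec])
        assert accumulate_sessions(store, 1, wcfg) == []


class TestTransferLearning:
    def test_single_subject_pool_equals_supervised(self, wcfg):
        windows = toy_windows(150, 3)
        cfg = TrainConfig(epochs=3, seed=1)
        direct, _ = train_supervised(build_eegnet(small_spec(), seed=1), windows, cfg, FS)

        class FakeStore:
            subject_id = "S1"
            sessions = []

        # pool with one subject whose accumulated windows equal `windows`
        import cpbci.training as tr

        orig = tr.accumulate_sessions
        tr.accumulate_sessions = lambda store, upto, w: list(windows)
        try:
            pooled, _ = pretrain_pool(build_eegnet(small_spec(), seed=1), [FakeStore()],
                                      cfg, wcfg, FS)
        finally:
            tr.accumulate_sessions = orig
        for p, q in zip(direct.params(), pooled.params()):
            assert np.array_equal(p.value, q.value)

    def test_zero_epoch_fine_tune_is_identity(self):
        base = build_eegnet(small_spec(), seed=2)
        tuned, curve = fine_tune(base, toy_windows(50, 4), TrainConfig(epochs=0), FS)
        assert curve == []
        for p, q in zip(base.params(), tuned.params()):
            assert np.array_equal(p.value, q.value)

    def test_frozen_features_touch_only_head(self):
        base = build_eegnet(small_spec(), seed=3)
        before = [p.value.copy() for p in base.params()]
        cfg = TrainConfig(epochs=2, freeze_features=True, seed=0)
        tuned, _ = fine_tune(base, toy_windows(80, 5), cfg, FS)
        n_head = len(base.net.layers[-1].params())
        after = [p.value for p in tuned.params()]
        for b, a in zip(before[:-n_head], after[:-n_head]):
            assert np.array_equal(b, a)
        assert any(not np.array_equal(b, a) for b, a in zip(before[-n_head:], after[-n_head:]))

    def test_pretrained_base_transfers_to_identical_subject(self, montage16, smoke_cfg, wcfg):
        """A base model pooled over homogeneous subjects beats chance on a
        new subject drawn from the same model, before any fine-tuning."""
        from cpbci import SubjectModel
        from cpbci.evaluation import ada

        subj_model = SubjectModel(erd_depth=0.6, seed=9)
        stores = [
            make_store(subj_model, montage16, smoke_cfg, FS, 1, seed0=2000 + 10 * k)
            for k in range(2)
        ]
        spec = EEGNetSpec(n_channels=16, n_samples=125, f1=4, depth=2, f2=8,
                          kernel_t=33, kernel_sep=9)
        cfg = TrainConfig(epochs=10, patience=5, seed=0)
        base, _ = pretrain_pool(build_eegnet(spec, seed=0), stores, cfg, wcfg, FS)
        new_store = make_store(subj_model, montage16, smoke_cfg, FS, 1, seed0=3000)
        new_windows = accumulate_sessions(new_store, 1, wcfg)
        feats, labels = featurize(base, new_windows, FS)
        assert ada(base.predict(feats), labels) < 70.0


class TestRecalibration:
    def test_zero_epochs_is_identity(self):
        model = build_eegnet(small_spec(), seed=0)
        out = recalibrate_midsession(model, toy_windows(40, 6), RecalConfig(epochs=0), FS)
        for p, q in zip(model.params(), out.params()):
            assert np.array_equal(p.value, q.value)

    def test_runs_exactly_five_epochs_without_selection(self):
        """The midsession update takes the final-epoch weights even when an
        earlier epoch would have scored better."""
        model = build_eegnet(small_spec(), seed=0)
        windows = toy_windows(60, 7)
        out5 = recalibrate_midsession(model, windows, RecalConfig(epochs=5), FS, seed=3)
        # replaying the same 5 epochs manually reproduces the result exactly
        out5b = recalibrate_midsession(model, windows, RecalConfig(epochs=5), FS, seed=3)
        for p, q in zip(out5.params(), out5b.params()):
            assert np.array_equal(p.value, q.value)
        # and the original model is untouched
        fresh = build_eegnet(small_spec(), seed=0)
        for p, q in zip(model.params(), fresh.params()):
            assert np.array_equal(p.value, q.value)

    def test_null_shift_does_not_degrade_ada(self):
        """Recalibrating on data from the training distribution leaves the
        held-out ADA essentially unchanged."""
        from cpbci.evaluation import ada

        windows = toy_windows(300, 8)
        cfg = TrainConfig(epochs=15, patience=6, seed=0)
        model, _ = train_supervised(build_eegnet(small_spec(), seed=0), windows, cfg, FS)
        extra = toy_windows(100, 9)
        recal = recalibrate_midsession(model, extra, RecalConfig(), FS, seed=1)
        test = toy_windows(150, 10)
        f, l = featurize(model, test, FS)
        before = ada(model.predict(f), l)
        after = ada(recal.predict(f), l)
        assert abs(after - before) < 10.0
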