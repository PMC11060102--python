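"""Synthetic MI subject: control-model inversion, lag, ERD spatial profile,
and the spectral content of generated EEG."""

import numpy as np
import pytest
from scipy import signal

from cpbci import (
    SubjectModel,
    SubjectSimulator,
    apply_reaction_lag,
    erd_gain_profile,
    generate_eeg,
    mi_activations,
    reduced_montage,
)


def band_power(x, fs, lo=8.0, hi=13.0):
    f, p = signal.welch(x, fs=fs, nperseg=min(len(x), int(fs)))
    return float(np.trapezoid(p[(f >= lo) & (f <= hi)], f[(f >= lo) & (f <= hi)]))


class TestMIActivations:
    @pytest.mark.parametrize(
        "direction,expected",
        [
            ((1, 0), (0.0, 1.0)),  # right: right-hand MI only
            ((-1, 0), (1.0, 0.0)),  # left: left-hand MI only
            ((0, 1), (1.0, 1.0)),  # up: both hands
            ((0, -1), (0.0, 0.0)),  # down: rest
            ((np.sqrt(2) / 2, np.sqrt(2) / 2), (0.5, 1.0)),  # oblique, clipped
            ((0, 0), (0.5, 0.5)),  # on target: neutral hover
        ],
    )
    def test_four_command_mapping(self, direction, expected):
        act = mi_activations(np.array(direction))
        assert (act.a_left, act.a_right) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            mi_activations(np.array([np.inf, 0.0]))

    def test_inverse_of_additive_control_model(self):
        """On the feasible set the activation pair reproduces the direction."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            theta = rng.uniform(0, 2 * np.pi)
            d = np.array([np.cos(theta), np.sin(theta)])
            a = mi_activations(d)
            recon = np.array([a.a_right - a.a_left, a.a_right + a.a_left - 1.0])
            if np.linalg.norm(recon) > 1e-9:
                recon = recon / np.linalg.norm(recon)
                # clipping can distort oblique directions; the angle stays acute
                assert recon @ d > 0.5


class TestReactionLag:
    def test_zero_lag_zero_smoothing_is_identity(self):
        x = np.random.default_rng(0).uniform(0, 1, (40, 2))
        model = SubjectModel(reaction_lag_s=0.0, activation_smoothing_s=0.0)
        assert np.allclose(apply_reaction_lag(x, model), x)

    def test_step_delayed_by_thirty_ticks(self):
        x = np.ones((60, 2))
        model = SubjectModel(reaction_lag_s=1.2, activation_smoothing_s=0.0)
        y = apply_reaction_lag(x, model)
        assert np.all(y[:30] == 0.0)
        assert np.all(y[30:] == 1.0)

    def test_first_order_step_response(self):
        """With a 0.2 s time constant the output reaches 63.2% of a step
        after 0.2 s of active input."""
        x = np.ones((50, 2))
        model = SubjectModel(reaction_lag_s=0.0, activation_smoothing_s=0.2)
        y = apply_reaction_lag(x, model, tick_s=0.040)
        assert y[4, 0] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-6)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            apply_reaction_lag(np.empty((0, 2)), SubjectModel())


class TestERDProfile:
    def test_peak_gain_at_seed_electrodes(self):
        m = reduced_montage(16)
        g = erd_gain_profile(m, SubjectModel())
        assert g[m.index("C3"), 0] == pytest.approx(1.0)
        assert g[m.index("C4"), 1] == pytest.approx(1.0)

    def test_gain_decays_with_distance(self):
        m = reduced_montage(64)
        model = SubjectModel(spatial_sigma=0.5)
        g = erd_gain_profile(m, model)
        far = np.argmax(m.great_circle_to("C3"))
        assert g[far, 0] < 1e-3

    def test_left_right_symmetry(self):
        m = reduced_montage(16)
        g = erd_gain_profile(m, SubjectModel())
        assert g[m.index("C4"), 0] == pytest.approx(g[m.index("C3"), 1], rel=1e-6)

    def test_missing_seed_channel_raises(self):
        m = reduced_montage(16).subset(["F3", "Fz", "F4"])
        with pytest.raises(KeyError):
            erd_gain_profile(m, SubjectModel())


class TestGenerateEEG:
    fs = 250.0

    def _activations(self, n_ticks, a_left, a_right):
        return np.tile([a_left, a_right], (n_ticks, 1)).astype(float)

    def test_depth_zero_envelope_independent_of_activation(self):
        m = reduced_montage(16)
        model = SubjectModel(erd_depth=0.0, noise_amp_uV=0.0, seed=3)
        rest = generate_eeg(self._activations(100, 0, 0), model, m, self.fs, 4.0,
                            rng=np.random.default_rng(3))
        mi = generate_eeg(self._activations(100, 0, 1), model, m, self.fs, 4.0,
                          rng=np.random.default_rng(3))
        assert np.allclose(rest, mi)

    def test_erd_suppresses_alpha_power_quantitatively(self):
        """Full right-hand MI at depth 0.5 leaves (1-0.5)^2 = 25% of the
        noise-free alpha band power at C3."""
        m = reduced_montage(16)
        model = SubjectModel(erd_depth=0.5, noise_amp_uV=0.0, seed=3)
        c3 = m.index("C3")
        rest = generate_eeg(self._activations(250, 0, 0), model, m, self.fs, 10.0,
                            rng=np.random.default_rng(3))
        mi = generate_eeg(self._activations(250, 0, 1), model, m, self.fs, 10.0,
                          rng=np.random.default_rng(3))
        ratio = band_power(mi[c3], self.fs) / band_power(rest[c3], self.fs)
        assert ratio == pytest.approx(0.25, abs=0.03)

    def test_lateralization_for_linear_decoding(self):
        """Left-hand MI lowers C4 band power more than C3, and vice versa."""
        m = reduced_montage(16)
        model = SubjectModel(erd_depth=0.6, seed=4)
        rng = np.random.default_rng
        rest = generate_eeg(self._activations(250, 0, 0), model, m, self.fs, 10.0, rng=rng(4))
        left = generate_eeg(self._activations(250, 1, 0), model, m, self.fs, 10.0, rng=rng(4))
        c3, c4 = m.index("C3"), m.index("C4")
        drop_c3 = band_power(rest[c3], self.fs) - band_power(left[c3], self.fs)
        drop_c4 = band_power(rest[c4], self.fs) - band_power(left[c4], self.fs)
        assert drop_c4 > drop_c3

    def test_determinism_under_seed(self):
        m = reduced_montage(16)
        model = SubjectModel(seed=7)
        acts = self._activations(50, 0.3, 0.8)
        a = generate_eeg(acts, model, m, self.fs, 2.0, rng=np.random.default_rng(7))
        b = generate_eeg(acts, model, m, self.fs, 2.0, rng=np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_rest_spectrum_shows_alpha_peak_above_pink_trend(self):
        m = reduced_montage(16)
        model = SubjectModel(seed=5)
        x = generate_eeg(self._activations(500, 0, 0), model, m, self.fs, 20.0,
                         rng=np.random.default_rng(5))
        f, p = signal.welch(x[m.index("Cz")], fs=self.fs, nperseg=500)
        alpha = p[(f >= 8) & (f <= 13)].max()
        flank = p[(f >= 15) & (f <= 25)].mean()
        assert alpha > 5 * flank

    def test_simulator_matches_batch_generator_envelope(self):
        """The tick-by-tick simulator and the batch generator agree on the
        lagged activation chain."""
        m = reduced_montage(16)
        model = SubjectModel(reaction_lag_s=0.2, activation_smoothing_s=0.1, seed=6)
        sim = SubjectSimulator(model, m, fs=self.fs)
        sim.start_trial(2.0, np.random.default_rng(6))
        intents = [np.array([1.0, 0.0])] * 50
        lagged = np.array([sim.step(i)[0] for i in intents])
        batch = apply_reaction_lag(
            np.array([mi_activations(i).as_array() for i in intents]), model
        )
        assert np.allclose(lagged, batch)
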