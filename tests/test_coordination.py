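import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stagewave.coordination import (
    AnalyticEpochs,
    across_trial_dpfc,
    bandpass_analytic,
    local_synchrony,
    relative_envelope_change,
    surrogate_significance,
    within_stage_dpfc,
)
from tests.conftest import lagged_analytic_epochs


class TestBandpassAnalytic:
    fs = 100.0

    def epochs(self, freq, n_trials=2, t_len=300):
        t = np.arange(t_len) / self.fs
        x = np.cos(2 * np.pi * freq * t)
        return np.tile(x, (n_trials, 3, 1))

    def onsets(self, n_trials=2, t_len=300):
        return np.tile([0, t_len], (n_trials, 1))

    def test_in_band_tone_has_flat_unit_envelope(self):
        out = bandpass_analytic(self.epochs(6.0), self.fs, self.onsets())
        env = np.abs(out.data)[:, :, 50:-50]
        assert np.all(np.abs(env - 1.0) < 0.02)

    def test_out_of_band_tone_attenuated(self):
        out = bandpass_analytic(self.epochs(20.0), self.fs, self.onsets())
        env = np.abs(out.data)[:, :, 50:-50]
        assert env.max() < 0.1  # > 90% attenuation at 20 Hz

    def test_zero_input_zero_output(self):
        out = bandpass_analytic(np.zeros((2, 3, 300)), self.fs, self.onsets())
        assert np.allclose(np.abs(out.data), 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_analytic(self.epochs(6.0), self.fs, self.onsets(),
                              low_hz=3.8, high_hz=60.0)


class TestWithinStageDpfc:
    def test_constant_lead_gives_plus_one(self):
        epochs = lagged_analytic_epochs(lag_pairs=((0, 1, 0.3),))
        res = within_stage_dpfc(epochs, 0, bump_samples=0)
        assert res.values[0, 1] == 1.0
        assert res.values[1, 0] == -1.0

    def test_identical_signals_give_zero(self):
        rng = np.random.default_rng(0)
        z = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(3, 1, 50)))
        data = np.repeat(z, 2, axis=1)
        epochs = AnalyticEpochs(data, 100.0, np.tile([0, 50], (3, 1)))
        res = within_stage_dpfc(epochs, 0, bump_samples=0)
        assert res.values[0, 1] == 0.0

    def test_independent_phases_near_zero(self):
        # 1e4 sign samples -> binomial spread ~ 1/sqrt(1e4) = 0.01
        rng = np.random.default_rng(1)
        data = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(100, 2, 100)))
        epochs = AnalyticEpochs(data, 100.0, np.tile([0, 100], (100, 1)))
        res = within_stage_dpfc(epochs, 0, bump_samples=0)
        assert abs(res.values[0, 1]) < 0.05

    def test_bump_samples_skipped(self):
        # stage 1 starts at sample 10 with a 5-sample bump during which the
        # lag is reversed; skipping the bump restores a clean +1
        epochs = lagged_analytic_epochs(t_len=60, lag_pairs=((0, 1, 0.3),))
        data = epochs.data.copy()
        data[:, 0, 10:15] = np.conj(data[:, 0, 10:15])
        onsets = np.tile([0, 10, 60], (epochs.n_trials, 1))
        flipped = AnalyticEpochs(data, 100.0, onsets)
        res = within_stage_dpfc(flipped, 1, bump_samples=5)
        assert res.values[0, 1] == 1.0
        # including the bump dilutes the statistic below 1
        res_all = within_stage_dpfc(flipped, 1, bump_samples=0)
        assert res_all.values[0, 1] < 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((3, 4, 40)) + 1j * rng.standard_normal((3, 4, 40))
        epochs = AnalyticEpochs(data, 100.0, np.tile([0, 40], (3, 1)))
        res = within_stage_dpfc(epochs, 0, bump_samples=0)
        assert np.allclose(res.values, -res.values.T)
        assert np.all(np.abs(res.values) <= 1.0)
        assert np.all(np.diag(res.values) == 0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-np.pi, np.pi), st.floats(0.1, 10.0))
    def test_invariance_common_phase_and_envelope_scale(self, shift, scale):
        epochs = lagged_analytic_epochs(lag_pairs=((0, 1, 0.4),), seed=2)
        base = within_stage_dpfc(epochs, 0, bump_samples=0).values
        data = epochs.data * scale * np.exp(1j * shift)
        moved = AnalyticEpochs(data, epochs.fs_hz, epochs.stage_onsets)
        assert np.allclose(
            within_stage_dpfc(moved, 0, bump_samples=0).values, base
        )


class TestAcrossTrialDpfc:
    def test_shared_lag_at_onset(self):
        epochs = lagged_analytic_epochs(lag_pairs=((0, 1, 0.3),))
        window, values, counts = across_trial_dpfc(epochs, 0, range(0, 5))
        assert np.all(values[:, 0, 1] == 1.0)
        assert np.all(counts == epochs.n_trials)

    def test_alternating_lags_cancel(self):
        rng = np.random.default_rng(0)
        t = np.arange(50) / 100.0
        base = 2 * np.pi * 6.0 * t
        data = np.empty((4, 2, 50), complex)
        for n in range(4):
            lag = 0.3 if n % 2 == 0 else -0.3
            off = rng.uniform(-np.pi, np.pi)
            data[n, 0] = np.exp(1j * (base + off + lag))
            data[n, 1] = np.exp(1j * (base + off))
        epochs = AnalyticEpochs(data, 100.0, np.tile([0, 50], (4, 1)))
        _, values, _ = across_trial_dpfc(epochs, 0, range(0, 5))
        assert np.all(values[:, 0, 1] == 0.0)

    def test_trials_exit_after_stage_end(self):
        # stage ends at different samples; offsets past a trial's stage end
        # must drop that trial from the average
        epochs = lagged_analytic_epochs(n_trials=6, t_len=100,
                                        lag_pairs=((0, 1, 0.3),))
        onsets = epochs.stage_onsets.copy()
        onsets[:, 1] = [20, 20, 20, 90, 90, 90]
        clipped = AnalyticEpochs(epochs.data, 100.0, onsets)
        window, values, counts = across_trial_dpfc(clipped, 0, range(0, 40))
        assert counts[0] == 6
        assert np.all(counts[25:] == 3)

    def test_truncates_when_too_few_trials(self):
        epochs = lagged_analytic_epochs(n_trials=3, t_len=60,
                                        lag_pairs=((0, 1, 0.3),))
        onsets = epochs.stage_onsets.copy()
        onsets[:, 1] = [10, 10, 50]
        clipped = AnalyticEpochs(epochs.data, 100.0, onsets)
        with pytest.warns(UserWarning, match="fewer than 2"):
            window, values, counts = across_trial_dpfc(clipped, 0, range(0, 40))
        assert window.size == 10


class TestSurrogates:
    def test_injected_lag_detected(self):
        epochs = lagged_analytic_epochs(
            n_trials=10, n_regions=4, lag_pairs=((0, 1, 0.4),),
            phase_noise=0.8, seed=3,
        )
        res = surrogate_significance(epochs, 0, n_surrogates=100, alpha=0.05,
                                     seed=0, bump_samples=0)
        assert res.significant[0, 1]
        assert np.allclose(res.significant, res.significant.T)

    def test_seed_reproducible(self):
        epochs = lagged_analytic_epochs(n_trials=6, phase_noise=1.0, seed=4)
        a = surrogate_significance(epochs, 0, 50, 0.05, seed=9, bump_samples=0)
        b = surrogate_significance(epochs, 0, 50, 0.05, seed=9, bump_samples=0)
        assert np.array_equal(a.significant, b.significant)

    def test_group_level_mean_over_subjects(self):
        # two subjects with the same injected lag: group mean stays strong
        # and the link is significant at the group level
        subjects = [
            lagged_analytic_epochs(n_trials=8, lag_pairs=((0, 1, 0.4),),
                                   phase_noise=0.6, seed=10 + s)
            for s in range(2)
        ]
        res = surrogate_significance(subjects, 0, n_surrogates=60, alpha=0.05,
                                     seed=1, bump_samples=0)
        single = within_stage_dpfc(subjects[0], 0, bump_samples=0).values
        other = within_stage_dpfc(subjects[1], 0, bump_samples=0).values
        assert np.isclose(res.values[0, 1], (single[0, 1] + other[0, 1]) / 2)
        assert res.significant[0, 1]

    def test_alpha_finer_than_resolution_warns(self):
        epochs = lagged_analytic_epochs(n_trials=4, phase_noise=1.0, seed=5)
        with pytest.warns(UserWarning, match="resolution"):
            res = surrogate_significance(epochs, 0, 20, 0.01, seed=0,
                                         bump_samples=0)
        assert res.n_surrogates == 20


class TestLocalSynchrony:
    def test_constant_envelope_rejected(self):
        data = np.exp(1j * np.linspace(0, 10, 50))[None, None, :].repeat(2, 0)
        epochs = AnalyticEpochs(data, 100.0, np.tile([10, 50], (2, 1)))
        with pytest.raises(ValueError, match="zero-variance"):
            local_synchrony(epochs, 0)

    def test_step_at_onset_survives_averaging(self):
        rng = np.random.default_rng(0)
        t_len, n_trials = 100, 8
        data = np.empty((n_trials, 1, t_len), complex)
        onsets = np.zeros((n_trials, 2), int)
        for n in range(n_trials):
            on = 30 + 4 * n
            env = np.ones(t_len) + 0.01 * rng.standard_normal(t_len)
            env[on:] += 1.0
            data[n, 0] = env * np.exp(1j * 2 * np.pi * 6 * np.arange(t_len) / 100)
            onsets[n] = [on, t_len]
        epochs = AnalyticEpochs(data, 100.0, onsets)
        offs, env = local_synchrony(epochs, 0, rel_window=(-6, 6))
        pre = env[0, offs < 0].mean()
        post = env[0, offs >= 0].mean()
        assert post - pre > 1.0  # step of ~2 pre/post std in z units

    def test_opposite_steps_cancel(self):
        t_len = 100
        base = np.exp(1j * 2 * np.pi * 6 * np.arange(t_len) / 100)
        env_up = np.concatenate([np.ones(50), 2 * np.ones(50)])
        env_dn = np.concatenate([2 * np.ones(50), np.ones(50)])
        data = np.stack([(env_up * base)[None], (env_dn * base)[None]])
        epochs = AnalyticEpochs(data, 100.0, np.tile([50, 100], (2, 1)))
        offs, env = local_synchrony(epochs, 0, rel_window=(-6, 6))
        assert np.all(np.abs(env) < 1e-9)


class TestRelativeEnvelopeChange:
    def test_flat_envelope_zero(self):
        assert relative_envelope_change(np.ones((3, 12)), 100.0)[0] == 0.0

    def test_unit_step_at_onset(self):
        env = np.zeros((1, 12))
        env[:, 6:] = 1.0
        assert np.isclose(relative_envelope_change(env, 100.0)[0], 1.0)

    def test_ramp_through_onset(self):
        # slope 1 z/s at 100 Hz; pre window centers at -35 ms, post at +25 ms
        offs = np.arange(-6, 6)
        env = (offs / 100.0)[None, :]  # z = t for slope 1 z/s
        change = relative_envelope_change(env, 100.0)[0]
        assert np.isclose(change, 0.060, atol=1e-12)

    def test_window_exceeding_data_rejected(self):
        with pytest.raises(ValueError, match="window"):
            relative_envelope_change(np.ones((2, 8)), 100.0, onset_index=6)
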