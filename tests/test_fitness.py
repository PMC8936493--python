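import numpy as np
import pytest

from stagewave.coordination import AnalyticEpochs
from stagewave.fitness import (
    TargetStateSet,
    build_initial_history,
    combined_fitness,
    evaluate_schedule,
    fitness_f1,
    fitness_f2,
    fitness_f3,
)
from stagewave.simulator import PulseSchedule


def toy_sign_matrices():
    """4-link toy: x = [1,-1,0,1], y = [1,1,-1,1] on a 4-region upper triangle."""
    x = np.zeros((4, 4))
    y = np.zeros((4, 4))
    links = [(0, 1), (0, 2), (0, 3), (1, 2)]
    for (i, j), xv, yv in zip(links, [1, -1, 0, 1], [1, 1, -1, 1]):
        x[i, j], x[j, i] = xv, -xv
        y[i, j], y[j, i] = yv, -yv
    return x, y


class TestObjectives:
    def test_f1_hand_evaluated_toy(self):
        x, y = toy_sign_matrices()
        assert np.isclose(fitness_f1(y, x), 1 / 3)

    def test_f1_perfect_and_opposed(self):
        x, _ = toy_sign_matrices()
        assert fitness_f1(x, x) == 1.0
        assert fitness_f1(-x, x) == -1.0

    def test_f1_all_zero_target_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            fitness_f1(np.zeros((3, 3)), np.zeros((3, 3)))

    def test_f2_identity_reversal_and_swap(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert fitness_f2(v, v) == 1.0
        assert fitness_f2(v[::-1], v) == -1.0
        # one adjacent swap on 4 ranks: rho = 1 - 6*2/(4*15) = 0.8
        assert np.isclose(fitness_f2(np.array([1.0, 3.0, 2.0, 4.0]), v), 0.8)

    def test_f2_constant_vector_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert fitness_f2(np.ones(5), np.arange(5.0)) == 0.0

    def test_f3_arithmetic_and_homogeneity(self):
        dl = np.array([0.5, -0.5])
        assert np.isclose(fitness_f3(dl, 1.0, 4), 0.25)
        assert fitness_f3(np.zeros(5), 2.0, 3) == 0.0
        assert np.isclose(fitness_f3(3 * dl, 1.0, 4), 3 * 0.25)

    def test_combined_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f1, f2, f3 = rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(0, 2)
            assert combined_fitness(f1, f2, f3) == f1 - (1 - f2) * f3

    def test_f2_one_makes_combined_equal_f1(self):
        assert combined_fitness(0.4, 1.0, 17.3) == 0.4


class TestTargetStateSet:
    def test_invariants_enforced(self):
        bad = np.zeros((1, 3, 3))
        bad[0, 0, 1] = 1.0  # not antisymmetric
        with pytest.raises(ValueError, match="antisymmetric"):
            TargetStateSet(bad, np.zeros((1, 3)), [0.3])

    def test_n_links_counts_upper_triangle(self):
        x, _ = toy_sign_matrices()
        t = TargetStateSet(x[None], np.zeros((1, 4)), [0.3])
        assert t.n_links[0] == 3


class TestEvaluateSchedule:
    def test_self_target_zero_pulse(self, model_fixture):
        """Targets taken from the unpulsed model itself give f1 = 1, f3 = 0."""
        from stagewave.synth import synth_target_states

        fx = model_fixture
        zero = PulseSchedule(
            onsets_s=fx.true_schedule.onsets_s,
            delta_L=np.zeros_like(fx.true_schedule.delta_L),
            l_max=fx.true_schedule.l_max,
        )
        targets, _ = synth_target_states(
            fx.connectome, fx.params, zero, fx.stage_durations_s,
            initial_histories=fx.initial_histories,
        )
        rep = evaluate_schedule(
            fx.connectome, fx.params, zero, targets,
            initial_histories=fx.initial_histories,
        )
        assert rep.f1 == 1.0
        assert rep.f3 == 0.0
        assert rep.combined == 1.0

    def test_self_consistency_true_schedule(self, model_fixture):
        fx = model_fixture
        rep = evaluate_schedule(
            fx.connectome, fx.params, fx.true_schedule, fx.targets,
            initial_histories=fx.initial_histories,
        )
        assert rep.f1 >= 0.9
        assert np.isclose(
            rep.combined, rep.f1 - (1 - rep.f2) * rep.f3, atol=1e-12
        )

    def test_stage_count_mismatch_rejected(self, model_fixture):
        fx = model_fixture
        one_stage = PulseSchedule(
            onsets_s=[0.0], delta_L=fx.true_schedule.delta_L[:1],
            l_max=fx.true_schedule.l_max,
        )
        with pytest.raises(ValueError, match="number of stages"):
            evaluate_schedule(fx.connectome, fx.params, one_stage, fx.targets)


def reference_epochs_for_history(n_trials=20, n_regions=6, seed=0,
                                 consistent=(0, 1, 2), phase_sigma=0.05):
    """Analytic epochs whose pre-onset phases are consistent for some regions."""
    rng = np.random.default_rng(seed)
    t_len, fs = 60, 100.0
    t = np.arange(t_len) / fs
    onset1 = 20
    data = np.empty((n_trials, n_regions, t_len), complex)
    base_phase = rng.uniform(-np.pi, np.pi, n_regions)
    for n in range(n_trials):
        for r in range(n_regions):
            if r in consistent:
                off = base_phase[r] + phase_sigma * rng.standard_normal()
            else:
                off = rng.uniform(-np.pi, np.pi)
            env = 0.5 + 0.1 * rng.random()
            data[n, r] = env * np.exp(1j * (2 * np.pi * 6 * t + off))
    onsets = np.tile([0, onset1, t_len], (n_trials, 1))
    return AnalyticEpochs(data, fs, onsets)


class TestBuildInitialHistory:
    def test_all_consistent_uses_circular_means(self):
        epochs = reference_epochs_for_history(consistent=range(6))
        hist, sim = build_initial_history(epochs, horizon=40, dt_s=0.001,
                                          noise_sigma=0.0, seed=1)
        assert hist.moduli.shape == (6, 40)
        assert np.all(hist.moduli >= 0) and np.all(hist.moduli <= 1)
        # with sigma = 0 the final phase equals the circular mean at -0.05 s
        idx = np.arange(epochs.n_trials)
        t50 = epochs.stage_onsets[:, 1] - 5
        circ = np.angle(np.exp(1j * np.angle(epochs.data[idx, :, t50])).mean(axis=0))
        assert np.allclose(
            np.angle(np.exp(1j * (hist.phases[:, -1] - circ))), 0.0, atol=1e-9
        )

    def test_free_phases_match_target_sign(self):
        epochs = reference_epochs_for_history(consistent=(0,))
        target = np.zeros((6, 6))
        for i, j in [(1, 2), (3, 4), (1, 5), (2, 4)]:
            target[i, j], target[j, i] = 1.0, -1.0
        hist, similarity = build_initial_history(
            epochs, horizon=40, dt_s=0.001, pre_stage_dpfc_target=target,
            noise_sigma=0.0, seed=2,
        )
        assert similarity == 1.0
        for i, j in [(1, 2), (3, 4), (1, 5), (2, 4)]:
            assert np.sin(hist.phases[i, -1] - hist.phases[j, -1]) > 0

    def test_no_consistency_no_target_warns(self):
        epochs = reference_epochs_for_history(consistent=(), seed=3)
        with pytest.warns(UserWarning, match="random phases"):
            build_initial_history(epochs, horizon=40, dt_s=0.001, seed=3)

    def test_noise_free_history_reproduces_trial_values(self):
        # identical trials, sigma = 0: moduli anchor exactly on the trial's
        # own (rescaled) pre-onset envelopes
        epochs = reference_epochs_for_history(n_trials=1, consistent=range(6),
                                              phase_sigma=0.0, seed=4)
        data = np.repeat(epochs.data, 5, axis=0)
        onsets = np.repeat(epochs.stage_onsets, 5, axis=0)
        same = AnalyticEpochs(data, epochs.fs_hz, onsets)
        hist, _ = build_initial_history(same, horizon=51, dt_s=0.001,
                                        noise_sigma=0.0, seed=0)
        env = np.abs(same.data)
        scale = np.percentile(env, 95)
        expected_t0 = np.clip(env[0, :, onsets[0, 1] - 5] / scale, 0.02, 0.98)
        assert np.allclose(hist.moduli[:, -1], expected_t0, atol=1e-12)
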