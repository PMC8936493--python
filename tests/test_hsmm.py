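import numpy as np
import pytest
from scipy.stats import binomtest

from stagewave.hsmm import (
    BumpModel,
    decode_onsets,
    discretized_gamma2_logpmf,
    fit_bump_hsmm,
    half_sine_window,
    preprocess_pca,
    score_model,
    select_n_bumps,
)
from stagewave.synth import synth_bump_scores


@pytest.fixture(scope="module")
def bump_data():
    """200 trials of 4-bump component scores at the reference conditions."""
    return synth_bump_scores(n_trials=200, seed=11)


@pytest.fixture(scope="module")
def fitted_model(bump_data):
    scores, lengths, onsets, mags = bump_data
    return fit_bump_hsmm(scores, lengths, 4, n_starts=20, seed=1)


class TestDurationPmf:
    @pytest.mark.parametrize("scale", [2.0, 10.0, 25.0])
    def test_pmf_sums_to_one(self, scale):
        logpmf = discretized_gamma2_logpmf(scale, 300)
        assert np.isclose(np.exp(logpmf).sum(), 1.0, atol=1e-9)

    def test_mean_approaches_twice_scale(self):
        scale = 8.0
        logpmf = discretized_gamma2_logpmf(scale, 2000)
        pmf = np.exp(logpmf)
        mean = (np.arange(pmf.size) * pmf).sum()
        # discretization pmf(d) = CDF(d) - CDF(d-1) shifts the mean ~0.5
        assert abs(mean - 2 * scale) < 0.6

    def test_minimum_duration_one_sample(self):
        logpmf = discretized_gamma2_logpmf(5.0, 100)
        assert logpmf[0] == -np.inf and np.isfinite(logpmf[1])


class TestHalfSine:
    def test_window_values(self):
        w = half_sine_window(5)
        assert np.isclose(w[2], 1.0)
        assert np.allclose(w, w[::-1])  # symmetric
        assert np.isclose((w**2).sum(), 2.5)


class TestFit:
    def test_zero_bump_closed_form(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((20, 3, 60))
        lengths = np.full(20, 50)
        model = fit_bump_hsmm(scores, lengths, 0)
        expected_const = sum(
            -0.5 * (scores[i, :, :50] ** 2).sum()
            - 0.5 * 3 * 50 * np.log(2 * np.pi)
            for i in range(20)
        )
        logpmf = discretized_gamma2_logpmf(model.gamma_scales[0], 60)
        assert np.isclose(
            model.log_likelihood, expected_const + 20 * logpmf[50], rtol=1e-10
        )

    def test_em_loglik_nondecreasing(self, fitted_model):
        path = fitted_model.loglik_path
        assert np.all(np.diff(path) >= -1e-6 * np.abs(path[:-1]))

    def test_magnitudes_and_scales_recovered(self, bump_data, fitted_model):
        scores, lengths, onsets, mags = bump_data
        for k in range(4):
            cos = np.dot(fitted_model.bump_magnitudes[k], mags[k]) / (
                np.linalg.norm(fitted_model.bump_magnitudes[k])
                * np.linalg.norm(mags[k])
            )
            assert cos > 0.95
        assert np.allclose(
            fitted_model.gamma_scales, (10, 7, 15, 10, 12), rtol=0.35
        )

    def test_duplicated_trials_double_loglik(self, bump_data):
        scores, lengths, _, _ = bump_data
        sub_s, sub_l = scores[:30], lengths[:30]
        model = fit_bump_hsmm(sub_s, sub_l, 4, n_starts=4, seed=0)
        single = score_model(model, sub_s, sub_l)
        double = score_model(
            model, np.concatenate([sub_s, sub_s]), np.concatenate([sub_l, sub_l])
        )
        assert np.isclose(double, 2 * single, rtol=1e-12)

    def test_posteriors_sum_to_one(self, bump_data, fitted_model):
        from stagewave.hsmm import _ModelEval

        scores, lengths, _, _ = bump_data
        ev = _ModelEval(scores[:50], lengths[:50], fitted_model,
                        np.zeros(50, int))
        ll, fwd, bwd = ev.forward_backward()
        post = np.exp(fwd + bwd - (ll - ev.const)[None, :, None])
        assert np.allclose(post.sum(axis=2), 1.0, atol=1e-8)

    def test_short_trials_excluded_with_warning(self, bump_data):
        scores, lengths, _, _ = bump_data
        lengths2 = lengths.copy()
        lengths2[:3] = 10  # shorter than 4 bumps need
        with pytest.warns(UserWarning, match="excluding 3 trials"):
            fit_bump_hsmm(scores, lengths2, 4, n_starts=2, seed=0,
                          max_iter=3)

    def test_onset_rmse_decreases_with_magnitude(self):
        rmses = []
        for mag in (1.0, 2.0, 4.0):
            scores, lengths, onsets, _ = synth_bump_scores(
                n_trials=80, magnitude=mag, seed=21
            )
            model = fit_bump_hsmm(scores, lengths, 4, n_starts=8, seed=2)
            seg = decode_onsets(model, scores, lengths)
            rmses.append(np.sqrt(np.mean((seg.onsets - onsets) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]


class TestDecode:
    def test_noise_free_exact_recovery(self):
        scores, lengths, onsets, mags = synth_bump_scores(
            n_trials=30, noise_sigma=0.0, seed=5
        )
        # tiny noise to avoid degenerate all-zero flats in the likelihood
        rng = np.random.default_rng(0)
        scores = scores + 1e-6 * rng.standard_normal(scores.shape)
        model = BumpModel(4, mags, np.array([10.0, 7.0, 15.0, 10.0, 12.0]))
        seg = decode_onsets(model, scores, lengths)
        assert np.array_equal(seg.onsets, onsets)

    def test_determinism_on_duplicated_trials(self, bump_data, fitted_model):
        scores, lengths, _, _ = bump_data
        pair_s = np.concatenate([scores[:1], scores[:1]])
        pair_l = np.concatenate([lengths[:1], lengths[:1]])
        seg = decode_onsets(fitted_model, pair_s, pair_l)
        assert np.array_equal(seg.onsets[0], seg.onsets[1])

    def test_durations_partition_trial(self, bump_data, fitted_model):
        scores, lengths, _, _ = bump_data
        seg = decode_onsets(fitted_model, scores[:20], lengths[:20])
        assert np.array_equal(seg.stage_durations.sum(axis=1), lengths[:20])
        assert np.all(np.diff(seg.onsets, axis=1) > 0)

    def test_pure_noise_still_returns_onsets(self, fitted_model):
        rng = np.random.default_rng(3)
        noise = rng.standard_normal((5, 10, 150))
        lengths = np.full(5, 140)
        seg = decode_onsets(fitted_model, noise, lengths)
        assert seg.onsets.shape == (5, 4)
        assert np.all(seg.map_log_posterior <= 0)


class TestSelection:
    def test_sign_test_arithmetic(self):
        # 15 of 18 improved: p = 2 * (C(18,15)+C(18,16)+C(18,17)+C(18,18)) / 2^18
        assert np.isclose(binomtest(15, 18).pvalue, 2 * 988 / 2**18, rtol=1e-12)
        # 9 of 18: p = 1 by symmetry
        assert binomtest(9, 18).pvalue == 1.0

    def test_condition_specific_scales(self):
        scores, lengths, onsets, mags = synth_bump_scores(n_trials=120, seed=31)
        conds = np.arange(120) % 2
        model = fit_bump_hsmm(
            scores, lengths, 4, n_starts=6, seed=0,
            conditions=conds, condition_stages=(2,),
        )
        assert set(model.condition_scales) == {2}
        assert set(model.condition_scales[2]) == {0, 1}
        for scale in model.condition_scales[2].values():
            assert scale > 0


class TestPreprocessPca:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(0)
        pattern = rng.standard_normal(6)
        series = rng.standard_normal((10, 1, 80))
        epochs = pattern[None, :, None] * series
        scores, proj, ratio = preprocess_pca(
            [epochs], [np.full(10, 80)], var_target=0.9
        )
        assert proj.shape[1] == 1
        assert ratio[0] > 0.999

    def test_var_target_one_keeps_full_rank(self):
        rng = np.random.default_rng(1)
        epochs = rng.standard_normal((5, 6, 60))
        scores, proj, _ = preprocess_pca([epochs], [np.full(5, 60)], var_target=1.0)
        assert proj.shape[1] == 6

    def test_signal_subspace_dimension_detected(self):
        # 68 channels, 33-dimensional signal subspace + isotropic noise;
        # per-component signal variance set so 33 components carry ~90%
        rng = np.random.default_rng(2)
        n_ch, n_sig = 68, 33
        sig_var = 0.9 * n_ch / (0.1 * n_sig)
        basis, _ = np.linalg.qr(rng.standard_normal((n_ch, n_sig)))
        latent = np.sqrt(sig_var) * rng.standard_normal((20, n_sig, 100))
        epochs = np.einsum("cs,nst->nct", basis, latent)
        epochs += rng.standard_normal(epochs.shape)
        _, proj, _ = preprocess_pca(
            [epochs], [np.full(20, 100)], band_hz=(1.0, 45.0),
            fs_hz=100.0, var_target=0.90,
        )
        assert abs(proj.shape[1] - 33) <= 3

    def test_baseline_window_subtracted(self):
        # a constant channel offset in the baseline window disappears
        rng = np.random.default_rng(3)
        epochs = rng.standard_normal((4, 3, 120)) + 5.0
        scores_raw, _, _ = preprocess_pca(
            [epochs], [np.full(4, 120)], baseline_window_s=None, var_target=1.0
        )
        scores_bc, _, _ = preprocess_pca(
            [epochs], [np.full(4, 120)], baseline_window_s=(0.0, 0.4),
            var_target=1.0,
        )
        # the band-pass already removes DC, so both paths agree closely; the
        # baseline path must at least produce near-zero-mean early samples
        assert abs(np.mean(scores_bc[0][:, :, :40])) < 0.2

    def test_invalid_var_target(self):
        with pytest.raises(ValueError, match="var_target"):
            preprocess_pca([np.zeros((2, 3, 50))], [np.full(2, 50)], var_target=1.5)
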