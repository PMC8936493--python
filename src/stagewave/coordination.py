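"""Theta-band analytic signals and directed phase-lag functional connectivity.

The directed phase-lag statistic (dpFC) between regions i and j is the
average sign of the imaginary part of their cross-spectral density
``S_ij = z_i conj(z_j)``; with the convention used here ``Im(S_ij)`` is
positive when i is phase-ahead of j (for lags below pi). Averaging the sign
over the samples of a stage's flat and over trials gives *within-stage*
dpFC; averaging across trials at each sample time-locked to a stage onset
gives *across-trial* dpFC. Zero-phase-lag coupling is invisible to both by
construction. Significance is assessed with circular-shift surrogates that
preserve each phase series' autocorrelation while destroying cross-region
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "AnalyticEpochs",
    "DpFCResult",
    "bandpass_analytic",
    "within_stage_dpfc",
    "across_trial_dpfc",
    "surrogate_significance",
    "local_synchrony",
    "relative_envelope_change",
]

THETA_BAND_HZ = (3.8, 8.5)
BUMP_WIDTH_SAMPLES = 5


@dataclass
class AnalyticEpochs:
    """Complex analytic epochs with per-trial stage-onset samples.

    ``stage_onsets[n]`` holds, for trial ``n``: the stimulus sample, the bump
    onsets of stages 2..S, and the response sample — all strictly increasing.
    Stage ``s`` (0-based) spans ``[stage_onsets[n, s], stage_onsets[n, s+1])``.
    """

    data: np.ndarray  # (N, R, T) complex
    fs_hz: float
    stage_onsets: np.ndarray  # (N, n_stages + 1) int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.stage_onsets = np.asarray(self.stage_onsets, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x regions x samples")
        if self.stage_onsets.shape[0] != self.data.shape[0]:
            raise ValueError("one onset row per trial required")
        if np.any(np.diff(self.stage_onsets, axis=1) <= 0):
            raise ValueError("stage onsets must be strictly increasing per trial")
        if self.stage_onsets.min() < 0 or self.stage_onsets.max() > self.data.shape[2]:
            raise ValueError("stage onsets outside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_stages(self) -> int:
        return self.stage_onsets.shape[1] - 1


@dataclass
class DpFCResult:
    """Antisymmetric signed phase-lead statistic per region pair."""

    values: np.ndarray  # (R, R) in [-1, 1], antisymmetric
    significant: np.ndarray | None = None  # (R, R) bool, symmetric
    n_surrogates: int = 0
    alpha: float = float("nan")


def bandpass_analytic(
    epochs_raw: np.ndarray,
    fs_hz: float,
    stage_onsets: np.ndarray,
    low_hz: float = THETA_BAND_HZ[0],
    high_hz: float = THETA_BAND_HZ[1],
    order: int = 4,
    pad_s: float = 0.4,
    subject_id: str | None = None,
) -> AnalyticEpochs:
    """Zero-phase Butterworth band-pass followed by the Hilbert analytic signal.

    Both the forward-backward filter and the Hilbert transform are computed
    on symmetrically padded epochs (``pad_s`` seconds each side) and the
    padding is discarded, suppressing edge artifacts.
    """
    if not 0 < low_hz < high_hz < fs_hz / 2:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    x = np.asarray(epochs_raw, dtype=float)
    pad = int(round(pad_s * fs_hz))
    if x.shape[-1] <= 2 * pad:
        raise ValueError("epochs shorter than twice the padding")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="symmetric")
    filt = sosfiltfilt(sos, xp, axis=-1)
    analytic = hilbert(filt, axis=-1)[..., pad:-pad]
    return AnalyticEpochs(analytic, fs_hz, stage_onsets, subject_id)


def _sign_im_cross(z: np.ndarray) -> np.ndarray:
    """sgn(Im(z_i conj z_j)) for a (R, T) block -> (R, R, T); sgn(0) = 0.

    Imaginary parts that are pure floating-point residue (identical or
    conjugate-symmetric inputs leave ~1e-16 relative noise) count as zero.
    """
    s = z[:, None, :] * np.conj(z[None, :, :])
    im = s.imag.copy()
    im[np.abs(im) <= 1e-12 * np.abs(s)] = 0.0
    return np.sign(im)


def _stage_slice(onsets_row: np.ndarray, stage: int, bump_samples: int) -> slice:
    start = int(onsets_row[stage]) + (bump_samples if stage > 0 else 0)
    return slice(start, int(onsets_row[stage + 1]))


def within_stage_dpfc(
    epochs: AnalyticEpochs,
    stage: int,
    bump_samples: int = BUMP_WIDTH_SAMPLES,
) -> DpFCResult:
    """Trial-averaged mean sign of phase lags over a stage's flat.

    The flat runs from the first sample after the stage-initial bump to the
    stage end; the first stage has no bump, so its flat starts at the stage
    onset. Trials whose flat is empty are skipped with a warning.
    """
    values = np.zeros((epochs.n_regions, epochs.n_regions))
    n_used = 0
    for n in range(epochs.n_trials):
        sl = _stage_slice(epochs.stage_onsets[n], stage, bump_samples)
        if sl.stop <= sl.start:
            warnings.warn(f"trial {n}: empty flat for stage {stage}; skipped")
            continue
        values += _sign_im_cross(epochs.data[n, :, sl.start : sl.stop]).mean(axis=-1)
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no trial has a non-empty flat for stage {stage}")
    return DpFCResult(values / n_used)


def across_trial_dpfc(
    epochs: AnalyticEpochs, stage: int, window: np.ndarray | range
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample dpFC across trials, time-locked to a stage onset.

    ``window`` contains sample offsets relative to the stage onset. A trial
    contributes at offset ``t`` only while the stage has not yet ended in
    that trial (and the sample is inside the epoch). The series is truncated
    with a warning once fewer than two trials remain.

    Returns ``(offsets, values, n_trials)`` with ``values`` of shape
    (W, R, R).
    """
    window = np.asarray(list(window), dtype=int)
    r = epochs.n_regions
    values = np.zeros((window.size, r, r))
    counts = np.zeros(window.size, dtype=int)
    t_len = epochs.data.shape[2]
    for wi, off in enumerate(window):
        acc = np.zeros((r, r))
        n_t = 0
        for n in range(epochs.n_trials):
            t = int(epochs.stage_onsets[n, stage]) + off
            if t < 0 or t >= t_len:
                continue
            if off >= 0 and t >= epochs.stage_onsets[n, stage + 1]:
                continue  # stage already over in this trial
            acc += np.sign(
                (epochs.data[n, :, t][:, None] * np.conj(epochs.data[n, :, t])[None, :]).imag
            )
            n_t += 1
        if n_t < 2:
            warnings.warn(
                f"fewer than 2 trials at offset {off}; truncating across-trial dpFC"
            )
            window = window[:wi]
            values = values[:wi]
            counts = counts[:wi]
            break
        values[wi] = acc / n_t
        counts[wi] = n_t
    return window, values, counts


def _shifted(epochs: AnalyticEpochs, rng: np.random.Generator) -> AnalyticEpochs:
    """Independent random circular time shift of every trial x region series."""
    data = np.empty_like(epochs.data)
    n, r, t = epochs.data.shape
    shifts = rng.integers(1, t, size=(n, r))
    for i in range(n):
        for j in range(r):
            data[i, j] = np.roll(epochs.data[i, j], shifts[i, j])
    return AnalyticEpochs(data, epochs.fs_hz, epochs.stage_onsets, epochs.subject_id)


def surrogate_significance(
    epochs: AnalyticEpochs | list[AnalyticEpochs],
    stage: int,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    bump_samples: int = BUMP_WIDTH_SAMPLES,
    fdr: bool = False,
) -> DpFCResult:
    """Two-sided circular-shift surrogate test of within-stage dpFC.

    Each surrogate applies an independent uniform circular shift to every
    trial x region phase series and recomputes the statistic. A link is
    significant when its empirical |dpFC| exceeds the (1 - alpha) quantile
    of its surrogate |dpFC| distribution. When a list of epochs (subjects)
    is given, the statistic is the across-subject mean and each surrogate
    shifts every subject independently. With ``fdr`` the surrogate p-values
    are Benjamini-Hochberg corrected instead of per-link thresholded.
    """
    if n_surrogates < 20:
        raise ValueError("use at least 20 surrogates")
    subjects = epochs if isinstance(epochs, list) else [epochs]

    def _stat(subj_list: list[AnalyticEpochs]) -> np.ndarray:
        return np.mean(
            [within_stage_dpfc(s, stage, bump_samples).values for s in subj_list],
            axis=0,
        )

    emp = _stat(subjects)
    rng = np.random.default_rng(seed)
    surr = np.empty((n_surrogates,) + emp.shape)
    for k in range(n_surrogates):
        surr[k] = _stat([_shifted(s, rng) for s in subjects])

    abs_surr = np.abs(surr)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p = (1.0 + (abs_surr >= np.abs(emp)[None]).sum(axis=0)) / (n_surrogates + 1.0)
        iu, ju = np.triu_indices(emp.shape[0], k=1)
        rej, *_ = multipletests(p[iu, ju], alpha=alpha, method="fdr_bh")
        significant = np.zeros(emp.shape, dtype=bool)
        significant[iu, ju] = rej
        significant |= significant.T
    else:
        if (n_surrogates + 1) * alpha < 1:
            warnings.warn(
                "alpha finer than the surrogate resolution; using the maximum "
                "surrogate value as threshold"
            )
            thresh = abs_surr.max(axis=0)
        else:
            thresh = np.quantile(abs_surr, 1.0 - alpha, axis=0)
        significant = np.abs(emp) > thresh
        significant &= significant.T  # symmetry (holds by construction)
    np.fill_diagonal(significant, False)
    return DpFCResult(emp, significant, n_surrogates, alpha)


def local_synchrony(
    epochs: AnalyticEpochs,
    stage: int,
    rel_window: tuple[int, int] = (-6, 6),
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-onset-locked average of per-trial z-scored envelopes.

    Envelopes are z-scored over each trial's full time axis, then averaged
    across trials at sample offsets ``rel_window[0] .. rel_window[1]-1``
    relative to the stage onset. Returns ``(offsets, env)`` with ``env`` of
    shape (R, W).
    """
    offsets = np.arange(rel_window[0], rel_window[1])
    env = np.abs(epochs.data)
    mean = env.mean(axis=2, keepdims=True)
    std = env.std(axis=2, keepdims=True)
    bad = np.argwhere(std[:, :, 0] <= 1e-10 * np.abs(mean[:, :, 0]))
    if bad.size:
        n, r = bad[0]
        raise ValueError(f"zero-variance envelope in trial {n}, region {r}")
    z = (env - mean) / std
    t_len = epochs.data.shape[2]
    acc = np.zeros((epochs.n_regions, offsets.size))
    cnt = np.zeros(offsets.size)
    for n in range(epochs.n_trials):
        t = int(epochs.stage_onsets[n, stage]) + offsets
        ok = (t >= 0) & (t < t_len)
        acc[:, ok] += z[n][:, t[ok]]
        cnt[ok] += 1
    if np.any(cnt == 0):
        raise ValueError("window extends beyond the data in every trial")
    return offsets, acc / cnt


def relative_envelope_change(
    stage_locked_env: np.ndarray,
    fs_hz: float,
    onset_index: int = 6,
    pre_ms: tuple[float, float] = (-60.0, -10.0),
    post_ms: tuple[float, float] = (0.0, 50.0),
) -> np.ndarray:
    """Difference of mean z-scored envelope after vs before a stage onset.

    Window bounds are inclusive sample sets: at 100 Hz the pre window
    [-60, -10] ms is samples -6..-1 and the post window [0, 50] ms is
    samples 0..5 relative to the onset. The change is a difference (not a
    ratio) since z-scores may be non-positive.
    """
    env = np.atleast_2d(np.asarray(stage_locked_env, dtype=float))
    w = env.shape[1]

    def _idx(lo_ms: float, hi_ms: float) -> np.ndarray:
        lo = onset_index + int(round(lo_ms / 1000.0 * fs_hz))
        hi = onset_index + int(round(hi_ms / 1000.0 * fs_hz))
        idx = np.arange(lo, hi + 1)
        if idx[0] < 0 or idx[-1] >= w:
            raise ValueError("envelope window exceeds the available data")
        return idx

    pre = env[:, _idx(*pre_ms)].mean(axis=1)
    post = env[:, _idx(*post_ms)].mean(axis=1)
    return post - pre
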