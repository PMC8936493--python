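"""Bump hidden semi-Markov segmentation of epoched multichannel signals.

A trial is modeled as a fixed sequence of cognitive stages. Every stage
after the first begins with a *bump*: a 50-ms (5 samples at 100 Hz)
multivariate amplitude modulation with a trial-invariant topology across
principal components, shaped in time by a half-sine window. Between bumps
the signal is a zero-mean *flat*. Flat durations follow a gamma
distribution with shape fixed at 2 and a free scale per stage (optionally
per experimental condition for designated stages), discretized to samples.
Emissions are independent Gaussians on z-scored component scores: mean 0 in
flats, mean ``w_p * B_kc`` during sample ``p`` of bump ``k``.

EM alternates exact forward-backward sums over all admissible bump
placements (dynamic programming; the duration convolutions are computed in
scaled linear space with FFTs) with closed-form updates of bump magnitudes
and gamma scales. Model order (number of bumps) is chosen by
leave-one-subject-out cross-validation with an exact sign test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, fftconvolve, sosfiltfilt
from scipy.stats import binomtest, gamma as gamma_dist

__all__ = [
    "BumpModel",
    "StageSegmentation",
    "preprocess_pca",
    "fit_bump_hsmm",
    "select_n_bumps",
    "decode_onsets",
    "discretized_gamma2_logpmf",
]

BUMP_WIDTH = 5
GAMMA_SHAPE = 2.0
MIN_SCALE = 0.25
_NEG_INF = -np.inf


def half_sine_window(width: int = BUMP_WIDTH) -> np.ndarray:
    """Temporal bump template: w_p = sin(pi (p + 1/2) / width)."""
    return np.sin(np.pi * (np.arange(width) + 0.5) / width)


def discretized_gamma2_logpmf(scale: float, d_max: int) -> np.ndarray:
    """Log-pmf of flat durations d = 0..d_max; pmf(d) = CDF(d) - CDF(d-1), d >= 1.

    Renormalized over the support 1..d_max; index 0 is -inf (flats last at
    least one sample). The mean of the pmf approaches 2*scale as the support
    grows.
    """
    d = np.arange(d_max + 1)
    cdf = gamma_dist.cdf(d, a=GAMMA_SHAPE, scale=scale)
    pmf = np.diff(cdf, prepend=0.0)
    pmf[0] = 0.0
    total = pmf.sum()
    if total <= 0:
        raise ValueError(f"degenerate duration pmf for scale={scale}")
    with np.errstate(divide="ignore"):
        return np.log(pmf / total)


@dataclass
class BumpModel:
    """Fitted bump HSMM: topologies, duration scales, and fit metadata."""

    n_bumps: int
    bump_magnitudes: np.ndarray  # (n_bumps, C)
    gamma_scales: np.ndarray  # (n_bumps + 1,) flat-duration scales (samples)
    condition_scales: dict[int, dict[int, float]] | None = None
    bump_width_samples: int = BUMP_WIDTH
    gamma_shape: float = GAMMA_SHAPE
    emission_var: float = 1.0
    log_likelihood: float = float("nan")
    loglik_path: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bump_magnitudes = np.atleast_2d(np.asarray(self.bump_magnitudes, float))
        self.gamma_scales = np.asarray(self.gamma_scales, dtype=float)
        if np.any(self.gamma_scales <= 0):
            raise ValueError("gamma scales must be positive")

    def scale_for(self, stage: int, condition: int | None) -> float:
        if self.condition_scales and stage in self.condition_scales:
            if condition is None:
                raise ValueError(f"stage {stage} needs a condition label")
            return self.condition_scales[stage][condition]
        return float(self.gamma_scales[stage])


@dataclass
class StageSegmentation:
    """MAP bump onsets and the stage durations they imply."""

    onsets: np.ndarray  # (N, n_bumps) sample of each bump onset
    stage_durations: np.ndarray  # (N, n_bumps + 1) bump + flat durations
    map_log_posterior: np.ndarray  # (N,) log posterior of the MAP placement


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_pca(
    epochs_by_subject: list[np.ndarray],
    lengths_by_subject: list[np.ndarray],
    fs_hz: float = 100.0,
    band_hz: tuple[float, float] = (1.0, 30.0),
    baseline_window_s: tuple[float, float] | None = None,
    var_target: float = 0.90,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Band-pass, baseline-correct, and project onto shared principal components.

    The channel covariance is computed per subject over in-trial samples,
    averaged across subjects, and eigendecomposed; enough components are
    retained to reach ``var_target`` explained variance. Scores are z-scored
    per component over each subject's concatenated trials.

    Returns ``(scores_by_subject, projection, explained_variance_ratio)``.
    """
    if not 0 < var_target <= 1:
        raise ValueError("var_target must lie in (0, 1]")
    sos = butter(4, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    filtered = []
    covs = []
    for epochs, lengths in zip(epochs_by_subject, lengths_by_subject):
        x = sosfiltfilt(sos, np.asarray(epochs, float), axis=-1)
        if baseline_window_s is not None:
            lo = int(round(baseline_window_s[0] * fs_hz))
            hi = int(round(baseline_window_s[1] * fs_hz))
            x = x - x[:, :, lo:hi].mean(axis=2, keepdims=True)
        filtered.append(x)
        samples = np.concatenate(
            [x[n, :, : int(t)] for n, t in enumerate(lengths)], axis=1
        )
        covs.append(np.cov(samples))
    mean_cov = np.mean(covs, axis=0)
    evals, evecs = np.linalg.eigh(mean_cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    ratio = evals / evals.sum()
    n_comp = int(np.searchsorted(np.cumsum(ratio), var_target) + 1)
    proj = evecs[:, :n_comp]
    scores = []
    for x, lengths in zip(filtered, lengths_by_subject):
        s = np.einsum("rc,nrt->nct", proj, x)
        flat = np.concatenate(
            [s[n, :, : int(t)] for n, t in enumerate(lengths)], axis=1
        )
        mu = flat.mean(axis=1)[None, :, None]
        sd = flat.std(axis=1)[None, :, None]
        scores.append((s - mu) / sd)
    return scores, proj, ratio[:n_comp]


# ---------------------------------------------------------------------------
# likelihood machinery


def _log_conv(log_w: np.ndarray, log_ker: np.ndarray, out_len: int) -> np.ndarray:
    """Log-space convolution along axis 1 via scaled FFT convolution.

    ``out[n, t] = logsumexp_u(log_w[n, u] + log_ker[t - u])``; rows that are
    all -inf stay all -inf.
    """
    mx = log_w.max(axis=1, keepdims=True)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    w = np.exp(log_w - safe)
    ker = np.exp(log_ker - log_ker.max(initial=_NEG_INF))
    conv = fftconvolve(w, ker[None, :], axes=1)[:, :out_len]
    conv = np.maximum(conv, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(conv) + safe + log_ker.max(initial=_NEG_INF)
    out[~np.isfinite(mx[:, 0])] = _NEG_INF
    return out


class _ModelEval:
    """Forward-backward quantities for one parameter setting on one data set."""

    def __init__(
        self,
        scores: np.ndarray,  # (N, C, T)
        lengths: np.ndarray,  # (N,)
        model: BumpModel,
        conditions: np.ndarray | None,
    ) -> None:
        self.scores = scores
        self.lengths = np.asarray(lengths, dtype=int)
        self.model = model
        n, c, t_max = scores.shape
        m = model.n_bumps
        width = model.bump_width_samples
        self.n, self.t_max, self.m, self.width = n, t_max, m, width
        self.conditions = (
            np.zeros(n, dtype=int) if conditions is None else np.asarray(conditions)
        )
        w = half_sine_window(width)
        var = model.emission_var
        # gain[n, k, t]: log-lik increment of placing bump k at onset t
        b = model.bump_magnitudes  # (m, C)
        proj = np.einsum("kc,nct->nkt", b, scores)  # (N, m, T)
        g_len = t_max - width + 1
        gain = np.zeros((n, max(m, 1), g_len))
        for p in range(width):
            gain += w[p] * proj[:, :, p : p + g_len]
        gain /= var
        gain -= (w**2).sum() * (b**2).sum(axis=1)[None, :, None] / (2.0 * var)
        # invalidate onsets too close to the trial end for the bump itself
        for i in range(n):
            lim = self.lengths[i] - width + 1
            gain[i, :, max(lim, 0) :] = _NEG_INF
        self.gain = gain
        # flat log-model constant per trial
        self.const = np.empty(n)
        for i in range(n):
            y = scores[i, :, : self.lengths[i]]
            self.const[i] = -0.5 * (y**2).sum() / var - 0.5 * y.size * math.log(
                2 * math.pi * var
            )

    def _log_kernels(self) -> dict[int, list[np.ndarray]]:
        """Per condition group: list of m+1 duration log-pmf vectors."""
        out: dict[int, list[np.ndarray]] = {}
        for cond in np.unique(self.conditions):
            out[int(cond)] = [
                discretized_gamma2_logpmf(
                    self.model.scale_for(s, int(cond)), self.t_max
                )
                for s in range(self.m + 1)
            ]
        return out

    def forward_backward(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (loglik per trial, F, B) with F/B of shape (m, N, G)."""
        m, n, width = self.m, self.n, self.width
        g_len = self.gain.shape[2]
        kernels = self._log_kernels()
        fwd = np.full((m, n, g_len), _NEG_INF)
        bwd = np.full((m, n, g_len), _NEG_INF)
        loglik = np.full(n, _NEG_INF)
        for cond, kers in kernels.items():
            rows = np.flatnonzero(self.conditions == cond)
            if rows.size == 0:
                continue
            # forward: F_0[t] = logpmf_0[t] + gain_0[t]  (first flat = t >= 1)
            f = kers[0][:g_len][None, :] + self.gain[rows, 0, :]
            fwd[0, rows] = f
            for k in range(1, m):
                # shift by bump width: flat duration = t - t' - width
                ker = np.full(g_len, _NEG_INF)
                ker[width:] = kers[k][: max(g_len - width, 0)]
                f = _log_conv(fwd[k - 1, rows], ker, g_len) + self.gain[rows, k, :]
                fwd[k, rows] = f
            # backward: B_{m-1}[t] = logpmf_m[T_n - t - width]
            last = np.full((rows.size, g_len), _NEG_INF)
            for ri, i in enumerate(rows):
                t_n = self.lengths[i]
                ts = np.arange(g_len)
                d = t_n - ts - width
                ok = (d >= 1) & (d <= self.t_max)
                last[ri, ok] = kers[m][d[ok]]
            bwd[m - 1, rows] = last
            for k in range(m - 2, -1, -1):
                ker = np.full(g_len, _NEG_INF)
                ker[width:] = kers[k + 1][: max(g_len - width, 0)]
                # reversed convolution: sum over t > t'
                nxt = bwd[k + 1, rows] + self.gain[rows, k + 1, :]
                rev = _log_conv(nxt[:, ::-1], ker, g_len)[:, ::-1]
                bwd[k, rows] = rev
            from scipy.special import logsumexp

            loglik[rows] = logsumexp(fwd[m - 1, rows] + bwd[m - 1, rows], axis=1)
        return self.const + loglik, fwd, bwd

    def loglik_flat_only(self) -> np.ndarray:
        """Log-likelihood of the 0-bump model (single flat spanning the trial)."""
        ker = {}
        ll = np.empty(self.n)
        for i in range(self.n):
            cond = int(self.conditions[i])
            if cond not in ker:
                ker[cond] = discretized_gamma2_logpmf(
                    self.model.scale_for(0, cond), self.t_max
                )
            ll[i] = self.const[i] + ker[cond][self.lengths[i]]
        return ll


# ---------------------------------------------------------------------------
# fitting


def _init_model(
    n_bumps: int,
    n_comp: int,
    mean_len: float,
    rng: np.random.Generator,
    condition_stages: tuple[int, ...],
    condition_values: np.ndarray,
) -> BumpModel:
    mags = 0.5 * rng.standard_normal((max(n_bumps, 1), n_comp))
    # scales from a uniform random partition of the mean trial length
    parts = rng.dirichlet(np.ones(n_bumps + 1))
    free = mean_len - BUMP_WIDTH * n_bumps
    scales = np.maximum(parts * free / GAMMA_SHAPE, MIN_SCALE)
    cond_scales = None
    if condition_stages:
        cond_scales = {
            s: {int(c): float(scales[s]) for c in condition_values}
            for s in condition_stages
        }
    return BumpModel(n_bumps, mags, scales, cond_scales)


def _em_iterations(
    ev: _ModelEval,
    max_iter: int,
    tol: float,
    update: bool = True,
    estimate_variance: bool = False,
) -> tuple[BumpModel, float, list[float]]:
    model = ev.model
    scores, lengths = ev.scores, ev.lengths
    n, _, t_max = scores.shape
    m, width = model.n_bumps, model.bump_width_samples
    w = half_sine_window(width)
    g_len = t_max - width + 1
    # half-sine-windowed data sums: wy[n, c, t] for onset t
    wy = np.zeros((n, scores.shape[1], g_len))
    for p in range(width):
        wy += w[p] * scores[:, :, p : p + g_len]
    path: list[float] = []
    total = float("nan")
    for it in range(max_iter):
        ll, fwd, bwd = ev.forward_backward()
        total = float(ll.sum())
        path.append(total)
        if not update:
            break
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol:
            break
        # posteriors over bump onsets (F/B exclude the flat-model constant)
        ll_core = ll - ev.const
        post = np.exp(fwd + bwd - ll_core[None, :, None])  # (m, N, G)
        post_sum = post.sum(axis=2)  # (m, N); ~1 per trial
        # magnitudes
        mags = np.empty_like(model.bump_magnitudes)
        wsq = (w**2).sum()
        for k in range(m):
            num = np.einsum("nt,nct->c", post[k], wy)
            den = wsq * post[k].sum()
            mags[k] = num / max(den, 1e-12)
        # expected bump onsets -> expected flat durations (linearity)
        t_idx = np.arange(g_len)
        e_on = np.einsum("knt,t->kn", post, t_idx) / np.maximum(post_sum, 1e-300)
        e_flat = np.empty((m + 1, n))
        e_flat[0] = e_on[0]
        for k in range(1, m):
            e_flat[k] = e_on[k] - e_on[k - 1] - width
        e_flat[m] = lengths - e_on[m - 1] - width
        scales = np.maximum(e_flat.mean(axis=1) / GAMMA_SHAPE, MIN_SCALE)
        var = model.emission_var
        if estimate_variance:
            # Gaussian MLE pooling flats and (posterior-weighted) bump samples
            sq = sum((scores[i, :, : lengths[i]] ** 2).sum() for i in range(n))
            cross = sum(
                np.einsum("nt,nct,c->", post[k], wy, mags[k]) for k in range(m)
            )
            bump_sq = (w**2).sum() * np.einsum(
                "kn,kc,kc->", post_sum, mags, mags
            )
            n_samples = scores.shape[1] * lengths.sum()
            var = max((sq - 2 * cross + bump_sq) / n_samples, 1e-6)
        cond_scales = None
        if model.condition_scales:
            cond_scales = {}
            for s in model.condition_scales:
                cond_scales[s] = {}
                for c in np.unique(ev.conditions):
                    rows = ev.conditions == c
                    cond_scales[s][int(c)] = float(
                        max(e_flat[s, rows].mean() / GAMMA_SHAPE, MIN_SCALE)
                    )
        model = BumpModel(
            m, mags, scales, cond_scales, width, GAMMA_SHAPE, var
        )
        ev.model = model
        ev.__init__(scores, lengths, model, ev.conditions)  # refresh gains
    return model, total, path


def fit_bump_hsmm(
    scores: np.ndarray,
    lengths: np.ndarray,
    n_bumps: int,
    n_starts: int = 200,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 0.05,
    conditions: np.ndarray | None = None,
    condition_stages: tuple[int, ...] = (),
    full_em_starts: bool = False,
    short_iters: int = 8,
    estimate_variance: bool = False,
) -> BumpModel:
    """Fit bump magnitudes and gamma scales by multi-start EM.

    ``scores`` is (N, C, T) z-scored component data with per-trial lengths.
    By default each random start runs a few EM iterations and only the most
    promising start (by log-likelihood) is run to convergence; with
    ``full_em_starts`` every start is run to convergence and the best kept.
    ``tol`` is the absolute log-likelihood change (nats) that stops EM.
    """
    scores = np.asarray(scores, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    min_len = n_bumps * BUMP_WIDTH + n_bumps + 1
    good = lengths > min_len
    if not np.all(good):
        warnings.warn(f"excluding {np.count_nonzero(~good)} trials shorter than "
                      f"{min_len + 1} samples")
        scores, lengths = scores[good], lengths[good]
        if conditions is not None:
            conditions = np.asarray(conditions)[good]
    if scores.shape[0] == 0:
        raise ValueError("no trial is long enough for this many bumps")
    conds = np.zeros(len(lengths), int) if conditions is None else np.asarray(conditions)

    if n_bumps == 0:
        scale = max(float(lengths.mean()) / GAMMA_SHAPE, MIN_SCALE)
        model = BumpModel(0, np.zeros((1, scores.shape[1])), np.array([scale]))
        ev = _ModelEval(scores, lengths, model, conds)
        model.log_likelihood = float(ev.loglik_flat_only().sum())
        return model

    rng = np.random.default_rng(seed)
    mean_len = float(lengths.mean())
    starts = [
        _init_model(n_bumps, scores.shape[1], mean_len, rng, tuple(condition_stages),
                    np.unique(conds))
        for _ in range(n_starts)
    ]
    results = []
    for m0 in starts:
        ev = _ModelEval(scores, lengths, m0, conds)
        iters = max_iter if full_em_starts else short_iters
        model, ll, path = _em_iterations(ev, iters, tol, estimate_variance=estimate_variance)
        results.append((ll, model, path))
    best_ll, best_model, best_path = max(results, key=lambda r: r[0])
    if not full_em_starts:
        ev = _ModelEval(scores, lengths, best_model, conds)
        best_model, best_ll, more = _em_iterations(
            ev, max_iter, tol, estimate_variance=estimate_variance
        )
        best_path = best_path + more[1:]
    best_model.log_likelihood = best_ll
    best_model.loglik_path = np.asarray(best_path)
    return best_model


def score_model(
    model: BumpModel,
    scores: np.ndarray,
    lengths: np.ndarray,
    conditions: np.ndarray | None = None,
) -> float:
    """Total log-likelihood of held-out data under a fitted model."""
    scores = np.asarray(scores, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    conds = np.zeros(len(lengths), int) if conditions is None else np.asarray(conditions)
    ev = _ModelEval(scores, lengths, model, conds)
    if model.n_bumps == 0:
        return float(ev.loglik_flat_only().sum())
    ll, _, _ = ev.forward_backward()
    return float(ll.sum())


def select_n_bumps(
    scores_by_subject: list[np.ndarray],
    lengths_by_subject: list[np.ndarray],
    candidate_range: range | list[int] = range(2, 7),
    n_starts: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, dict[tuple[int, int], float]]:
    """Choose the number of bumps by LOSO cross-validation and a sign test.

    For each candidate, the model is fitted on all-but-one subject and the
    held-out subject's log-likelihood recorded. Starting from the smallest
    candidate, the next larger model is adopted only while an exact
    two-sided binomial sign test says it fits significantly more subjects
    better (ties dropped). Returns the chosen count, the per-subject LOSO
    log-likelihood table, and consecutive-pair p-values.
    """
    candidates = sorted(candidate_range)
    if not candidates:
        raise ValueError("empty candidate range")
    n_subj = len(scores_by_subject)
    if n_subj < 6:
        warnings.warn("fewer than 6 subjects: the sign test has little power")
    table = np.empty((len(candidates), n_subj))
    for ci, m in enumerate(candidates):
        for held in range(n_subj):
            train_s = np.concatenate(
                [s for i, s in enumerate(scores_by_subject) if i != held], axis=0
            )
            train_l = np.concatenate(
                [l for i, l in enumerate(lengths_by_subject) if i != held]
            )
            model = fit_bump_hsmm(
                train_s, train_l, m, n_starts=n_starts,
                seed=seed + 1000 * m + held, **fit_kwargs,
            )
            table[ci, held] = score_model(
                model, scores_by_subject[held], lengths_by_subject[held]
            )
    df = pd.DataFrame(
        table, index=pd.Index(candidates, name="n_bumps"),
        columns=[f"subject_{i}" for i in range(n_subj)],
    )
    pvals: dict[tuple[int, int], float] = {}
    chosen = candidates[0]
    for ci in range(len(candidates) - 1):
        diff = table[ci + 1] - table[ci]
        better = int(np.sum(diff > 0))
        informative = int(np.sum(diff != 0))
        p = 1.0 if informative == 0 else binomtest(better, informative, 0.5).pvalue
        pvals[(candidates[ci], candidates[ci + 1])] = float(p)
        if p < alpha and better > informative / 2:
            chosen = candidates[ci + 1]
        else:
            break
    return chosen, df, pvals


def decode_onsets(
    model: BumpModel,
    scores: np.ndarray,
    lengths: np.ndarray,
    conditions: np.ndarray | None = None,
) -> StageSegmentation:
    """MAP bump placement per trial by Viterbi dynamic programming."""
    scores = np.asarray(scores, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    conds = np.zeros(len(lengths), int) if conditions is None else np.asarray(conditions)
    ev = _ModelEval(scores, lengths, model, conds)
    m, width = model.n_bumps, model.bump_width_samples
    if m == 0:
        raise ValueError("a 0-bump model has no onsets to decode")
    n, _, t_max = scores.shape
    g_len = ev.gain.shape[2]
    kernels = ev._log_kernels()
    onsets = np.zeros((n, m), dtype=int)
    logpost = np.zeros(n)
    ll, _, _ = ev.forward_backward()
    shift_mats: dict[tuple[int, int], np.ndarray] = {}
    for cond, kers in kernels.items():
        for k in range(1, m):
            ker = np.full(g_len, _NEG_INF)
            ker[width:] = kers[k][: max(g_len - width, 0)]
            shift_mats[(cond, k)] = _shift_matrix(ker, g_len)
    for i in range(n):
        cond = int(conds[i])
        kers = kernels[cond]
        v = kers[0][:g_len] + ev.gain[i, 0]
        back = np.zeros((m, g_len), dtype=int)
        for k in range(1, m):
            # score[t', t] = v[t'] + ker[t - t']
            mat = v[:, None] + shift_mats[(cond, k)]
            back[k] = np.argmax(mat, axis=0)
            v = mat[back[k], np.arange(g_len)] + ev.gain[i, k]
        d_last = lengths[i] - np.arange(g_len) - width
        ok = (d_last >= 1) & (d_last <= t_max)
        final = np.full(g_len, _NEG_INF)
        final[ok] = v[ok] + kers[m][d_last[ok]]
        t = int(np.argmax(final))
        best = final[t]
        path = [t]
        for k in range(m - 1, 0, -1):
            t = int(back[k][t])
            path.append(t)
        onsets[i] = path[::-1]
        logpost[i] = best + ev.const[i] - ll[i]
    bounds = np.concatenate(
        [np.zeros((n, 1), int), onsets, lengths[:, None]], axis=1
    )
    durations = np.diff(bounds, axis=1)
    return StageSegmentation(onsets, durations, logpost)


def _shift_matrix(ker: np.ndarray, g_len: int) -> np.ndarray:
    """Matrix K[t', t] = ker[t - t'] (with -inf outside the kernel support)."""
    mat = np.full((g_len, g_len), _NEG_INF)
    for tp in range(g_len):
        span = g_len - tp
        mat[tp, tp:] = ker[:span]
    return mat
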