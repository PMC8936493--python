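"""Synthetic connectomes and task-like epochs with known ground truth.

The task generator emulates the statistical structure assumed by the stage
model and the coordination measures: trials traverse a fixed sequence of
cognitive stages whose durations follow a gamma distribution with shape 2;
every stage after the first begins with a 50-ms multivariate amplitude bump
with a fixed cross-channel topology; within a stage, a theta-band carrier
realizes a prescribed region-pair phase-lag structure and a prescribed
envelope step at the stage onset. White sensor noise is added on top.
Everything is seed-deterministic, so each downstream module can be tested
for recovery against the exact generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectome import StructuralConnectome

__all__ = [
    "SynthTaskSpec",
    "SynthTaskResult",
    "synth_connectome",
    "synth_task_epochs",
    "synth_bump_scores",
    "synth_target_states",
    "ModelFixture",
    "synth_model_fixture",
]


@dataclass
class ModelFixture:
    """A self-contained pulse-switching study: model, truth, and targets."""

    connectome: StructuralConnectome
    params: object  # GwbmParams
    true_schedule: object  # PulseSchedule
    initial_histories: list
    targets: object  # TargetStateSet
    stage_durations_s: np.ndarray


def synth_model_fixture(
    n_regions: int = 16,
    n_stages: int = 2,
    n_pulsed: int = 8,
    l_max: float = 200.0,
    stage_duration_s: float = 0.3,
    n_replicates: int = 25,
    connectome_seed: int = 5,
    seed: int = 0,
    sign_threshold: float = 0.5,
):
    """Known-truth fixture for pulse recovery, lesioning, and relaxation.

    Builds a distance-dependent connectome with conduction delays, the
    reference couplings (G = 0.15, L = 0.7, theta-band center), a replicate
    ensemble started from a phase-aligned base state (mirroring the
    data-informed initialization, where theta phases are nearly aligned and
    link signs live in small consistent lags), and a ground-truth schedule
    pulsing ``n_pulsed`` random regions per stage with mixed-sign magnitudes
    in [0.3, 1] x l_max. The largest-magnitude pulse of each stage is made
    negative: inhibitory (order-parameter-collapsing) pulses are the
    mechanistically active kind, so the lesion analysis probes a pulse that
    can matter. Targets are generated from the true schedule itself.
    """
    from .connectome import compute_delays
    from .simulator import GwbmParams, PulseSchedule, RegionHistory, history_ensemble
    from .simulator import required_horizon

    con = compute_delays(synth_connectome(n_regions, seed=connectome_seed), 5.0)
    # couplings from the resting-state grid search on this connectome (the
    # metastability/autocorrelation trade-off point), mirroring the reference
    # protocol of tuning (G, L) to resting dynamics before the task
    params = GwbmParams(global_coupling=0.3, local_coupling=2.0)
    horizon = max(
        required_horizon(con, params.dt_s), int(round(0.07 / params.dt_s)) + 1
    )
    rng = np.random.default_rng(seed)
    delta_l = np.zeros((n_stages, n_regions))
    for s in range(n_stages):
        idx = rng.choice(n_regions, size=n_pulsed, replace=False)
        delta_l[s, idx] = rng.uniform(0.3 * l_max, l_max, n_pulsed) * rng.choice(
            [-1.0, 1.0], n_pulsed
        )
        biggest = idx[np.argmax(np.abs(delta_l[s, idx]))]
        delta_l[s, biggest] = -abs(delta_l[s, biggest])
    onsets = np.arange(n_stages) * stage_duration_s
    schedule = PulseSchedule(onsets_s=onsets, delta_L=delta_l, l_max=l_max)
    # phase-aligned base state rotating at the carrier frequency
    omega = float(np.atleast_1d(params.omega_rad_s)[0])
    t_grid = -(horizon - 1 - np.arange(horizon)) * params.dt_s
    r0 = rng.uniform(0.2, 0.5, n_regions)
    base = RegionHistory(
        np.repeat(r0[:, None], horizon, axis=1),
        (omega * t_grid[None, :] * np.ones((n_regions, 1)) + np.pi) % (2 * np.pi)
        - np.pi,
    )
    histories = history_ensemble(n_regions, horizon, n_replicates, rng, base=base)
    durations = np.full(n_stages, stage_duration_s)
    targets, _ = synth_target_states(
        con, params, schedule, durations,
        sign_threshold=sign_threshold, initial_histories=histories,
    )
    return ModelFixture(con, params, schedule, histories, targets, durations)


def synth_target_states(
    connectome: StructuralConnectome,
    params,
    true_schedule,
    stage_durations_s: Sequence[float],
    n_replicates: int = 25,
    seed: int = 0,
    sign_threshold: float = 0.5,
    initial_histories=None,
):
    """Targets generated by the model itself under a known schedule.

    Runs the stage-chained simulation protocol with ``true_schedule`` and
    packages the per-stage dpFC signatures and envelope changes as a target
    state set: links whose replicate-averaged mean phase-lag sign has
    magnitude at least ``sign_threshold`` keep their sign, the rest are set
    to 0 (a plain-threshold stand-in for surrogate significance masking,
    adequate because the generating truth is known). Enables
    self-consistency and pulse-recovery tests without any empirical data.

    Returns ``(targets, initial_histories)`` so the same replicate histories
    can be reused downstream.
    """
    from .fitness import TargetStateSet, simulate_stage
    from .simulator import history_ensemble, required_horizon

    durations = np.asarray(stage_durations_s, dtype=float)
    if durations.size != true_schedule.n_stages:
        raise ValueError("need one duration per schedule stage")
    horizon = max(
        required_horizon(connectome, params.dt_s),
        int(round(0.07 / params.dt_s)) + 1,
    )
    if initial_histories is None:
        rng = np.random.default_rng(seed)
        initial_histories = history_ensemble(
            connectome.n_regions, horizon, n_replicates, rng
        )
    histories = initial_histories
    n_stages = true_schedule.n_stages
    r = connectome.n_regions
    target_dpfc = np.zeros((n_stages, r, r))
    target_env = np.zeros((n_stages, r))
    for s in range(n_stages):
        dpfc_vals, env_change, tails = simulate_stage(
            connectome, params, histories, float(durations[s]),
            true_schedule.delta_L[s], true_schedule.l_max,
            pulse_duration_s=true_schedule.duration_s,
        )
        sign = np.sign(dpfc_vals)
        sign[np.abs(dpfc_vals) < sign_threshold] = 0.0
        target_dpfc[s] = sign
        target_env[s] = env_change
        histories = tails
    targets = TargetStateSet(target_dpfc, target_env, durations)
    return targets, initial_histories

BUMP_WIDTH_SAMPLES = 5
CARRIER_HZ = 6.0
HEAD_RADIUS_MM = 70.0


def synth_connectome(
    n_regions: int,
    density: float = 0.6,
    length_scale_mm: float = 60.0,
    seed: int = 0,
) -> StructuralConnectome:
    """Distance-dependent random connectome inside a head-sized sphere.

    Region centers are uniform in a 140-mm-diameter sphere; weights decay as
    exp(-distance/length_scale) and a random ``density`` fraction of links is
    kept. Lengths are Euclidean distances; weights are normalized to mean 1.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    # rejection-sample uniform points in the sphere
    pts = np.empty((n_regions, 3))
    got = 0
    while got < n_regions:
        cand = rng.uniform(-1, 1, size=(2 * n_regions, 3))
        cand = cand[np.sum(cand**2, axis=1) <= 1.0]
        take = min(len(cand), n_regions - got)
        pts[got : got + take] = cand[:take]
        got += take
    pts *= HEAD_RADIUS_MM
    diff = pts[:, None, :] - pts[None, :, :]
    lengths = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(lengths, 0.0)
    weights = np.exp(-lengths / length_scale_mm)
    np.fill_diagonal(weights, 0.0)
    iu, ju = np.triu_indices(n_regions, k=1)
    keep = rng.random(iu.size) < density
    if not keep.any():
        keep[rng.integers(iu.size)] = True  # never produce an empty graph
    drop = ~keep
    weights[iu[drop], ju[drop]] = 0.0
    weights[ju[drop], iu[drop]] = 0.0
    weights *= weights.size / weights.sum()
    labels = [f"synth_{i:03d}" for i in range(n_regions)]
    return StructuralConnectome(labels, weights, lengths)


def synth_bump_scores(
    n_trials: int = 200,
    n_bumps: int = 4,
    n_components: int = 10,
    magnitude: float = 2.0,
    components_per_bump: int = 2,
    noise_sigma: float = 1.0,
    stage_gamma_scales: Sequence[float] = (10.0, 7.0, 15.0, 10.0, 12.0),
    max_trial_samples: int = 250,
    seed: int = 0,
    bump_magnitudes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Component-space data sampled from the stage model's own assumptions.

    Each trial is a first flat followed by ``n_bumps`` (bump, flat) pairs;
    flat durations are gamma(shape 2) draws with the given per-stage scales;
    bumps are 5-sample half-sine modulations. Each bump loads a magnitude of
    ``magnitude`` on ``components_per_bump`` randomly chosen components with
    random signs (so the pattern norm is ``magnitude * sqrt(k)``); white unit
    noise is added on top. This is the natural recovery fixture for the
    stage-segmentation machinery: no mixing, filtering, or carrier.

    Returns ``(scores, lengths, true_onsets, bump_magnitudes)``.
    """
    if len(stage_gamma_scales) != n_bumps + 1:
        raise ValueError("need one gamma scale per stage (n_bumps + 1)")
    rng = np.random.default_rng(seed)
    if bump_magnitudes is not None:
        # shared topographies, e.g. across synthetic subjects
        mags = np.asarray(bump_magnitudes, dtype=float)
        if mags.shape != (n_bumps, n_components):
            raise ValueError("bump_magnitudes shape mismatch")
    else:
        mags = np.zeros((n_bumps, n_components))
        for k in range(n_bumps):
            idx = rng.choice(n_components, size=components_per_bump, replace=False)
            mags[k, idx] = magnitude * rng.choice([-1.0, 1.0], size=idx.size)
    w = np.sin(np.pi * (np.arange(BUMP_WIDTH_SAMPLES) + 0.5) / BUMP_WIDTH_SAMPLES)
    scales = np.asarray(stage_gamma_scales, dtype=float)
    scores = np.zeros((n_trials, n_components, max_trial_samples))
    onsets = np.zeros((n_trials, n_bumps), dtype=int)
    lengths = np.zeros(n_trials, dtype=int)
    for n in range(n_trials):
        for attempt in range(101):
            if attempt == 100:
                raise RuntimeError("stage durations kept exceeding the trial cap")
            d = np.maximum(1, np.rint(rng.gamma(2.0, scales)).astype(int))
            if d[0] + int(np.sum(d[1:] + BUMP_WIDTH_SAMPLES)) <= max_trial_samples:
                break
        t = d[0]
        for k in range(n_bumps):
            onsets[n, k] = t
            scores[n, :, t : t + BUMP_WIDTH_SAMPLES] += mags[k][:, None] * w[None, :]
            t += BUMP_WIDTH_SAMPLES + d[k + 1]
        lengths[n] = t
    scores += noise_sigma * rng.standard_normal(scores.shape)
    return scores, lengths, onsets, mags


def _default_lag_structure(
    n_stages: int, n_regions: int, rng: np.random.Generator,
    n_pairs: int = 3, lag_rad: float = 0.5,
) -> list[list[tuple[int, int, float]]]:
    structure = []
    for _ in range(n_stages):
        perm = rng.permutation(n_regions)
        pairs = []
        for k in range(min(n_pairs, n_regions // 2)):
            i, j = int(perm[2 * k]), int(perm[2 * k + 1])
            pairs.append((i, j, float(lag_rad * rng.choice([-1.0, 1.0]))))
        structure.append(pairs)
    return structure


def _default_env_steps(
    n_stages: int, n_regions: int, rng: np.random.Generator,
    n_active: int = 4, step: float = 0.5,
) -> np.ndarray:
    steps = np.zeros((n_stages, n_regions))
    for s in range(n_stages):
        idx = rng.choice(n_regions, size=min(n_active, n_regions), replace=False)
        steps[s, idx] = step * rng.choice([-1.0, 1.0], size=idx.size)
    return steps


@dataclass
class SynthTaskSpec:
    """Generating conditions for synthetic task epochs.

    ``stage_gamma_scales`` are the gamma(shape 2) scales of the *flat*
    durations in samples (the 5 bump samples are appended separately for
    stages after the first). ``bump_magnitudes`` rows live in a latent
    ``n_components``-dimensional pattern space mixed into regions through a
    random orthonormal map; by default each bump is a random direction of
    norm ``bump_amplitude``. ``lag_structure``/``env_steps`` default to
    sparse random per-stage patterns.
    """

    n_trials: int = 50
    n_regions: int = 16
    fs_hz: float = 100.0
    n_stages: int = 5
    stage_gamma_scales: Sequence[float] = (10.0, 7.0, 15.0, 10.0, 12.0)
    bump_magnitudes: np.ndarray | None = None
    n_components: int = 5
    bump_amplitude: float = 2.0
    lag_structure: list[list[tuple[int, int, float]]] | None = None
    env_steps: np.ndarray | None = None
    carrier_amplitude: float = 1.0
    noise_sigma: float = 1.0
    max_trial_s: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_gamma_scales) != self.n_stages:
            raise ValueError("need one gamma scale per stage")
        if np.any(np.asarray(self.stage_gamma_scales) <= 0):
            raise ValueError("gamma scales must be positive")


@dataclass
class SynthTaskResult:
    """Epochs plus the exact generating truth."""

    epochs: np.ndarray  # (N, R, T) raw signals
    onsets: np.ndarray  # (N, n_stages + 1): stimulus, bump onsets, response
    trial_lengths: np.ndarray  # (N,) response sample per trial
    flat_durations: np.ndarray  # (N, n_stages) true flat durations (samples)
    bump_magnitudes: np.ndarray  # (n_stages - 1, C) latent bump patterns
    mixing: np.ndarray  # (R, C) orthonormal latent-to-region map
    lag_structure: list[list[tuple[int, int, float]]]
    env_steps: np.ndarray  # (n_stages, R)
    fs_hz: float


def synth_task_epochs(spec: SynthTaskSpec) -> SynthTaskResult:
    """Generate multi-trial epochs following the stage/bump/lag/envelope model."""
    rng = np.random.default_rng(spec.seed)
    n_stages, n_reg = spec.n_stages, spec.n_regions
    fs = spec.fs_hz
    cap = int(round(spec.max_trial_s * fs))
    n_bumps = n_stages - 1

    if spec.bump_magnitudes is None:
        n_lat = min(spec.n_components, n_reg)
        dirs = rng.standard_normal((n_bumps, n_lat))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        bumps = spec.bump_amplitude * dirs
    else:
        bumps = np.asarray(spec.bump_magnitudes, dtype=float)
        if bumps.shape[0] != n_bumps:
            raise ValueError("need n_stages - 1 bump magnitude rows")
        if bumps.shape[1] > n_reg:
            raise ValueError("latent bump space larger than the region space")
    n_comp = bumps.shape[1]
    # random orthonormal mixing map region <- latent component
    q, _ = np.linalg.qr(rng.standard_normal((n_reg, n_comp)))
    mixing = q[:, :n_comp]

    lags = spec.lag_structure
    if lags is None:
        lags = _default_lag_structure(n_stages, n_reg, rng)
    env_steps = spec.env_steps
    if env_steps is None:
        env_steps = _default_env_steps(n_stages, n_reg, rng)
    env_steps = np.asarray(env_steps, dtype=float)

    # per-stage per-region carrier phase offsets realizing the lag structure
    offsets = np.zeros((n_stages, n_reg))
    for s, pairs in enumerate(lags):
        for i, j, lag in pairs:
            offsets[s, i] = lag
            offsets[s, j] = 0.0

    half_sine = np.sin(np.pi * (np.arange(BUMP_WIDTH_SAMPLES) + 0.5) / BUMP_WIDTH_SAMPLES)
    scales = np.asarray(spec.stage_gamma_scales, dtype=float)

    epochs = np.empty((spec.n_trials, n_reg, cap))
    onsets = np.zeros((spec.n_trials, n_stages + 1), dtype=int)
    lengths = np.zeros(spec.n_trials, dtype=int)
    flats = np.zeros((spec.n_trials, n_stages), dtype=int)

    for n in range(spec.n_trials):
        for attempt in range(101):
            if attempt == 100:
                raise RuntimeError("stage durations kept exceeding the epoch cap")
            d = np.maximum(1, np.rint(rng.gamma(2.0, scales)).astype(int))
            total = d[0] + int(np.sum(d[1:] + BUMP_WIDTH_SAMPLES))
            if total <= cap:
                break
        flats[n] = d
        bump_on = np.empty(n_bumps, dtype=int)
        t = d[0]
        for k in range(n_bumps):
            bump_on[k] = t
            t += BUMP_WIDTH_SAMPLES + d[k + 1]
        resp = t
        onsets[n, 0] = 0
        onsets[n, 1 : n_bumps + 1] = bump_on
        onsets[n, -1] = resp
        lengths[n] = resp

        # stage index per sample (bump samples belong to the new stage);
        # samples past the response keep the last stage's regime
        stage_of = np.full(cap, n_stages - 1, dtype=int)
        stage_of[: d[0]] = 0
        for k in range(n_bumps):
            end = bump_on[k + 1] if k + 1 < n_bumps else resp
            stage_of[bump_on[k] : end] = k + 1

        tvec = np.arange(cap) / fs
        # random per-trial carrier phase: ongoing theta is not stimulus-locked
        phase = (
            2 * np.pi * CARRIER_HZ * tvec[None, :]
            + offsets[stage_of, :].T
            + rng.uniform(-np.pi, np.pi)
        )
        env = spec.carrier_amplitude * (1.0 + env_steps[stage_of, :].T)
        sig = env * np.cos(phase)
        for k in range(n_bumps):
            pattern = mixing @ bumps[k]
            sl = slice(bump_on[k], bump_on[k] + BUMP_WIDTH_SAMPLES)
            sig[:, sl] += pattern[:, None] * half_sine[None, :]
        sig += spec.noise_sigma * rng.standard_normal((n_reg, cap))
        epochs[n] = sig

    return SynthTaskResult(
        epochs=epochs,
        onsets=onsets,
        trial_lengths=lengths,
        flat_durations=flats,
        bump_magnitudes=bumps,
        mixing=mixing,
        lag_structure=lags,
        env_steps=env_steps,
        fs_hz=fs,
    )
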