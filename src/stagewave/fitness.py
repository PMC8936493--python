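"""Target coordination states, the three-objective fitness, and stage evaluation.

A *target state set* holds, per cognitive stage: the signed significant
within-stage dpFC pattern (entries -1/0/+1), the empirical relative envelope
change at the stage onset, and the stage's median duration. A candidate
pulse schedule is scored against it with three objectives:

    f1 = sum_links x_i y_i / sum_links |x_i|        (dpFC sign agreement)
    f2 = Spearman(sim envelope change, target)       (local synchrony)
    f3 = (1/L_max) sum_j |dL_j| / sum_links |x_i|    (pulse economy)

combined as ``f = f1 - (1 - f2) * f3``: dpFC similarity dominates, and pulse
size is only penalized to the extent that the envelope fit is poor.

Stage evaluation mirrors the reference simulation protocol: per stage, a
small ensemble of replicates with different initial histories is integrated
for the stage's median duration with the stage pulse applied for 30 ms at
onset; simulated dpFC treats replicates as trials, the envelope proxy is the
order-parameter modulus itself, and each stage's replicates start from the
terminal samples of the previous stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .connectome import StructuralConnectome
from .simulator import (
    GwbmParams,
    GwbmTrajectory,
    PulseSchedule,
    RegionHistory,
    history_ensemble,
    random_history,
    required_horizon,
    simulate,
)

__all__ = [
    "TargetStateSet",
    "FitnessReport",
    "fitness_f1",
    "fitness_f2",
    "fitness_f3",
    "build_initial_history",
    "evaluate_schedule",
    "simulate_stage",
    "StageSimulator",
    "samplewise_f1_profile",
]

PULSE_DURATION_S = 0.03
PRE_ROLL_S = 0.1


@dataclass
class TargetStateSet:
    """Per-stage coordination targets the pulses must reach."""

    target_dpfc: np.ndarray  # (S, R, R) entries in {-1, 0, +1}, antisymmetric
    target_env_change: np.ndarray  # (S, R)
    median_durations_s: np.ndarray  # (S,)

    def __post_init__(self) -> None:
        self.target_dpfc = np.asarray(self.target_dpfc, dtype=float)
        self.target_env_change = np.atleast_2d(
            np.asarray(self.target_env_change, dtype=float)
        )
        self.median_durations_s = np.atleast_1d(
            np.asarray(self.median_durations_s, dtype=float)
        )
        if self.target_dpfc.ndim != 3:
            raise ValueError("target_dpfc must be stages x R x R")
        if not np.all(np.isin(self.target_dpfc, (-1.0, 0.0, 1.0))):
            raise ValueError("target_dpfc entries must be -1, 0 or +1")
        if np.abs(self.target_dpfc + self.target_dpfc.transpose(0, 2, 1)).max() > 0:
            raise ValueError("target_dpfc must be antisymmetric")
        if np.any(self.median_durations_s <= 0):
            raise ValueError("median durations must be positive")

    @property
    def n_stages(self) -> int:
        return self.target_dpfc.shape[0]

    @property
    def n_links(self) -> np.ndarray:
        """Per-stage count of nonzero target links (upper triangle)."""
        r = self.target_dpfc.shape[1]
        iu, ju = np.triu_indices(r, k=1)
        return np.count_nonzero(self.target_dpfc[:, iu, ju], axis=1)


@dataclass
class FitnessReport:
    """Three objectives and the combined index for one schedule evaluation."""

    f1: float
    f2: float
    f3: float
    combined: float
    per_stage_f1: np.ndarray = field(default_factory=lambda: np.zeros(0))
    per_stage_f2: np.ndarray = field(default_factory=lambda: np.zeros(0))
    per_stage_f3: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sim_dpfc_sign: np.ndarray | None = None  # (S, R, R)
    sim_env_change: np.ndarray | None = None  # (S, R)
    final_histories: list[RegionHistory] | None = None


def fitness_f1(sim_dpfc_sign: np.ndarray, target: np.ndarray) -> float:
    """Signed-link agreement between a simulated and a target dpFC pattern."""
    sim = np.asarray(sim_dpfc_sign, dtype=float)
    tgt = np.asarray(target, dtype=float)
    iu, ju = np.triu_indices(tgt.shape[0], k=1)
    x = tgt[iu, ju]
    y = sim[iu, ju]
    denom = np.abs(x).sum()
    if denom == 0:
        raise ValueError("target dpFC has no nonzero links")
    return float((x * y).sum() / denom)


def fitness_f2(sim_env_change: np.ndarray, target_env_change: np.ndarray) -> float:
    """Spearman rank correlation of simulated vs target envelope changes."""
    a = np.asarray(sim_env_change, dtype=float)
    b = np.asarray(target_env_change, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 regions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant envelope-change vector; Spearman set to 0")
        return 0.0
    rho = spearmanr(a, b).statistic
    return float(rho)


def fitness_f3(delta_l: np.ndarray, l_max: float, n_links: int) -> float:
    """Normalized total pulse size for one stage (Eq-6-style economy term)."""
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if n_links == 0:
        raise ValueError("cannot normalize by zero target links")
    return float(np.abs(delta_l).sum() / (l_max * n_links))


def combined_fitness(f1: float, f2: float, f3: float) -> float:
    return f1 - (1.0 - f2) * f3


def _dpfc_sign_values(phases: np.ndarray) -> np.ndarray:
    """Mean over time of sgn(sin(psi_i - psi_j)) -> (R, R) in [-1, 1]."""
    z = np.exp(1j * phases)
    s = np.einsum("it,jt->ijt", z, np.conj(z)).imag
    return np.sign(s).mean(axis=2)


def _env_change_windows(dt_s: float) -> tuple[np.ndarray, np.ndarray]:
    pre = np.arange(int(round(-0.060 / dt_s)), int(round(-0.010 / dt_s)) + 1)
    post = np.arange(0, int(round(0.050 / dt_s)) + 1)
    return pre, post


class StageSimulator:
    """Reusable stage-response evaluator for a fixed set of replicate histories.

    Pre-stacks the connectome and history arrays once so that repeated
    evaluations with different pulse vectors (the optimizer's inner loop)
    pay only the integration cost.
    """

    def __init__(
        self,
        connectome: StructuralConnectome,
        params: GwbmParams,
        histories: list[RegionHistory],
        duration_s: float,
        pre_roll_s: float = PRE_ROLL_S,
        pulse_duration_s: float = PULSE_DURATION_S,
    ) -> None:
        dt = params.dt_s
        n_regions = connectome.n_regions
        self.dsteps = np.rint(connectome.delays_s / dt).astype(np.int64)
        need = int(self.dsteps.max(initial=0)) + 1
        horizon = histories[0].horizon
        if horizon < need:
            raise ValueError("replicate histories shorter than the delay horizon")
        self.horizon = horizon
        self.onset = int(round(pre_roll_s / dt))
        self.pulse_steps = int(round(pulse_duration_s / dt))
        self.n_steps = int(round((pre_roll_s + duration_s) / dt))
        self.omega, self.delta, self.l_base = params.arrays(n_regions)
        self.pre_w, self.post_w = _env_change_windows(dt)
        if self.onset + self.pre_w[0] < -(horizon - 1):
            raise ValueError("pre-roll too short for the envelope pre-window")
        self.weights = np.ascontiguousarray(connectome.weights)
        self.r_hists = np.ascontiguousarray(
            np.stack([h.moduli[:, -horizon:] for h in histories])
        )
        self.psi_hists = np.ascontiguousarray(
            np.stack([h.phases[:, -horizon:] for h in histories])
        )
        self.params = params
        self.n_regions = n_regions
        self.n_replicates = len(histories)

    def respond(
        self, pulse: np.ndarray | None, with_tails: bool = True
    ) -> tuple[np.ndarray, np.ndarray, list[RegionHistory]]:
        from . import _kernels

        pulse_arr = (
            np.zeros(self.n_regions)
            if pulse is None
            else np.ascontiguousarray(pulse, dtype=float)
        )
        dpfc, env, r_tails, psi_tails, bad = _kernels.stage_response_batch(
            self.weights,
            self.dsteps,
            self.r_hists,
            self.psi_hists,
            self.omega,
            self.delta,
            self.l_base,
            float(self.params.global_coupling),
            self.params.dt_s,
            self.params.r_floor,
            self.n_steps,
            self.onset,
            self.onset + self.pulse_steps,
            pulse_arr,
            self.onset + self.pulse_steps,
            self.onset,
            self.pre_w,
            self.post_w,
            self.horizon,
        )
        if bad >= 0:
            raise RuntimeError(f"non-finite state at integration step {bad}")
        tails = (
            [
                RegionHistory(r_tails[b].copy(), psi_tails[b].copy())
                for b in range(self.n_replicates)
            ]
            if with_tails
            else []
        )
        return dpfc, env, tails


def simulate_stage(
    connectome: StructuralConnectome,
    params: GwbmParams,
    histories: list[RegionHistory],
    duration_s: float,
    pulse: np.ndarray | None,
    l_max: float = 20.0,
    pre_roll_s: float = PRE_ROLL_S,
    pulse_duration_s: float = PULSE_DURATION_S,
) -> tuple[np.ndarray, np.ndarray, list[RegionHistory]]:
    """Simulate one stage for every replicate history.

    Each replicate runs ``pre_roll_s`` seconds unperturbed, then the stage
    pulse is applied for ``pulse_duration_s`` at the stage onset, and the
    run continues for ``duration_s`` (the stage's median duration). Returns
    ``(dpfc_values, env_change, tail_histories)`` where ``dpfc_values`` is
    the replicate-averaged mean phase-lag sign over the stage flat (samples
    after the pulse window), ``env_change`` the replicate-averaged modulus
    change across the onset windows, and ``tail_histories`` the terminal
    replicate states for chaining the next stage.
    """
    sim = StageSimulator(
        connectome, params, histories, duration_s, pre_roll_s, pulse_duration_s
    )
    return sim.respond(pulse)


def evaluate_schedule(
    connectome: StructuralConnectome,
    params: GwbmParams,
    schedule: PulseSchedule,
    targets: TargetStateSet,
    n_replicates: int = 25,
    seed: int = 0,
    initial_histories: list[RegionHistory] | None = None,
    pre_roll_s: float = PRE_ROLL_S,
) -> FitnessReport:
    """Score a full multi-stage schedule against the targets.

    Stages are simulated in sequence; each stage's replicates start from the
    terminal samples of the previous stage's replicates. f1 and f2 are
    averaged over stages, f3 is summed, and the combined index is
    ``mean(f1) - (1 - mean(f2)) * sum(f3)``.
    """
    if schedule.n_stages != targets.n_stages:
        raise ValueError("schedule and targets disagree on the number of stages")
    horizon = max(
        required_horizon(connectome, params.dt_s),
        int(round(0.07 / params.dt_s)) + 1,  # envelope pre-window needs 60 ms
    )
    if initial_histories is None:
        rng = np.random.default_rng(seed)
        initial_histories = history_ensemble(
            connectome.n_regions, horizon, n_replicates, rng
        )
    histories = initial_histories
    s_count = targets.n_stages
    f1s = np.zeros(s_count)
    f2s = np.zeros(s_count)
    f3s = np.zeros(s_count)
    signs = np.zeros((s_count,) + targets.target_dpfc.shape[1:])
    envs = np.zeros((s_count, connectome.n_regions))
    n_links = targets.n_links
    for s in range(s_count):
        dpfc_vals, env_change, tails = simulate_stage(
            connectome,
            params,
            histories,
            float(targets.median_durations_s[s]),
            schedule.delta_L[s],
            schedule.l_max,
            pre_roll_s,
            schedule.duration_s,
        )
        sign = np.sign(dpfc_vals)
        signs[s] = sign
        envs[s] = env_change
        f1s[s] = fitness_f1(sign, targets.target_dpfc[s])
        f2s[s] = fitness_f2(env_change, targets.target_env_change[s])
        f3s[s] = fitness_f3(schedule.delta_L[s], schedule.l_max, int(n_links[s]))
        histories = tails
    f1, f2, f3 = float(f1s.mean()), float(f2s.mean()), float(f3s.sum())
    return FitnessReport(
        f1, f2, f3, combined_fitness(f1, f2, f3),
        f1s, f2s, f3s, signs, envs, histories,
    )


def samplewise_f1_profile(
    connectome: StructuralConnectome,
    params: GwbmParams,
    histories: list[RegionHistory],
    target: np.ndarray,
    duration_s: float,
    decimate: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise dpFC agreement with a target while the network relaxes.

    Each replicate history is integrated unpulsed for ``duration_s``; at
    every ``decimate``-th sample the across-replicate dpFC (mean sign of the
    instantaneous phase lags, the across-trial form of the statistic) is
    signed and scored against ``target`` with the link-agreement objective.
    Used to watch a pulse-established coordination state dissolve back to
    the unperturbed baseline.

    Returns ``(times_s, f1_series)``.
    """
    target = np.asarray(target, dtype=float)
    r = connectome.n_regions
    iu, ju = np.triu_indices(r, k=1)
    x = target[iu, ju]
    denom = np.abs(x).sum()
    if denom == 0:
        raise ValueError("target dpFC has no nonzero links")
    phases = []
    for hist in histories:
        traj = simulate(connectome, params, hist, duration_s)
        phases.append(traj.phases[:, ::decimate])
    stack = np.stack(phases)  # (B, R, T')
    dphi = stack[:, iu, :] - stack[:, ju, :]
    sign_vals = np.sign(np.sin(dphi)).mean(axis=0)  # (links, T')
    y = np.sign(sign_vals)
    f1_series = (x[:, None] * y).sum(axis=0) / denom
    times = np.arange(stack.shape[2]) * params.dt_s * decimate
    return times, f1_series


# ---------------------------------------------------------------------------
# initial histories from reference data


def _phase_consistency_pvals(
    phases_at: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> np.ndarray:
    """Surrogate p-values for inter-trial phase consistency per region.

    The statistic is the resultant length across trials; the null draws
    uniform phases for the same trial count.
    """
    n_trials, n_regions = phases_at.shape
    obs = np.abs(np.exp(1j * phases_at).mean(axis=0))
    null = np.abs(
        np.exp(1j * rng.uniform(-np.pi, np.pi, size=(n_surrogates, n_trials))).mean(
            axis=1
        )
    )
    return (1.0 + (null[:, None] >= obs[None, :]).sum(axis=0)) / (n_surrogates + 1.0)


def _phase_match_fraction(
    phases: np.ndarray, target: np.ndarray
) -> float:
    """Fraction of nonzero target links whose instantaneous lag sign matches."""
    iu, ju = np.triu_indices(phases.size, k=1)
    x = target[iu, ju]
    nz = x != 0
    if not nz.any():
        return 1.0
    s = np.sign(np.sin(phases[iu[nz]] - phases[ju[nz]]))
    return float(np.mean(s == x[nz]))


def _optimize_free_phases(
    phases: np.ndarray,
    free: np.ndarray,
    target: np.ndarray,
    rng: np.random.Generator,
    n_iter: int = 300,
    pop: int = 24,
) -> tuple[np.ndarray, float]:
    """(1+lambda) evolution strategy over the unconstrained phases."""
    best = phases.copy()
    best[free] = rng.uniform(-np.pi, np.pi, size=free.sum())
    best_score = _phase_match_fraction(best, target)
    sigma = 1.0
    for _ in range(n_iter):
        if best_score >= 1.0:
            break
        cand = np.repeat(best[None, :], pop, axis=0)
        cand[:, free] += sigma * rng.standard_normal((pop, free.sum()))
        scores = np.array([_phase_match_fraction(c, target) for c in cand])
        k = int(np.argmax(scores))
        if scores[k] >= best_score:
            improved = scores[k] > best_score
            best, best_score = cand[k], float(scores[k])
            sigma = min(sigma * (1.3 if improved else 1.0), np.pi)
        else:
            sigma = max(sigma * 0.85, 0.05)
    return best, best_score


def build_initial_history(
    reference_epochs,
    horizon: int,
    dt_s: float,
    pre_stage_dpfc_target: np.ndarray | None = None,
    consistency_alpha: float = 0.05,
    noise_sigma: float = 0.01,
    seed: int = 0,
    omega_rad_s: float | np.ndarray = 2 * np.pi * 6.0,
    n_surrogates: int = 200,
) -> tuple[RegionHistory, float]:
    """Build a simulation history from reference analytic epochs.

    The modulus history is a straight line joining the across-trial mean
    envelopes measured 0.10 s and 0.05 s before the onset of the first
    post-stimulus stage (rescaled to order-parameter range by the 95th
    envelope percentile), plus Gaussian noise. Phases of regions with
    significant inter-trial phase consistency at -0.05 s are fixed to their
    across-trial circular means (plus noise); the remaining phases are set
    by a derivative-free optimizer maximizing the fraction of target
    pre-stage dpFC link signs realized by the instantaneous phase lags. All
    phases rotate backwards through the history at the natural frequency.

    Returns ``(history, achieved_similarity)``.
    """
    rng = np.random.default_rng(seed)
    fs = reference_epochs.fs_hz
    onset1 = reference_epochs.stage_onsets[:, 1]
    t100 = onset1 - int(round(0.10 * fs))
    t50 = onset1 - int(round(0.05 * fs))
    if t100.min() < 0:
        raise ValueError("epochs lack 0.10 s of pre-onset data")
    n_trials = reference_epochs.n_trials
    n_regions = reference_epochs.n_regions
    idx = np.arange(n_trials)
    env = np.abs(reference_epochs.data)
    e100 = env[idx, :, t100].mean(axis=0)
    e50 = env[idx, :, t50].mean(axis=0)
    scale = np.percentile(env, 95)
    r100 = np.clip(e100 / scale, 0.02, 0.98)
    r50 = np.clip(e50 / scale, 0.02, 0.98)
    # straight line through (t=-0.05 s, r50) and (t=-0.10 s, r100), evaluated
    # on the horizon grid ending at t = 0
    t_grid = -(horizon - 1 - np.arange(horizon)) * dt_s
    frac = (t_grid + 0.10) / 0.05  # 0 at -0.10 s, 1 at -0.05 s
    moduli = r100[:, None] + (r50 - r100)[:, None] * frac[None, :]
    moduli += noise_sigma * rng.standard_normal(moduli.shape)
    moduli = np.clip(moduli, 0.0, 1.0)

    phase_at = np.angle(reference_epochs.data[idx, :, t50])
    pvals = _phase_consistency_pvals(phase_at, n_surrogates, rng)
    consistent = pvals < consistency_alpha
    circ_mean = np.angle(np.exp(1j * phase_at).mean(axis=0))
    phases0 = circ_mean.copy()
    similarity = float("nan")
    if not consistent.all():
        free = ~consistent
        if pre_stage_dpfc_target is None:
            if not consistent.any():
                warnings.warn(
                    "no region shows phase consistency and no target given; "
                    "falling back to random phases"
                )
            phases0[free] = rng.uniform(-np.pi, np.pi, size=free.sum())
        else:
            phases0, similarity = _optimize_free_phases(
                phases0, free, np.asarray(pre_stage_dpfc_target), rng
            )
    else:
        if pre_stage_dpfc_target is not None:
            similarity = _phase_match_fraction(phases0, np.asarray(pre_stage_dpfc_target))
    phases0 = phases0 + noise_sigma * rng.standard_normal(n_regions)
    omega = np.broadcast_to(np.asarray(omega_rad_s, dtype=float), (n_regions,))
    phases = phases0[:, None] + omega[:, None] * t_grid[None, :]
    phases = (phases + np.pi) % (2 * np.pi) - np.pi
    return RegionHistory(moduli, phases), similarity
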