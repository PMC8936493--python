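"""Delayed mean-field whole-brain model and its finite-oscillator oracle.

Each cortical region is an infinite pool of Kuramoto oscillators with
Lorentzian-distributed natural frequencies, reduced via the Ott-Antonsen
ansatz to a single complex order parameter ``z_i = r_i exp(i psi_i)``.
Regions interact through the structural weight matrix ``A`` with
fiber-length transmission delays ``tau_ij``:

    dr_i/dt  = -Delta_i r_i + (L_i/2) r_i (1 - r_i^2)
               + (G / 2R) (1 - r_i^2) sum_j A_ij r_j(t - tau_ij)
                                            cos(psi_j(t - tau_ij) - psi_i)
    dpsi_i/dt = Omega_i + (G / 2R) (r_i + 1/r_i) sum_j A_ij r_j(t - tau_ij)
                                            sin(psi_j(t - tau_ij) - psi_i)

``L_i`` is the local (within-region) coupling; transient "thalamocortical"
pulses add a signed increment to ``L_i`` during short windows. Integration is
first-order Euler with a ring of past states for the delayed reads, the
reference configuration of the model. Without between-region coupling the
modulus has the closed-form fixed point ``r* = sqrt(1 - 2 Delta / L)``
(stable when L > 2 Delta), which anchors the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .connectome import StructuralConnectome

__all__ = [
    "GwbmParams",
    "RegionHistory",
    "PulseSchedule",
    "GwbmTrajectory",
    "SimulationError",
    "random_history",
    "simulate",
    "simulate_micro_oracle",
    "metastability",
    "grid_search_resting",
]

THETA_CENTER_HZ = 6.0


class SimulationError(RuntimeError):
    """Numerical failure or inconsistent simulation configuration."""


def _per_region(value, n_regions: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_regions, float(arr))
    if arr.shape != (n_regions,):
        raise ValueError(f"expected scalar or ({n_regions},) vector, got {arr.shape}")
    return arr.copy()


@dataclass
class GwbmParams:
    """Model parameters; scalars broadcast to all regions.

    Defaults are the reference configuration: theta-band center 6 Hz,
    Lorentzian half-width ``Delta = 1``, local coupling ``L = 0.7``, global
    coupling ``G = 0.15``, Euler step 1 ms. ``r_floor`` guards the 1/r term
    in the phase equation only.
    """

    omega_rad_s: float | np.ndarray = 2.0 * np.pi * THETA_CENTER_HZ
    delta: float | np.ndarray = 1.0
    local_coupling: float | np.ndarray = 0.7
    global_coupling: float = 0.15
    dt_s: float = 0.001
    r_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if np.any(np.asarray(self.delta) <= 0):
            raise ValueError("delta must be positive")
        if not 0.0 < self.r_floor < 0.01:
            raise ValueError("r_floor must lie in (0, 0.01)")

    def arrays(self, n_regions: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            _per_region(self.omega_rad_s, n_regions),
            _per_region(self.delta, n_regions),
            _per_region(self.local_coupling, n_regions),
        )


@dataclass
class RegionHistory:
    """Past order-parameter states over the delay horizon; col -1 is t = 0."""

    moduli: np.ndarray  # (R, H)
    phases: np.ndarray  # (R, H)

    def __post_init__(self) -> None:
        self.moduli = np.atleast_2d(np.asarray(self.moduli, dtype=float))
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if self.moduli.shape != self.phases.shape:
            raise ValueError("moduli and phases shapes differ")
        if np.any(self.moduli < 0) or np.any(self.moduli > 1):
            raise ValueError("history moduli must lie in [0, 1]")

    @property
    def horizon(self) -> int:
        return self.moduli.shape[1]


def random_history(
    n_regions: int, horizon: int, rng: np.random.Generator
) -> RegionHistory:
    """Random initial history: per-region constant modulus U(0.1, 0.9), phase U(-pi, pi)."""
    r = rng.uniform(0.1, 0.9, size=n_regions)
    psi = rng.uniform(-np.pi, np.pi, size=n_regions)
    return RegionHistory(
        np.repeat(r[:, None], horizon, axis=1),
        np.repeat(psi[:, None], horizon, axis=1),
    )


def history_ensemble(
    n_regions: int,
    horizon: int,
    n_replicates: int,
    rng: np.random.Generator,
    noise_sigma: float = 0.01,
    base: RegionHistory | None = None,
) -> list[RegionHistory]:
    """Replicate histories: one shared base state plus small Gaussian jitter.

    Mirrors the task-simulation protocol, where all replicates start from
    the same data-informed state up to sigma = 0.01 noise; replicates must
    share their phase relationships for replicate-averaged phase-lag
    statistics to be meaningful.
    """
    if base is None:
        base = random_history(n_regions, horizon, rng)
    out = []
    for _ in range(n_replicates):
        moduli = np.clip(
            base.moduli + noise_sigma * rng.standard_normal(base.moduli.shape), 0, 1
        )
        phases = base.phases + noise_sigma * rng.standard_normal(base.phases.shape)
        out.append(RegionHistory(moduli, phases))
    return out


@dataclass
class PulseSchedule:
    """Per-stage transient local-coupling increments ("thalamocortical pulses").

    ``delta_L[s, i]`` is added to region i's local coupling during
    ``[onsets_s[s], onsets_s[s] + duration_s)``.
    """

    onsets_s: np.ndarray  # (S,)
    delta_L: np.ndarray  # (S, R)
    duration_s: float = 0.03
    l_max: float = 20.0

    def __post_init__(self) -> None:
        self.onsets_s = np.atleast_1d(np.asarray(self.onsets_s, dtype=float))
        self.delta_L = np.atleast_2d(np.asarray(self.delta_L, dtype=float))
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.onsets_s.size != self.delta_L.shape[0]:
            raise ValueError("one onset per stage required")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(np.abs(self.delta_L) > self.l_max + 1e-12):
            raise ValueError("|delta_L| exceeds l_max")

    @property
    def n_stages(self) -> int:
        return self.delta_L.shape[0]


@dataclass
class GwbmTrajectory:
    """Per-region order-parameter time series from one simulation replicate."""

    times_s: np.ndarray  # (T,)
    moduli: np.ndarray  # (R, T)
    phases: np.ndarray  # (R, T)
    params_used: GwbmParams
    seed: int | None = None

    @property
    def n_regions(self) -> int:
        return self.moduli.shape[0]

    def tail_history(self, horizon: int) -> RegionHistory:
        """Terminal window of the trajectory, usable to chain a next simulation."""
        if self.moduli.shape[1] < horizon:
            raise ValueError("trajectory shorter than requested horizon")
        return RegionHistory(
            self.moduli[:, -horizon:].copy(), self.phases[:, -horizon:].copy()
        )


def _delay_steps(connectome: StructuralConnectome, dt_s: float) -> np.ndarray:
    return np.rint(connectome.delays_s / dt_s).astype(np.int64)


def required_horizon(connectome: StructuralConnectome, dt_s: float) -> int:
    """Number of history samples (incl. the t=0 state) needed for the delays."""
    return int(_delay_steps(connectome, dt_s).max(initial=0)) + 1


def _schedule_steps(
    schedule: PulseSchedule | None, dt_s: float, n_regions: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if schedule is None:
        return (
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.zeros((0, n_regions)),
        )
    if schedule.delta_L.shape[1] != n_regions:
        raise ValueError("schedule delta_L region count mismatch")
    start = np.rint(schedule.onsets_s / dt_s).astype(np.int64)
    stop = np.rint((schedule.onsets_s + schedule.duration_s) / dt_s).astype(np.int64)
    return start, stop, np.asarray(schedule.delta_L, dtype=float)


def simulate(
    connectome: StructuralConnectome,
    params: GwbmParams,
    history: RegionHistory,
    duration_s: float,
    schedule: PulseSchedule | None = None,
    seed: int | None = None,
) -> GwbmTrajectory:
    """Integrate the delayed mean-field network for ``duration_s`` seconds.

    The returned trajectory includes the t = 0 state, so it has
    ``round(duration_s / dt) + 1`` samples. Deterministic: all randomness
    lives in the initial ``history``.
    """
    n_regions = connectome.n_regions
    dt = params.dt_s
    if duration_s < dt:
        raise ValueError("duration_s must be at least one integration step")
    dsteps = _delay_steps(connectome, dt)
    need = int(dsteps.max(initial=0)) + 1
    if history.horizon < need:
        raise SimulationError(
            f"history horizon {history.horizon} < {need} samples required by delays"
        )
    if history.moduli.shape[0] != n_regions:
        raise SimulationError("history region count mismatch")
    n_steps = int(round(duration_s / dt))
    omega, delta, l_base = params.arrays(n_regions)
    p_start, p_stop, p_dl = _schedule_steps(schedule, dt, n_regions)
    r_hist = history.moduli[:, -need:]
    psi_hist = history.phases[:, -need:]
    r_buf, psi_buf, bad = _kernels.integrate_reduced(
        np.ascontiguousarray(connectome.weights),
        dsteps,
        np.ascontiguousarray(r_hist),
        np.ascontiguousarray(psi_hist),
        omega,
        delta,
        l_base,
        float(params.global_coupling),
        dt,
        params.r_floor,
        n_steps,
        p_start,
        p_stop,
        p_dl,
    )
    if bad >= 0:
        raise SimulationError(f"non-finite state at integration step {bad}")
    times = np.arange(n_steps + 1) * dt
    return GwbmTrajectory(
        times, r_buf[:, need - 1 :], psi_buf[:, need - 1 :], params, seed
    )


def simulate_micro_oracle(
    connectome: StructuralConnectome,
    params: GwbmParams,
    n_oscillators_per_region: int,
    duration_s: float,
    seed: int,
    history: RegionHistory | None = None,
    init_phase_spread: float = 1.0,
) -> GwbmTrajectory:
    """Integrate the full finite-N Kuramoto network-of-networks.

    Serves as an independent oracle for :func:`simulate`: per-region order
    parameters of the finite network converge to the mean-field trajectories
    as N grows. Natural frequencies are Lorentzian(Omega_i, Delta_i) draws.
    Initial oscillator phases are drawn around the (optional) history's t=0
    phases with circular spread chosen to match its moduli; with no history,
    phases are spread to match modulus ~0.5.
    """
    if n_oscillators_per_region < 100:
        raise ValueError("use at least 100 oscillators per region")
    n_regions = connectome.n_regions
    dt = params.dt_s
    rng = np.random.default_rng(seed)
    omega, delta, l_base = params.arrays(n_regions)
    # Lorentzian draws via inverse CDF of the Cauchy distribution
    u = rng.random((n_regions, n_oscillators_per_region))
    nat = omega[:, None] + delta[:, None] * np.tan(np.pi * (u - 0.5))

    dsteps = _delay_steps(connectome, dt)
    need = int(dsteps.max(initial=0)) + 1
    if history is None:
        psi0 = np.zeros(n_regions)
        r0 = np.full(n_regions, 0.5)
        r_hist = np.repeat(r0[:, None], need, axis=1)
        psi_hist = np.repeat(psi0[:, None], need, axis=1)
    else:
        if history.horizon < need:
            raise SimulationError("history horizon too short for delays")
        r_hist = history.moduli[:, -need:].copy()
        psi_hist = history.phases[:, -need:].copy()
        psi0 = psi_hist[:, -1]
        r0 = r_hist[:, -1]
    # wrapped-normal spread sigma with mean resultant length r0: r = exp(-s^2/2)
    sigma = np.sqrt(-2.0 * np.log(np.clip(r0, 1e-6, 1 - 1e-9)))
    theta0 = psi0[:, None] + init_phase_spread * sigma[:, None] * rng.standard_normal(
        (n_regions, n_oscillators_per_region)
    )
    theta0 = (theta0 + np.pi) % (2 * np.pi) - np.pi

    n_steps = int(round(duration_s / dt))
    r_buf, psi_buf = _kernels.integrate_micro(
        np.ascontiguousarray(connectome.weights),
        dsteps,
        theta0,
        nat,
        np.ascontiguousarray(r_hist),
        np.ascontiguousarray(psi_hist),
        l_base,
        float(params.global_coupling),
        dt,
        n_steps,
    )
    times = np.arange(n_steps + 1) * dt
    return GwbmTrajectory(
        times, r_buf[:, need - 1 :], psi_buf[:, need - 1 :], params, seed
    )


def _acf_abs_mean(x: np.ndarray) -> float:
    """Mean absolute autocorrelation over lags 1..T-1 (0 for constant series)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        return 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n]
    acf = acov / denom
    return float(np.mean(np.abs(acf[1:])))


def metastability(
    trajectory: GwbmTrajectory,
) -> tuple[np.ndarray, float, float, float]:
    """Local and global metastability of a trajectory.

    Returns ``(local, local_mean, global_meta, global_acf_mean)``: per-region
    temporal std of the modulus, its mean over regions, the temporal std of
    the global order parameter's modulus (global synchrony computed from the
    mean of unit phasors across regions), and the mean absolute
    autocorrelation of that global-modulus series.
    """
    r = trajectory.moduli
    if r.shape[1] < 2:
        raise ValueError("need at least 2 samples to measure metastability")
    local = r.std(axis=1)
    global_mod = np.abs(np.exp(1j * trajectory.phases).mean(axis=0))
    return (
        local,
        float(local.mean()),
        float(global_mod.std()),
        _acf_abs_mean(global_mod),
    )


def global_modulus(trajectory: GwbmTrajectory, amplitude_weighted: bool = False) -> np.ndarray:
    """Modulus of the global order parameter over time.

    By default phases only (mean of unit phasors across regions); optionally
    amplitude-weighted (mean of the regional complex order parameters).
    """
    z = np.exp(1j * trajectory.phases)
    if amplitude_weighted:
        z = trajectory.moduli * z
    return np.abs(z.mean(axis=0))


def grid_search_resting(
    connectome: StructuralConnectome,
    g_values: Sequence[float],
    l_values: Sequence[float],
    n_replicates: int,
    duration_s: float,
    burn_in_s: float,
    seed: int,
    params: GwbmParams | None = None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Characterize resting-state metastability over a (G, L) grid.

    For each pair, ``n_replicates`` runs from random initial histories are
    simulated for ``duration_s`` seconds; the first ``burn_in_s`` seconds are
    discarded before measuring metastability, and metrics are averaged over
    replicates. The selected pair maximizes a rank-sum trade-off score: high
    local and global metastability, low autocorrelation of global synchrony,
    ties resolved toward the smallest (G, L).
    """
    g_values = list(g_values)
    l_values = list(l_values)
    if not g_values or not l_values:
        raise ValueError("empty parameter grid")
    if burn_in_s >= duration_s:
        raise ValueError("burn_in_s must be smaller than duration_s")
    base = params or GwbmParams()
    horizon = required_horizon(connectome, base.dt_s)
    burn = int(round(burn_in_s / base.dt_s))
    rows = []
    for gi, g in enumerate(g_values):
        for li, lv in enumerate(l_values):
            p = GwbmParams(
                omega_rad_s=base.omega_rad_s,
                delta=base.delta,
                local_coupling=lv,
                global_coupling=g,
                dt_s=base.dt_s,
                r_floor=base.r_floor,
            )
            mets = np.zeros((n_replicates, 3))
            for rep in range(n_replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, gi, li, rep])
                )
                hist = random_history(connectome.n_regions, horizon, rng)
                traj = simulate(connectome, p, hist, duration_s)
                traj = GwbmTrajectory(
                    traj.times_s[burn:], traj.moduli[:, burn:],
                    traj.phases[:, burn:], p,
                )
                _, lm, gm, ga = metastability(traj)
                mets[rep] = (lm, gm, ga)
            m = mets.mean(axis=0)
            rows.append(
                dict(G=g, L=lv, local_mean_meta=m[0], global_meta=m[1],
                     global_acf_mean=m[2])
            )
    table = pd.DataFrame(rows)
    score = (
        table.local_mean_meta.rank(ascending=False)
        + table.global_meta.rank(ascending=False)
        + table.global_acf_mean.rank(ascending=True)
    )
    order = np.lexsort((table.L.values, table.G.values, score.values))
    best = table.iloc[order[0]]
    return table, (float(best.G), float(best.L))
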