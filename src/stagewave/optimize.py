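"""Island-model differential evolution of per-region stage-onset pulses.

Stages are optimized sequentially: each stage's decision vector is the
R-vector of signed local-coupling increments applied at that stage's onset,
bounded by ``l_max``; once a stage's best pulse is selected, the terminal
samples of its replicate simulations initialize the next stage. Islands are
connected in a ring, each running differential evolution with its own
(F, CR, mutation-variant) setting, exchanging their best individuals
periodically. Selection uses greedy replacement, so the per-island best
fitness is non-decreasing across generations. The final pick per stage is
the individual with minimal (1 - f2) * f3 among the top-K individuals by
combined fitness, which guards against solutions with good dpFC agreement
but poor envelope fit and large pulses. Every evaluated individual is kept
in an archive for ensemble analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import StructuralConnectome
from .fitness import (
    PRE_ROLL_S,
    PULSE_DURATION_S,
    StageSimulator,
    TargetStateSet,
    combined_fitness,
    fitness_f1,
    fitness_f2,
    fitness_f3,
    simulate_stage,
)
from .simulator import (
    GwbmParams,
    PulseSchedule,
    RegionHistory,
    history_ensemble,
    random_history,
    required_horizon,
)

__all__ = ["optimize_pulses", "ensemble_pick", "OptimizationResult", "DE_ISLAND_SETTINGS"]

# Per-island DE control parameters: (F, CR, variant). Islands cycle through
# this table; the set spans exploratory (high F, rand-base) and exploitative
# (best-base, low CR) configurations.
DE_ISLAND_SETTINGS: list[tuple[float, float, str]] = [
    (0.5, 0.9, "rand1"),
    (0.5, 0.3, "best1"),
    (0.8, 0.9, "rand1"),
    (0.6, 0.9, "best1"),
    (0.9, 0.5, "rand1"),
    (0.5, 0.5, "best1"),
    (0.7, 0.1, "rand1"),
    (0.4, 0.7, "best1"),
    (1.0, 0.9, "rand1"),
    (0.6, 0.5, "rand1"),
]


@dataclass
class OptimizationResult:
    best_schedule: PulseSchedule
    archive: pd.DataFrame  # one row per evaluated individual
    best_fitness_path: np.ndarray  # (S, generations + 1) best combined f
    initial_histories: list[RegionHistory]


def _stage_objective(
    connectome,
    params,
    histories,
    duration_s,
    target_dpfc,
    target_env,
    n_links,
    l_max,
    pre_roll_s,
    pulse_duration_s,
):
    sim = StageSimulator(
        connectome, params, histories, duration_s, pre_roll_s, pulse_duration_s
    )

    def evaluate(x: np.ndarray) -> tuple[float, float, float, float]:
        dpfc_vals, env_change, _ = sim.respond(x, with_tails=False)
        f1 = fitness_f1(np.sign(dpfc_vals), target_dpfc)
        f2 = fitness_f2(env_change, target_env)
        f3 = fitness_f3(x, l_max, n_links)
        return f1, f2, f3, combined_fitness(f1, f2, f3)

    return evaluate


def optimize_pulses(
    connectome: StructuralConnectome,
    params: GwbmParams,
    targets: TargetStateSet,
    l_max: float = 20.0,
    islands: int = 10,
    pop_per_island: int = 50,
    generations: int = 100,
    migration_interval: int = 10,
    n_replicates: int = 25,
    seed: int = 0,
    initial_histories: list[RegionHistory] | None = None,
    top_k: int = 5000,
    pre_roll_s: float = PRE_ROLL_S,
    pulse_duration_s: float = PULSE_DURATION_S,
) -> OptimizationResult:
    """Optimize the per-stage pulse vectors against the target states."""
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if islands < 1 or pop_per_island < 4:
        raise ValueError("need at least 1 island and 4 individuals per island")
    n_regions = connectome.n_regions
    horizon = max(
        required_horizon(connectome, params.dt_s),
        int(round(0.07 / params.dt_s)) + 1,
    )
    if initial_histories is None:
        rng0 = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        initial_histories = history_ensemble(n_regions, horizon, n_replicates, rng0)
    histories = initial_histories
    n_stages = targets.n_stages
    n_links = targets.n_links
    archive_rows: list[dict] = []
    best_paths = np.zeros((n_stages, generations + 1))
    best_pulses = np.zeros((n_stages, n_regions))

    for s in range(n_stages):
        evaluate = _stage_objective(
            connectome, params, histories, float(targets.median_durations_s[s]),
            targets.target_dpfc[s], targets.target_env_change[s], int(n_links[s]),
            l_max, pre_roll_s, pulse_duration_s,
        )
        stage_rows: list[dict] = []

        def record(x, fits):
            f1, f2, f3, f = fits
            stage_rows.append(
                dict(stage=s, f1=f1, f2=f2, f3=f3, f=f,
                     **{f"dl_{i}": x[i] for i in range(n_regions)})
            )

        rngs = [
            np.random.default_rng(np.random.SeedSequence([seed, s + 1, isl]))
            for isl in range(islands)
        ]
        pops = []
        fits = []
        for isl in range(islands):
            pop = rngs[isl].uniform(-l_max, l_max, size=(pop_per_island, n_regions))
            fit = [evaluate(x) for x in pop]
            for x, ft in zip(pop, fit):
                record(x, ft)
            pops.append(pop)
            fits.append(np.array([ft[3] for ft in fit]))
        best_paths[s, 0] = max(f.max() for f in fits)

        for gen in range(1, generations + 1):
            for isl in range(islands):
                f_de, cr, variant = DE_ISLAND_SETTINGS[isl % len(DE_ISLAND_SETTINGS)]
                rng = rngs[isl]
                pop, fvals = pops[isl], fits[isl]
                ibest = int(np.argmax(fvals))
                for i in range(pop_per_island):
                    choices = rng.choice(pop_per_island - 1, size=3, replace=False)
                    choices[choices >= i] += 1  # never the current individual
                    a, b, c = pop[choices]
                    base = pop[ibest] if variant == "best1" else a
                    mutant = np.clip(base + f_de * (b - c), -l_max, l_max)
                    cross = rng.random(n_regions) < cr
                    cross[rng.integers(n_regions)] = True
                    child = np.where(cross, mutant, pop[i])
                    child_fit = evaluate(child)
                    record(child, child_fit)
                    if child_fit[3] >= fvals[i]:
                        pop[i] = child
                        fvals[i] = child_fit[3]
                ibest = int(np.argmax(fvals))
            if gen % migration_interval == 0 and islands > 1:
                bests = [pops[k][int(np.argmax(fits[k]))].copy() for k in range(islands)]
                best_f = [float(fits[k].max()) for k in range(islands)]
                for k in range(islands):
                    tgt = (k + 1) % islands
                    worst = int(np.argmin(fits[tgt]))
                    if best_f[k] > fits[tgt][worst]:
                        pops[tgt][worst] = bests[k]
                        fits[tgt][worst] = best_f[k]
            best_paths[s, gen] = max(f.max() for f in fits)

        stage_df = pd.DataFrame(stage_rows)
        k = min(top_k, len(stage_df))
        top = stage_df.nlargest(k, "f")
        pick = top.assign(_res=(1.0 - top.f2) * top.f3).nsmallest(1, "_res").iloc[0]
        best_pulses[s] = pick[[f"dl_{i}" for i in range(n_regions)]].to_numpy(float)
        archive_rows.extend(stage_rows)
        # chain: terminal samples of the best individual's replicates
        _, _, tails = simulate_stage(
            connectome, params, histories, float(targets.median_durations_s[s]),
            best_pulses[s], l_max, pre_roll_s, pulse_duration_s,
        )
        histories = tails

    onsets = np.concatenate([[0.0], np.cumsum(targets.median_durations_s[:-1])])
    schedule = PulseSchedule(
        onsets_s=onsets, delta_L=best_pulses,
        duration_s=pulse_duration_s, l_max=l_max,
    )
    return OptimizationResult(
        schedule, pd.DataFrame(archive_rows), best_paths, initial_histories
    )


def ensemble_pick(
    archive: pd.DataFrame,
    targets: TargetStateSet,
    l_max: float = 20.0,
    top_fraction: float = 0.01,
    n_picks: int = 1000,
    seed: int = 0,
    pulse_duration_s: float = PULSE_DURATION_S,
) -> list[PulseSchedule]:
    """Random sample of schedules from the top fraction of the archive.

    For each stage the pool is the top ``top_fraction`` of that stage's
    evaluated individuals by combined fitness (at least one); picks combine
    independently sampled per-stage pulses. Pools smaller than ``n_picks``
    are sampled with replacement.
    """
    if archive.empty:
        raise ValueError("empty archive")
    rng = np.random.default_rng(seed)
    dl_cols = [c for c in archive.columns if c.startswith("dl_")]
    stage_picks = []
    for s in range(targets.n_stages):
        stage_df = archive[archive.stage == s]
        n_pool = max(1, int(np.ceil(top_fraction * len(stage_df))))
        pool = stage_df.nlargest(n_pool, "f")[dl_cols].to_numpy(float)
        replace = len(pool) < n_picks
        idx = rng.choice(len(pool), size=n_picks, replace=replace)
        stage_picks.append(pool[idx])
    onsets = np.concatenate([[0.0], np.cumsum(targets.median_durations_s[:-1])])
    return [
        PulseSchedule(
            onsets_s=onsets,
            delta_L=np.stack([stage_picks[s][p] for s in range(targets.n_stages)]),
            duration_s=pulse_duration_s,
            l_max=l_max,
        )
        for p in range(n_picks)
    ]
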