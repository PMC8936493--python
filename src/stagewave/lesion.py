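"""Region relevance for coordination-state switches via pulse lesions.

A region's pulse at one stage is "lesioned" (set to zero) while everything
else — including the replicate initial histories — is held fixed, and the
lesioned model's within-stage dpFC signature is compared to the full
model's. Relevance is the fraction of target links that the full model
matched but the lesioned model lost. A region with a zero pulse is a no-op
lesion and has relevance exactly 0. Relevance is then regressed on simple
per-region predictors: the absolute pulse size, and its interaction with
the log-scaled structural node strength.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectome import StructuralConnectome
from .fitness import PRE_ROLL_S, StageSimulator, TargetStateSet
from .simulator import (
    GwbmParams,
    PulseSchedule,
    RegionHistory,
    history_ensemble,
    required_horizon,
)

__all__ = ["RelevanceMap", "lesion_region", "relevance_map", "regress_relevance"]


@dataclass
class RelevanceMap:
    """Per-(stage, region) relevance of pulses for reaching the targets."""

    relevance: np.ndarray  # (S, R) non-negative
    matched_full: np.ndarray  # (S,) links matched by the full model
    model_id: int = 0


def lesion_region(schedule: PulseSchedule, stage: int, region: int) -> PulseSchedule:
    """Copy of the schedule with one (stage, region) pulse set to zero."""
    s_count, r_count = schedule.delta_L.shape
    if not (0 <= stage < s_count and 0 <= region < r_count):
        raise IndexError(f"(stage={stage}, region={region}) out of range")
    delta = schedule.delta_L.copy()
    delta[stage, region] = 0.0
    return dc_replace(schedule, delta_L=delta)


def _stage_match_mask(
    sim_sign: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Boolean upper-triangle mask of nonzero target links the simulation matches."""
    r = target.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    x = target[iu, ju]
    y = sim_sign[iu, ju]
    return (x != 0) & (y == x)


def relevance_map(
    connectome: StructuralConnectome,
    params: GwbmParams,
    schedule: PulseSchedule,
    targets: TargetStateSet,
    n_replicates: int = 25,
    seed: int = 0,
    initial_histories: list[RegionHistory] | None = None,
    model_id: int = 0,
    pre_roll_s: float = PRE_ROLL_S,
) -> RelevanceMap:
    """Relevance of every (stage, region) pulse under identical initial states.

    The full schedule is evaluated stage by stage (chained); for each stage,
    every region's pulse is zeroed in turn and only that stage re-simulated
    from the same pre-stage histories, so the lesion is the only difference.
    Relevance = (#links matched by the full model but not the lesioned one)
    / (#links matched by the full model at that stage).
    """
    n_stages, n_regions = schedule.delta_L.shape
    if targets.n_stages != n_stages:
        raise ValueError("schedule and targets disagree on stage count")
    horizon = max(
        required_horizon(connectome, params.dt_s),
        int(round(0.07 / params.dt_s)) + 1,
    )
    if initial_histories is None:
        rng = np.random.default_rng(seed)
        initial_histories = history_ensemble(n_regions, horizon, n_replicates, rng)
    histories = initial_histories
    relevance = np.zeros((n_stages, n_regions))
    matched_counts = np.zeros(n_stages, dtype=int)
    for s in range(n_stages):
        duration = float(targets.median_durations_s[s])
        sim = StageSimulator(
            connectome, params, histories, duration, pre_roll_s, schedule.duration_s
        )
        dpfc_vals, _, tails = sim.respond(schedule.delta_L[s])
        full_match = _stage_match_mask(np.sign(dpfc_vals), targets.target_dpfc[s])
        n_matched = int(full_match.sum())
        matched_counts[s] = n_matched
        if n_matched == 0:
            raise ValueError(
                f"full model matches zero target links at stage {s}; "
                "relevance is undefined"
            )
        for region in range(n_regions):
            if schedule.delta_L[s, region] == 0.0:
                continue  # no-op lesion, relevance exactly 0
            lesioned = lesion_region(schedule, s, region)
            les_vals, _, _ = sim.respond(lesioned.delta_L[s])
            les_match = _stage_match_mask(np.sign(les_vals), targets.target_dpfc[s])
            relevance[s, region] = float((full_match & ~les_match).sum()) / n_matched
        histories = tails
    return RelevanceMap(relevance, matched_counts, model_id)


def regress_relevance(
    relevance_maps: RelevanceMap | list[RelevanceMap],
    schedules: PulseSchedule | list[PulseSchedule],
    connectome: StructuralConnectome,
) -> pd.DataFrame:
    """Single-predictor OLS of relevance, one fit per ensemble model.

    Pools all (stage, region) points of a model into one regression per
    predictor: |dL| and |dL| * log(node strength + eps), with eps a tenth of
    the smallest positive strength so isolated nodes stay finite. Returns a
    tidy frame with one row per (model, predictor) and the R^2, plus
    mean +- SEM rows (model id "summary").
    """
    if isinstance(relevance_maps, RelevanceMap):
        relevance_maps = [relevance_maps]
    if isinstance(schedules, PulseSchedule):
        schedules = [schedules]
    if len(relevance_maps) != len(schedules):
        raise ValueError("one schedule per relevance map required")
    strength = connectome.weights.sum(axis=1)
    pos = strength[strength > 0]
    eps = (pos.min() / 10.0) if pos.size else 1.0
    log_strength = np.log(strength + eps)
    rows = []
    for rmap, sched in zip(relevance_maps, schedules):
        y = rmap.relevance.ravel()
        abs_dl = np.abs(sched.delta_L).ravel()
        interaction = (np.abs(sched.delta_L) * log_strength[None, :]).ravel()
        if y.size < 3:
            raise ValueError("need at least 3 (stage, region) points")
        for name, x in (("abs_pulse", abs_dl), ("abs_pulse_x_log_strength", interaction)):
            if np.ptp(x) == 0:
                r2 = np.nan  # zero-variance predictor
            else:
                fit = sm.OLS(y, sm.add_constant(x)).fit()
                r2 = float(fit.rsquared)
            rows.append(dict(model_id=rmap.model_id, predictor=name, r_squared=r2))
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("predictor")
        .r_squared.agg(["mean", "sem", "count"])
        .reset_index()
    )
    summary.columns = ["predictor", "r_squared_mean", "r_squared_sem", "n_models"]
    return df.merge(summary, on="predictor", how="left")
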