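"""End-to-end orchestration: segment -> measure -> target -> optimize -> lesion.

`run_analysis` takes epoched multichannel data (or generates a synthetic
bundle), discovers stage onsets with the bump HSMM, measures theta-band
coordination (within-stage dpFC with surrogate significance, stage-locked
local synchrony, relative envelope changes) and writes a targets file.
`run_model` consumes a targets file and a connectome, optionally grid-
searches the resting couplings, optimizes the stage pulses, draws an
ensemble, and runs the lesion-relevance analysis with regressions. Every
output directory gets a JSON provenance record (config, seeds, versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import StructuralConnectome, compute_delays, load_connectome
from .coordination import (
    bandpass_analytic,
    local_synchrony,
    relative_envelope_change,
    surrogate_significance,
)
from .fitness import TargetStateSet
from .hsmm import decode_onsets, fit_bump_hsmm, preprocess_pca, select_n_bumps
from .lesion import regress_relevance, relevance_map
from .optimize import ensemble_pick, optimize_pulses
from .simulator import GwbmParams, grid_search_resting
from .synth import SynthTaskSpec, synth_connectome, synth_task_epochs

__all__ = ["RunConfig", "run_analysis", "run_model", "load_config", "load_targets"]


@dataclass
class RunConfig:
    """Declarative configuration; unknown keys are rejected at load time.

    Defaults are the reference values: 100 Hz sampling, theta band
    3.8-8.5 Hz, 200 surrogates, 30-ms pulses, 1-ms integration step,
    G = 0.15, L = 0.7, Delta = 1, 6 Hz center, 5 m/s conduction velocity,
    gamma shape 2, 5-sample bumps, 10 islands x 50 individuals.
    """

    out_dir: str = "stagewave_out"
    seed: int = 0
    # inputs (None -> synthesize)
    connectome_weights: str | None = None
    connectome_lengths: str | None = None
    epochs_path: str | None = None  # .npz with epochs, onsets, lengths
    targets_path: str | None = None
    # synthetic fallbacks
    synth_regions: int = 16
    synth_trials: int = 100
    # analysis parameters
    fs_hz: float = 100.0
    theta_band_hz: tuple[float, float] = (3.8, 8.5)
    hsmm_band_hz: tuple[float, float] = (1.0, 30.0)
    n_bumps: int | None = 4  # None -> select by LOSO
    n_starts: int = 20
    n_surrogates: int = 200
    alpha: float = 0.05
    var_target: float = 0.90
    # model parameters
    velocity_m_per_s: float = 5.0
    omega_hz: float = 6.0
    delta: float = 1.0
    local_coupling: float = 0.7
    global_coupling: float = 0.15
    dt_s: float = 0.001
    pulse_duration_s: float = 0.03
    l_max: float = 20.0
    islands: int = 10
    pop_per_island: int = 50
    generations: int = 100
    migration_interval: int = 10
    n_replicates: int = 25
    run_gridsearch: bool = False
    grid_g: tuple[float, ...] = (0.05, 0.1, 0.15, 0.3, 0.6)
    grid_l: tuple[float, ...] = (0.3, 0.5, 0.7, 1.0, 2.0)
    grid_duration_s: float = 120.0
    grid_burn_in_s: float = 20.0
    ensemble_picks: int = 50
    ensemble_top_fraction: float = 0.01

    def params(self) -> GwbmParams:
        return GwbmParams(
            omega_rad_s=2 * np.pi * self.omega_hz,
            delta=self.delta,
            local_coupling=self.local_coupling,
            global_coupling=self.global_coupling,
            dt_s=self.dt_s,
        )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("theta_band_hz", "hsmm_band_hz", "grid_g", "grid_l"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _provenance(config: RunConfig, extra: dict) -> dict:
    cfg = dataclasses.asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return dict(
        config=cfg,
        config_sha256=hashlib.sha256(blob).hexdigest(),
        stagewave_version=__version__,
        numpy_version=np.__version__,
        **extra,
    )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _load_epochs(config: RunConfig):
    if config.epochs_path is not None:
        path = Path(config.epochs_path)
        if not path.exists():
            raise FileNotFoundError(f"epochs file not found: {path}")
        with np.load(path) as z:
            return z["epochs"], z["onsets"], z["lengths"]
    spec = SynthTaskSpec(
        n_trials=config.synth_trials,
        n_regions=config.synth_regions,
        fs_hz=config.fs_hz,
        seed=config.seed,
    )
    res = synth_task_epochs(spec)
    return res.epochs, res.onsets, res.trial_lengths


def run_analysis(config: RunConfig) -> Path:
    """Stage segmentation, coordination measurement, and target assembly."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs, _true_onsets, lengths = _load_epochs(config)

    scores_list, projection, _ = preprocess_pca(
        [epochs], [lengths], config.fs_hz, config.hsmm_band_hz,
        var_target=config.var_target,
    )
    scores = scores_list[0]
    if config.n_bumps is None:
        raise ValueError(
            "automatic bump-count selection needs multiple subjects; "
            "use select_n_bumps directly or set n_bumps"
        )
    model = fit_bump_hsmm(
        scores, lengths, config.n_bumps, n_starts=config.n_starts,
        seed=config.seed,
    )
    seg = decode_onsets(model, scores, lengths)
    n_stages = config.n_bumps + 1
    onsets = np.concatenate(
        [np.zeros((len(lengths), 1), int), seg.onsets, lengths[:, None]], axis=1
    )
    pd.DataFrame(
        seg.onsets, columns=[f"bump_{k}" for k in range(config.n_bumps)]
    ).to_csv(out / "segmentation.csv", index_label="trial")

    analytic = bandpass_analytic(
        epochs, config.fs_hz, onsets, *config.theta_band_hz
    )
    target_dpfc = []
    target_env = []
    medians = []
    for s in range(1, n_stages):  # post-stimulus stages only
        dp = surrogate_significance(
            analytic, s, config.n_surrogates, config.alpha,
            seed=config.seed + s,
        )
        masked = np.sign(dp.values) * dp.significant
        target_dpfc.append(masked)
        offs, env = local_synchrony(analytic, s)
        change = relative_envelope_change(env, config.fs_hz, onset_index=-offs[0])
        target_env.append(change)
        medians.append(np.median(onsets[:, s + 1] - onsets[:, s]) / config.fs_hz)
        pd.DataFrame(dp.values).to_csv(out / f"dpfc_stage{s}.csv", index=False)
        pd.DataFrame(dp.significant.astype(int)).to_csv(
            out / f"dpfc_stage{s}_mask.csv", index=False
        )
    targets = dict(
        target_dpfc=np.stack(target_dpfc),
        target_env_change=np.stack(target_env),
        median_durations_s=np.asarray(medians),
    )
    _write_json(out / "targets.json", targets)
    _write_json(out / "provenance.json", _provenance(config, dict(step="analysis")))
    return out


def load_targets(path: str | Path) -> TargetStateSet:
    raw = json.loads(Path(path).read_text())
    return TargetStateSet(
        np.asarray(raw["target_dpfc"]),
        np.asarray(raw["target_env_change"]),
        np.asarray(raw["median_durations_s"]),
    )


def _load_connectome(config: RunConfig) -> StructuralConnectome:
    if config.connectome_weights is not None:
        con = load_connectome(config.connectome_weights, config.connectome_lengths)
    else:
        con = synth_connectome(config.synth_regions, seed=config.seed)
    return compute_delays(con, config.velocity_m_per_s)


def run_model(config: RunConfig) -> Path:
    """Grid search (optional), pulse optimization, ensemble, lesion analysis."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.targets_path is None:
        raise FileNotFoundError("run_model requires a targets file (targets_path)")
    targets = load_targets(config.targets_path)
    con = _load_connectome(config)
    params = config.params()
    if config.run_gridsearch:
        table, (g_best, l_best) = grid_search_resting(
            con, config.grid_g, config.grid_l, n_replicates=3,
            duration_s=config.grid_duration_s, burn_in_s=config.grid_burn_in_s,
            seed=config.seed, params=params,
        )
        table.to_csv(out / "gridsearch.csv", index=False)
        params = GwbmParams(
            omega_rad_s=params.omega_rad_s, delta=params.delta,
            local_coupling=l_best, global_coupling=g_best, dt_s=params.dt_s,
        )
    result = optimize_pulses(
        con, params, targets, l_max=config.l_max, islands=config.islands,
        pop_per_island=config.pop_per_island, generations=config.generations,
        migration_interval=config.migration_interval,
        n_replicates=config.n_replicates, seed=config.seed,
        pulse_duration_s=config.pulse_duration_s,
    )
    result.archive.to_csv(out / "archive.csv", index=False)
    np.savetxt(out / "best_schedule.txt", result.best_schedule.delta_L, fmt="%.8g")
    picks = ensemble_pick(
        result.archive, targets, config.l_max,
        config.ensemble_top_fraction, config.ensemble_picks, seed=config.seed,
        pulse_duration_s=config.pulse_duration_s,
    )
    maps = []
    for i, sched in enumerate(picks[: min(len(picks), 10)]):
        maps.append(
            relevance_map(
                con, params, sched, targets,
                n_replicates=config.n_replicates, seed=config.seed,
                initial_histories=result.initial_histories, model_id=i,
            )
        )
    rel_rows = []
    for m in maps:
        for s in range(m.relevance.shape[0]):
            for r in range(m.relevance.shape[1]):
                rel_rows.append(
                    dict(model_id=m.model_id, stage=s, region=r,
                         relevance=m.relevance[s, r])
                )
    pd.DataFrame(rel_rows).to_csv(out / "relevance.csv", index=False)
    reg = regress_relevance(maps, picks[: len(maps)], con)
    reg.to_csv(out / "relevance_regression.csv", index=False)
    _write_json(out / "provenance.json", _provenance(config, dict(step="model")))
    return out
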