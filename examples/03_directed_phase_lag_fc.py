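"""Measure stage-wise directed phase-lag connectivity with significance.

Generates theta-band task epochs whose second stage contains a known
phase-lead between two regions, computes the within-stage directed
phase-lag statistic, and tests it against circular-shift surrogates.
"""

import numpy as np

from stagewave import (
    SynthTaskSpec,
    bandpass_analytic,
    surrogate_significance,
    synth_task_epochs,
)

spec = SynthTaskSpec(
    n_trials=40, n_regions=8, n_stages=2,
    stage_gamma_scales=(40.0, 60.0), max_trial_s=4.0,
    lag_structure=[[], [(0, 1, 0.5), (2, 3, -0.4)]],
    env_steps=np.zeros((2, 8)),
    noise_sigma=0.3, seed=4,
)
res = synth_task_epochs(spec)
analytic = bandpass_analytic(res.epochs, res.fs_hz, res.onsets)

dp = surrogate_significance(analytic, stage=1, n_surrogates=200, alpha=0.05, seed=0)
print("within-stage dpFC (stage 2), selected links:")
print(f"  region 0 -> 1 : {dp.values[0, 1]:+.2f}  significant={bool(dp.significant[0, 1])}")
print(f"  region 2 -> 3 : {dp.values[2, 3]:+.2f}  significant={bool(dp.significant[2, 3])}")
print(f"  region 4 -> 5 : {dp.values[4, 5]:+.2f}  significant={bool(dp.significant[4, 5])}")
n_sig = int(dp.significant.sum() // 2)
print(f"significant links: {n_sig} of {8 * 7 // 2}")
print()
print("A value of +1 means region i is consistently phase-ahead of region j")
print("throughout the stage; the surrogate mask keeps only links whose lag")
print("consistency beats 200 circularly-shifted null datasets.")
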