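import numpy as np
import pytest

from stagewave.connectome import compute_delays
from stagewave.synth import synth_connectome


@pytest.fixture(scope="session")
def toy_connectome():
    """16-region distance-dependent connectome with 5 m/s delays."""
    return compute_delays(synth_connectome(16, seed=5), 5.0)


@pytest.fixture(scope="session")
def tri_connectome():
    """Dense 3-region connectome for oracle-equivalence runs."""
    return compute_delays(synth_connectome(3, density=1.0, seed=1), 5.0)


@pytest.fixture(scope="session")
def model_fixture():
    """Known-truth pulse-switching study on the 16-region connectome."""
    from stagewave.synth import synth_model_fixture

    return synth_model_fixture(seed=0)


def lagged_analytic_epochs(
    n_trials=8,
    n_regions=4,
    t_len=120,
    fs=100.0,
    lag_pairs=((0, 1, 0.3),),
    seed=0,
    phase_noise=0.0,
):
    """Analytic epochs with fixed phase leads; one stage spanning the epoch.

    Region i leads region j by ``lag`` radians for every (i, j, lag) in
    ``lag_pairs``; other regions get independent random phase offsets.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t_len) / fs
    offsets = rng.uniform(-np.pi, np.pi, size=(n_trials, n_regions))
    for i, j, lag in lag_pairs:
        offsets[:, j] = rng.uniform(-np.pi, np.pi, size=n_trials)
        offsets[:, i] = offsets[:, j] + lag
    phase = (
        2 * np.pi * 6.0 * t[None, None, :]
        + offsets[:, :, None]
        + phase_noise * rng.standard_normal((n_trials, n_regions, t_len))
    )
    data = np.exp(1j * phase)
    onsets = np.tile([0, t_len], (n_trials, 1))
    from stagewave.coordination import AnalyticEpochs

    return AnalyticEpochs(data, fs, onsets)
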