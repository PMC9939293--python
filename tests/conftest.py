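import numpy as np
import pytest

from popfam import SynthConfig, generate_population, preprocess


@pytest.fixture(scope="session")
def multistim_config():
    return SynthConfig(seed=7, n_neurons=30)


@pytest.fixture(scope="session")
def multistim_recording(multistim_config):
    return generate_population(multistim_config)


@pytest.fixture(scope="session")
def multistim_traces(multistim_recording):
    rec, _ = multistim_recording
    return preprocess(rec, mode="multistim")


@pytest.fixture(scope="session")
def plasticity_recording():
    cfg = SynthConfig(seed=11, n_neurons=30, schedule_kind="plasticity",
                      baseline_rate=0.1, tuned_rate=3.0)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def planted_binary():
    """Two planted 10-neuron ensembles plus 10 weakly active independents."""
    rng = np.random.default_rng(3)
    n, T = 30, 2000
    b = (rng.random((n, T)) < 0.02).astype(np.int8)
    ev1 = np.flatnonzero(rng.random(T) < 0.05)
    ev2 = np.flatnonzero(rng.random(T) < 0.05)
    b[:10][:, ev1] = 1
    b[10:20][:, ev2] = 1
    members = np.zeros((n, 2), dtype=bool)
    members[:10, 0] = True
    members[10:20, 1] = True
    return b, members, (ev1, ev2)
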