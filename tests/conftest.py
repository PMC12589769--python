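import numpy as np
import pytest

from meagdn import preprocessing as pre
from meagdn import synthetic_mea as syn


@pytest.fixture(scope="session")
def small_scenario():
    """A short coupled recording scenario used across preprocessing tests."""
    net = syn.GroundTruthNetwork.random(4, 3, 0.8, seed=11, delay_ms=2.0)
    return syn.SimulationScenario(n_channels=4, duration_s=5.0, base_rate_hz=3.0,
                                  network=net, seed=5)


@pytest.fixture(scope="session")
def small_recording(small_scenario):
    return syn.simulate_recording(small_scenario)


@pytest.fixture(scope="session")
def small_am_train(small_recording):
    rec, _gt = small_recording
    filt = pre.bandpass_filter(rec)
    thresholds = pre.estimate_thresholds(filt)
    events = pre.detect_spikes(filt, thresholds)
    return pre.build_am_spike_train(filt, events)


def random_digraph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.random((n, n)) < p
    np.fill_diagonal(a, False)
    return a
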