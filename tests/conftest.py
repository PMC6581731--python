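import numpy as np
import pytest

from saelstm import synth


@pytest.fixture(scope="session")
def small_noiseless_trials():
    """Four noiseless 63 s trials of 12 mixed sources — shared by tests that
    only read the data."""
    panel = synth.simulate_sources(4, 12, 63.0, 128.0, seed=101)
    truth = synth.make_mixing(32, 12, noise_sd=0.0, seed=102)
    trials = synth.mix(panel, truth)
    return trials, panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
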