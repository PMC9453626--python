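import numpy as np
import pytest

from somnostim.signals import Hypnogram
from somnostim.synth import SynthParams, generate_eeg


@pytest.fixture(scope="session")
def n3_recording():
    """30 min of stationary N3-like EEG (no spindles, no artifacts)."""
    hyp = Hypnogram(["N3"] * 90)
    params = SynthParams(seed=5, spindle_rate=0.0, movement_rate_per_h=0.0)
    rec, truth = generate_eeg(hyp, params)
    return rec, truth, params


@pytest.fixture(scope="session")
def n2_recording():
    """20 min of N2-like EEG with spindles at the default rate."""
    hyp = Hypnogram(["N2"] * 60)
    params = SynthParams(seed=0, movement_rate_per_h=0.0)
    rec, truth = generate_eeg(hyp, params)
    return rec, truth, params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
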