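"""Shared fixtures: small synthetic scenarios generated at test time."""

import numpy as np
import pytest

from trfdecode.crossval import Trial
from trfdecode.synthetic import SyntheticScenario, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact two-talker dataset: 12 trials x 15 s, 8 channels, decodable SNR."""
    scen = SyntheticScenario(n_trials=12, trial_s=15.0, fs=64.0, n_channels=8,
                             snr_db=-5.0, n_noise_sources=4, seed=7)
    return generate_dataset(scen)


@pytest.fixture(scope="session")
def small_trials(small_dataset):
    return [Trial(t.eeg, t.attended_env, t.unattended_env, t.attended)
            for t in small_dataset.trials]


@pytest.fixture(scope="session")
def clean_dataset():
    """Near-noiseless single-stream-dominant dataset for identifiability checks."""
    scen = SyntheticScenario(n_trials=8, trial_s=15.0, fs=64.0, n_channels=6,
                             snr_db=25.0, n_noise_sources=3, seed=11,
                             attended_gain=2.0, unattended_gain=0.0)
    return generate_dataset(scen)
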