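import numpy as np
import pytest

from tensiowork.synthetic import (ParticipantProfile, TrialSpec,
                                  default_gait_pattern, make_trial)


@pytest.fixture(scope="session")
def pattern():
    return default_gait_pattern()


@pytest.fixture(scope="session")
def profile():
    return ParticipantProfile()


@pytest.fixture(scope="session")
def level_trial(pattern, profile):
    """20 level strides, mild noise, 50 ms start delay."""
    spec = TrialSpec(n_strides=20, slope_sequence=np.zeros(20),
                     sync_delay=0.05, noise_scale=0.01, seed=42)
    return make_trial(profile, pattern, spec)


@pytest.fixture(scope="session")
def noiseless_trial(pattern, profile):
    """10 level strides, zero noise, aligned clocks."""
    spec = TrialSpec(n_strides=10, slope_sequence=np.zeros(10),
                     sync_delay=0.0, noise_scale=0.0, seed=7)
    return make_trial(profile, pattern, spec)
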