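import numpy as np
import pytest

from bcishield import synthgen as sg


@pytest.fixture(scope="session")
def default_profile():
    return sg.SubjectProfile()


@pytest.fixture(scope="session")
def small_dataset():
    """One subject at 1/10 scale: 24 P300 + 120 nonP300 trials."""
    return sg.synth_dataset(n_subjects=1, seed=42, scale=0.1)[0]


@pytest.fixture(scope="session")
def donor_trials():
    """Trials from two donor subjects (distinct from any victim seed used)."""
    donors = sg.synth_dataset(n_subjects=2, seed=777, scale=0.05)
    return [t for d in donors for t in d.trials]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
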