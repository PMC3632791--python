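import numpy as np
import pytest

from transsacc.observer import control_preset, simulate_session, thalamic_preset


@pytest.fixture(scope="session")
def control_session():
    """One full simulated session of a healthy observer."""
    return simulate_session(control_preset(), rng_seed=11, subject="C01")


@pytest.fixture(scope="session")
def thalamic_session():
    """One full simulated session of a lesion-like observer (both directions)."""
    return simulate_session(thalamic_preset(), rng_seed=12, subject="P01")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
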