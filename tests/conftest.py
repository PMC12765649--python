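import numpy as np
import pytest

from pupilpredict import observers, stimgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """30-trial session reused by observer and regressor tests."""
    cfg = stimgen.SessionConfig(n_blocks=2, trials_per_block=15)
    return stimgen.generate_session(cfg, 7)


@pytest.fixture(scope="session")
def small_session_traces(small_session):
    return observers.session_traces(small_session, model="drex")
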