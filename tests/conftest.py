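import numpy as np
import pytest

from bciloop import SessionConfig, SSVEPConfig, generate_errp_session, generate_ssvep_session


@pytest.fixture(scope="session")
def default_errp_session():
    """One default passive session (200 trials, 20% error, snr=1), reused by
    every test that only reads it."""
    return generate_errp_session(SessionConfig(seed=0))


@pytest.fixture(scope="session")
def small_errp_session():
    """A short passive session for I/O and CLI tests."""
    return generate_errp_session(SessionConfig(n_trials=40, seed=1))


@pytest.fixture(scope="session")
def small_ssvep_session():
    return generate_ssvep_session(SSVEPConfig(trials_per_class=6, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
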