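import numpy as np
import pytest

from dfcengage import synthdata
from dfcengage.config import RunConfig
from dfcengage.paradigm import build_paradigm, segment_windows


@pytest.fixture(scope="session")
def paradigm():
    return build_paradigm(seed=0)


@pytest.fixture(scope="session")
def windows(paradigm):
    return segment_windows(paradigm, wl_tr=30, shift_tr=4)


@pytest.fixture(scope="session")
def small_states():
    """16-component covariance states (small for fast unit tests)."""
    return synthdata.make_state_covariances(n_components=16, n_modules=4, seed=1)


@pytest.fixture(scope="session")
def small_subject(paradigm, small_states):
    return synthdata.simulate_subject(paradigm, small_states, seed=7)


@pytest.fixture()
def fast_config():
    """Scaled-down analysis settings for quick end-to-end runs."""
    cfg = RunConfig()
    cfg.synth.n_components = 16
    cfg.cluster.n_init = 10
    cfg.graph.n_reps = 16
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
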