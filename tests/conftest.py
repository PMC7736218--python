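import numpy as np
import pytest

from betastop.pipeline import make_fixtures
from betastop.synthgen import CohortConfig, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three small subjects (90 go / 30 stop) with EEG epochs."""
    cfg = make_fixtures("tiny")
    return cfg, list(simulate_cohort(cfg))


@pytest.fixture(scope="session")
def behavioral_session():
    """One full-length behavioral session (no EEG) with its config."""
    from betastop.synthgen import run_staircase_session, trials_to_frame

    cfg = CohortConfig(include_eeg=False, seed=3)
    outs = run_staircase_session(cfg, np.random.default_rng(3))
    return cfg, outs, trials_to_frame(outs)
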