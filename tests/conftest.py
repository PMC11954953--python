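import numpy as np
import pytest

import boutwise as bw


@pytest.fixture(scope="session")
def small_session():
    """A 40-cell session with strong planted coupling, shared across tests."""
    cfg = bw.SessionConfig(
        n_cells=40,
        fractions=(0.4, 0.2, 0.4),
        habituation_s=200.0,
        stimulus_s=400.0,
    )
    session, gt = bw.simulate_session(cfg, seed=101)
    return session, gt


@pytest.fixture(scope="session")
def small_session_z(small_session):
    session, gt = small_session
    z, degenerate = bw.zscore_traces(session.traces, bouts=session.bouts)
    return session, gt, z, degenerate


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
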