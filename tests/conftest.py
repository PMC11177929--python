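import numpy as np
import pytest

from wmv1.simulate import SimConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One mid-sized session with the default tuning structure."""
    cfg = SimConfig(n_electrodes=8, n_trials_per_condition=120, seed=42)
    return cfg, simulate_session(cfg)


@pytest.fixture(scope="session")
def null_session():
    """No stimulus tuning, no delay modulation, no off-response."""
    cfg = SimConfig(n_electrodes=6, n_trials_per_condition=120, seed=7,
                    stim_gain=np.ones((6, 4)), delay_delta=np.zeros((6, 4)),
                    off_response_amp=0.0, incorrect_fraction=0.0)
    return cfg, simulate_session(cfg)
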