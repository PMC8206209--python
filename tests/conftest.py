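import numpy as np
import pytest

import reflexmri as rm
from reflexmri.emg_sim import EmgSimParams, generate_session_recording


@pytest.fixture(scope="session")
def protocol():
    """Default 60-trial session timeline."""
    return rm.generate_protocol(rm.ProtocolSpec(seed=7))


@pytest.fixture(scope="session")
def session():
    """One synthetic in-scanner session with ground truth (shared, read-only)."""
    protocol = rm.generate_protocol(rm.ProtocolSpec(seed=7))
    recordings, truth = generate_session_recording(
        protocol, EmgSimParams(), np.random.default_rng(42)
    )
    return protocol, recordings, truth


@pytest.fixture(scope="session")
def validation_experiment():
    """Synthetic multi-participant validation study (12 participants,
    OUT1 / IN1 / OUT2 sessions), shared read-only across tests."""
    from reflexmri.experiment import simulate_validation_experiment

    table, _ = simulate_validation_experiment(
        12, seed=77, sessions=("OUT1", "IN1", "OUT2")
    )
    return table


@pytest.fixture(scope="session")
def clean_session():
    """Artifact-free session (out-of-scanner conditions) with ground truth."""
    protocol = rm.generate_protocol(rm.ProtocolSpec(seed=7))
    recordings, truth = generate_session_recording(
        protocol, EmgSimParams(artifact_gain=0.0), np.random.default_rng(42)
    )
    return protocol, recordings, truth
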