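import numpy as np
import pytest

from g4peakbench.simulate import (
    SimConfig,
    generate_genome,
    generate_peaksets,
    generate_tracks,
)


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated study, shared across tests."""
    config = SimConfig(seed=1)
    sim = generate_genome(config)
    tracks = generate_tracks(sim)
    peaksets = generate_peaksets(sim.peaks, config)
    return sim, tracks, peaksets


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
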