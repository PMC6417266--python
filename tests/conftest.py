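import pytest

from enhancerscope import (
    SimConfig,
    simulate_expression,
    simulate_genome,
    simulate_peaks_and_tracks,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_bundle(default_cfg):
    """One default synthetic bundle shared across tests (read-only)."""
    genome = simulate_genome(default_cfg)
    sim = simulate_peaks_and_tracks(default_cfg, genome)
    expr = simulate_expression(default_cfg, genome, sim.truth)
    return genome, sim, expr
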