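import pytest

from targetcall.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def noiseless_sim():
    """Default study conditions: 20 target genes, 5 replicates, no dropout."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced dataset for fast structural tests."""
    config = SimulationConfig(
        seed=3,
        n_genes=24,
        n_target_genes=6,
        n_background_genes_with_peaks=4,
        chromosome_length=250_000,
    )
    return simulate(config)
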