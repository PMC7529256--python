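import pytest

from pgaqp import make_reference_panel, plant_genome, simulate_hsps


@pytest.fixture(scope="session")
def panel():
    return make_reference_panel(n_per_family=2, seed=0)


@pytest.fixture(scope="session")
def planted(panel):
    """Default-scale planted genome: 12 functional, 3 pseudo, 3 decoys."""
    return plant_genome(panel, n_genes=12, n_pseudo=3, n_decoys=3, seed=7)


@pytest.fixture(scope="session")
def planted_hsps(planted):
    genome, annotation, truths = planted
    return simulate_hsps(genome, annotation, truths, spurious_rate=0.0,
                         redundancy=0.0, seed=7)
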