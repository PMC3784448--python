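"""Shared synthetic fixtures: a small genome pair, read mixture and indices."""

import pytest

import xenopart as xp


@pytest.fixture(scope="session")
def genome_pair():
    """20 kb graft/host pair at human/mouse-like 12% divergence."""
    return xp.evolve_genomes(20_000, divergence=0.12, seed=101)


@pytest.fixture(scope="session")
def mixture(genome_pair):
    """2,000 pairs, 20% host, low error — reads and truth labels."""
    params = xp.SimParams(n_pairs=2000, host_fraction=0.2, error_rate=0.001, seed=202)
    return xp.simulate_mixture(genome_pair, params)


@pytest.fixture(scope="session")
def graft_index(genome_pair):
    return xp.build_index(genome_pair.graft_sequence, genome_id="graft")


@pytest.fixture(scope="session")
def host_index(genome_pair):
    return xp.build_index(genome_pair.host_sequence, genome_id="host")
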