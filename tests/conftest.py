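import pytest
from hypothesis import settings

from bittermap import mining, simulate

settings.register_profile("deterministic", derandomize=True,
                          database=None, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def genome_sim():
    """One synthetic assembly with planted genes and per-filter decoys."""
    return simulate.generate_genome(seed=11)


@pytest.fixture(scope="session")
def mining_result(genome_sim):
    """The full discovery pipeline run once on the shared assembly."""
    return mining.mine_genome(
        genome_sim.genome, genome_sim.queries, genome_sim.reference_genome,
        genome_sim.validated_intervals, species="synthsp",
    )


@pytest.fixture(scope="session")
def species_tree():
    from bittermap.genome_io import parse_newick

    return parse_newick("(((A:60,B:60):40,C:100):80,D:180);")
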