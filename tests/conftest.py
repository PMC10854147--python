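import numpy as np
import pytest

from gsthemes import GeneSet, GeneSetCollection, SyntheticSpec, simulate_collection


@pytest.fixture(scope="session")
def default_sim():
    """One default-spec synthetic collection (seed 0), shared across tests."""
    return simulate_collection(SyntheticSpec(seed=0))


@pytest.fixture()
def small_collection():
    """Four named sets over a 10-gene universe with known overlaps."""
    universe = [f"g{i}" for i in range(10)]
    sets = [
        GeneSet("S1", "first", {"g0", "g1", "g2", "g3"}),
        GeneSet("S2", "second", {"g2", "g3", "g4", "g5"}),
        GeneSet("S3", "third", {"g0", "g1", "g2"}),
        GeneSet("S4", "fourth", {"g7", "g8"}),
    ]
    return GeneSetCollection(sets, universe)


def random_set_pair(rng, n_universe, max_size=60):
    """Two random gene-sets plus their universe, for oracle comparisons."""
    universe = [f"g{i}" for i in range(n_universe)]
    kx = rng.integers(1, max_size)
    ky = rng.integers(1, max_size)
    x = frozenset(rng.choice(universe, size=kx, replace=False))
    y = frozenset(rng.choice(universe, size=ky, replace=False))
    return GeneSet("X", "", x), GeneSet("Y", "", y), frozenset(universe)
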