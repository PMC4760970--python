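import random

import pytest

from rigidmol import make_fixture
from rigidmol.mechanics import Multigraph


@pytest.fixture(scope="session")
def water():
    return make_fixture("water")


@pytest.fixture(scope="session")
def ethane():
    return make_fixture("ethane")


@pytest.fixture(scope="session")
def ethylene():
    return make_fixture("ethylene")


@pytest.fixture(scope="session")
def dipeptide():
    return make_fixture("dipeptide")


@pytest.fixture(scope="session")
def helix8():
    return make_fixture("toy_helix", n_res=8)


def random_multigraph(rng: random.Random, max_v: int = 6,
                      max_e: int = 40) -> Multigraph:
    """Seeded random loop-free multigraph for oracle comparisons."""
    nv = rng.randint(1, max_v)
    edges = []
    for t in range(rng.randint(0, max_e)):
        u, v = rng.randrange(nv), rng.randrange(nv)
        if u != v:
            edges.append((min(u, v), max(u, v), t))
    return Multigraph(list(range(nv)), edges)
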