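import random
from itertools import combinations

import pytest

from dapgminer import ComplexSet, GraphType, PPINetwork, fig1_fixture


@pytest.fixture
def fig1():
    """The 7-vertex toy network and its three maximal cliques."""
    return fig1_fixture()


@pytest.fixture
def triangle():
    net = PPINetwork(GraphType.UNONE)
    for a, b in combinations("123", 2):
        net.add_interaction(a, b)
    return net


def random_network(n: int, p: float, seed: int, weighted: bool = False) -> PPINetwork:
    """Seeded Erdős–Rényi network over proteins v0..v{n-1}."""
    rng = random.Random(seed)
    net = PPINetwork(GraphType.USYM if weighted else GraphType.UNONE)
    for i in range(n):
        net.add_protein(f"v{i}")
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = rng.random() if weighted else 1.0
                net.add_interaction(f"v{i}", f"v{j}", w)
    return net


def random_complex_set(rng: random.Random, k: int, universe: int = 20) -> ComplexSet:
    out = []
    while len(out) < k:
        size = rng.randint(2, 6)
        c = frozenset(f"p{i}" for i in rng.sample(range(universe), size))
        if c not in out:
            out.append(c)
    return ComplexSet(out)
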