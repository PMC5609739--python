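"""Synthetic PPI networks with known ground truth.

Planted networks emulate the clique / near-clique patterns that real
complexes leave in interactomes: each planted complex is a clique
(optionally with one edge removed, the "four proteins missing an edge"
pattern), consecutive complexes may share one protein (multifunctional
proteins), and background vertices with sparse Erdős–Rényi edges stand in
for the noisy remainder of the network.  Everything is seeded.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

from .network import ComplexSet, GraphType, PPINetwork

__all__ = ["SyntheticSpec", "planted_network", "add_random_edges", "fig1_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-complex network.

    overlap_fraction is the probability that a complex shares one protein
    with the previous one; missing_edge_fraction the probability that a
    planted clique loses a single edge; weight_noise > 0 makes the network
    weighted, with weights drawn uniformly from [1 - weight_noise, 1].
    """

    n_complexes: int = 5
    size_range: tuple[int, int] = (3, 6)
    overlap_fraction: float = 0.0
    background_vertices: int = 0
    background_edge_prob: float = 0.0
    weight_noise: float = 0.0
    missing_edge_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError("size_range must satisfy 3 <= min <= max")
        if self.n_complexes < 1:
            raise ValueError("need at least one complex")
        for p in (self.overlap_fraction, self.background_edge_prob,
                  self.missing_edge_fraction, self.weight_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.background_vertices < 0:
            raise ValueError("background_vertices must be >= 0")


def _protein_name(i: int) -> str:
    return f"P{i:04d}"


def planted_network(spec: SyntheticSpec) -> tuple[PPINetwork, ComplexSet]:
    """Build a seeded network of planted complexes plus background noise.

    Returns the network and the ground-truth complex set.  Deterministic
    for a given spec (including seed).
    """
    rng = random.Random(spec.seed)
    gtype = GraphType.USYM if spec.weight_noise > 0 else GraphType.UNONE
    net = PPINetwork(gtype)

    def draw_weight() -> float:
        if spec.weight_noise > 0:
            return rng.uniform(1.0 - spec.weight_noise, 1.0)
        return 1.0

    next_id = 0
    truth: list[frozenset[str]] = []
    prev_members: list[str] = []
    for k in range(spec.n_complexes):
        size = rng.randint(*spec.size_range)
        members: list[str] = []
        if k > 0 and prev_members and rng.random() < spec.overlap_fraction:
            members.append(rng.choice(prev_members))
        while len(members) < size:
            members.append(_protein_name(next_id))
            next_id += 1
        pairs = list(combinations(members, 2))
        if spec.missing_edge_fraction > 0 and len(pairs) > 1 and (
            rng.random() < spec.missing_edge_fraction
        ):
            pairs.remove(rng.choice(pairs))
        for a, b in pairs:
            net.add_interaction(a, b, draw_weight())
        truth.append(frozenset(members))
        prev_members = members

    for _ in range(spec.background_vertices):
        net.add_protein(_protein_name(next_id))
        next_id += 1

    if spec.background_edge_prob > 0:
        n = net.num_vertices
        for u in range(n):
            for v in range(u + 1, n):
                if not net.has_edge(u, v) and rng.random() < spec.background_edge_prob:
                    net.add_interaction(net.names[u], net.names[v], draw_weight())

    return net, ComplexSet(truth).deduplicated()


def add_random_edges(net: PPINetwork, fraction: float, seed: int = 0) -> PPINetwork:
    """Copy *net* with floor(fraction * |E|) extra uniformly-drawn non-edges.

    The original edge set is preserved exactly; new edges get weight 1.0
    (uniform in [0, 1] would misstate confidence for an unweighted run, and
    weighted networks keep their scale by drawing 1.0 as well — the paper's
    robustness experiment perturbs topology, not weights).
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    rng = random.Random(seed)
    n = net.num_vertices
    n_new = int(fraction * net.num_edges)
    max_possible = n * (n - 1) // 2 - net.num_edges
    if n_new > max_possible:
        raise ValueError(
            f"cannot add {n_new} edges: only {max_possible} vertex pairs are free"
        )
    out = PPINetwork(net.graph_type)
    for name in net.names:
        out.add_protein(name)
    for u, v, data in net.graph.edges(data=True):
        out.add_interaction(net.names[u], net.names[v], data["weight"])
    added = 0
    while added < n_new:
        u = rng.randrange(n)
        v = rng.randrange(n)
        if u != v and not out.has_edge(u, v):
            out.add_interaction(out.names[u], out.names[v], 1.0)
            added += 1
    return out


def fig1_fixture() -> tuple[PPINetwork, ComplexSet]:
    """The 7-vertex toy interactome whose maximal cliques are
    {1,2,3}, {3,4,5,6} and {4,5,6,7} (12 edges in the union)."""
    cliques = [("1", "2", "3"), ("3", "4", "5", "6"), ("4", "5", "6", "7")]
    net = PPINetwork(GraphType.UNONE)
    for name in "1234567":
        net.add_protein(name)
    for cl in cliques:
        for a, b in combinations(cl, 2):
            net.add_interaction(a, b)
    return net, ComplexSet([frozenset(c) for c in cliques])
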