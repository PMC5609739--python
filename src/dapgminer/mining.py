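"""Greedy mining of overlapping dense subgraphs over the prefix DAG.

A dense subgraph (DSG) is a pair (S, C) of vertex sets with every pair
(s, c), s != c, an edge of the interaction graph; it generalizes cliques
(S = C) and bicliques (S and C disjoint).  Every DAPG node u seeds one walk:
starting from S = vertexSet(u), C = {u}, an *inverse traveler function*
climbs parent arcs toward a root, and each visited node p is folded in
(S <- S n vertexSet(p), C <- C u {p}) exactly when that strictly improves
the configured objective and keeps S nonempty.  Because S is always an
intersection of closed neighborhoods of C members, validity (S x C within
the edge set) holds by construction at every step.

One candidate comes out of each walk; walks that never improve on their
seed produce nothing ("at most one dense subgraph per node").  Candidates
are then reduced to the maximal ones under inclusion of their vertex sets
S u C.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable

from .dapg import Dapg, Phi
from .network import PPINetwork

__all__ = [
    "Traveler",
    "Objective",
    "MiningConfig",
    "DenseSubgraph",
    "objective_score",
    "traveler_next",
    "walk_path",
    "mine_from_node",
    "mine_all",
    "filter_maximal",
]


class Traveler(str, Enum):
    """Inverse traveler functions: which parent to climb to next."""

    DEEPEST = "deepest"
    SHARING = "sharing"


class Objective(str, Enum):
    """Objective functions scored on a candidate (S, C).

    UNONE: intersection size |S n C| (the default, for unweighted runs).
    WDEGREE / WEDGE: weighted degree / edge density over the S x C edges.
    FWDEGREE / FWEDGE: the same densities over *all* edges induced by S u C.
    """

    UNONE = "UNONE"
    WDEGREE = "WDEGREE"
    WEDGE = "WEDGE"
    FWDEGREE = "FWDEGREE"
    FWEDGE = "FWEDGE"


@dataclass(frozen=True)
class MiningConfig:
    traveler: Traveler = Traveler.DEEPEST
    objective: Objective = Objective.UNONE
    phi: Phi = Phi.ID


@dataclass(frozen=True)
class DenseSubgraph:
    """A mined DSG: S x C (minus self-pairs) is contained in the edge set."""

    S: frozenset[int]
    C: frozenset[int]
    score: float
    seed_node: int

    @property
    def vertices(self) -> frozenset[int]:
        return self.S | self.C

    def is_valid(self, net: PPINetwork) -> bool:
        """Exhaustive validity check against the source network."""
        return all(
            net.has_edge(s, c) for s in self.S for c in self.C if s != c
        )


def _sxc_weight(S: frozenset[int], C: frozenset[int], net: PPINetwork) -> float:
    """Total weight of the unordered edges {s, c}, s in S, c in C, s != c."""
    small, other = (S, C) if len(S) <= len(C) else (C, S)
    total = 0.0
    seen: set[tuple[int, int]] = set()
    for s in small:
        for c in net.neighbors(s):
            if c in other and c != s:
                e = (s, c) if s < c else (c, s)
                if e not in seen:
                    seen.add(e)
                    total += net.weight(*e)
    return total


def _induced_weight(vertices: frozenset[int], net: PPINetwork) -> float:
    total = 0.0
    for u in vertices:
        for v in net.neighbors(u):
            if v in vertices and u < v:
                total += net.weight(u, v)
    return total


def objective_score(
    S: Iterable[int], C: Iterable[int], objective: Objective, net: PPINetwork
) -> float:
    """Score a candidate (S, C) under one of the five objectives."""
    S, C = frozenset(S), frozenset(C)
    if not S or not C:
        raise ValueError("S and C must be nonempty")
    objective = Objective(objective)
    if objective is Objective.UNONE:
        return float(len(S & C))
    union = S | C
    n = len(union)
    if objective in (Objective.WDEGREE, Objective.WEDGE):
        total = _sxc_weight(S, C, net)
    else:
        total = _induced_weight(union, net)
    if objective in (Objective.WDEGREE, Objective.FWDEGREE):
        return total / n
    if n < 2:
        return 0.0  # degenerate denominator
    return 2.0 * total / (n * (n - 1))


def traveler_next(dapg: Dapg, u: int, traveler: Traveler) -> int | None:
    """Parent chosen by the traveler, or None when u is a root.

    DEEPEST picks a parent on a longest root path (max_depth(p) =
    max_depth(u) - 1); SHARING picks the parent with the largest vertex-set
    overlap.  Ties break to the smallest id.
    """
    parents = dapg.parents[u]
    if not parents:
        return None
    if Traveler(traveler) is Traveler.DEEPEST:
        target = dapg.max_depth[u] - 1
        return min(p for p in parents if dapg.max_depth[p] == target)
    vu = dapg.vertex_set[u]
    return min(parents, key=lambda p: (-len(vu & dapg.vertex_set[p]), p))


def walk_path(dapg: Dapg, u: int, traveler: Traveler) -> list[int]:
    """The node sequence visited climbing from u to a root (u excluded)."""
    path: list[int] = []
    node = u
    while (nxt := traveler_next(dapg, node, traveler)) is not None:
        path.append(nxt)
        node = nxt
    return path


def mine_from_node(
    dapg: Dapg,
    u: int,
    cfg: MiningConfig,
    net: PPINetwork,
    trace: list[str] | None = None,
) -> DenseSubgraph:
    """Run one greedy walk seeded at DAPG node u and return its best DSG.

    The walk path is fixed by the traveler alone; acceptance only selects
    which visited nodes join C.  A step is accepted iff it strictly
    improves the objective and keeps the intersection S nonempty; rejected
    nodes are skipped and the climb continues toward the root.  The
    returned snapshot is the best one seen (the seed itself when nothing
    was ever accepted — ``|C| == 1`` flags that case).
    """
    S = dapg.vertex_set[u]
    C = frozenset([u])
    score = objective_score(S, C, cfg.objective, net)
    if trace is not None:
        trace.append(f"seed {u}: S={sorted(S)} C={sorted(C)} score={score:g}")
    for p in walk_path(dapg, u, cfg.traveler):
        s_new = S & dapg.vertex_set[p]
        if not s_new:
            if trace is not None:
                trace.append(f"  skip {p}: empty intersection")
            continue
        c_new = C | {p}
        sc_new = objective_score(s_new, c_new, cfg.objective, net)
        if sc_new > score:
            S, C, score = s_new, c_new, sc_new
            if trace is not None:
                trace.append(f"  take {p}: S={sorted(S)} C={sorted(C)} score={score:g}")
        elif trace is not None:
            trace.append(f"  skip {p}: score {sc_new:g} <= {score:g}")
    return DenseSubgraph(S=S, C=C, score=score, seed_node=u)


def mine_all(
    dapg: Dapg,
    cfg: MiningConfig,
    net: PPINetwork,
    keep_seed_only: bool = False,
) -> list[DenseSubgraph]:
    """One walk per DAPG node, then maximality filtering.

    Walks that never accepted a step (their DSG is just the seed's closed
    neighborhood with C = {u}) are discarded unless *keep_seed_only* —
    those stars are the input adjacency, not a mined structure, and
    reporting them lets a single hub swallow genuine cliques during
    maximality filtering.
    """
    candidates = [mine_from_node(dapg, u, cfg, net) for u in dapg.nodes]
    if not keep_seed_only:
        candidates = [d for d in candidates if len(d.C) > 1]
    return filter_maximal(candidates)


def filter_maximal(dsgs: list[DenseSubgraph]) -> list[DenseSubgraph]:
    """Keep DSGs whose vertex set S u C is not contained in another's.

    Among DSGs with identical vertex sets, the survivor is the one with the
    highest score, then the smallest seed id.
    """
    best: dict[frozenset[int], DenseSubgraph] = {}
    for d in dsgs:
        v = d.vertices
        cur = best.get(v)
        if cur is None or (-d.score, d.seed_node) < (-cur.score, cur.seed_node):
            best[v] = d
    # larger sets first so each set only needs checking against bigger ones
    distinct = sorted(best.values(), key=lambda d: -len(d.vertices))
    kept: list[DenseSubgraph] = []
    for d in distinct:
        if any(d.vertices < k.vertices for k in kept):
            continue
        kept.append(d)
    return sorted(kept, key=lambda d: d.seed_node)
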