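"""End-to-end protein complex prediction.

Pipeline: node ordering -> sorted closed adjacency lists -> DAPG ->
max-depth annotation -> greedy DSG mining -> candidate complexes
(|S u C| >= minSize, back-translated to protein names) -> optional UNION
grouping, which merges complexes whose pairwise overlap score exceeds a
threshold (default 0.8) by connected components.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .dapg import Phi, build_dapg_from_network
from .evaluation import overlap_score
from .mining import DenseSubgraph, MiningConfig, mine_all
from .network import (
    ComplexSet,
    NodeMapping,
    OrderingScheme,
    PPINetwork,
    build_node_ordering,
)

__all__ = ["Grouping", "PredictConfig", "candidates_from_dsgs", "group_union", "predict"]


class Grouping(str, Enum):
    NONE = "NONE"
    UNION = "UNION"


@dataclass(frozen=True)
class PredictConfig:
    """Everything that determines a prediction run (deterministic given this)."""

    min_size: int = 3
    grouping: Grouping = Grouping.NONE
    union_threshold: float = 0.8
    mining: MiningConfig = field(default_factory=MiningConfig)
    ordering: OrderingScheme = OrderingScheme.FIRST
    seed: int = 0
    mapping: NodeMapping | None = None  # wins over `ordering` when given

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not 0.0 < self.union_threshold <= 1.0:
            raise ValueError("union_threshold must be in (0, 1]")

    def run_label(self) -> str:
        """Compact run descriptor mirroring the tool's log grammar."""
        dm = "" if self.mining.objective.value == "UNONE" else self.mining.objective.value
        return (
            f"DAPGU{dm}({self.ordering.value})"
            f"r{self.mining.phi.value[0]}f{self.grouping.value[0]}"
        )


def candidates_from_dsgs(
    dsgs: list[DenseSubgraph], min_size: int, names: list[str]
) -> ComplexSet:
    """Map each maximal DSG to the complex S u C, keeping those >= min_size."""
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for d in dsgs:
        if len(d.vertices) < min_size:
            continue
        members = frozenset(names[v] for v in d.vertices)
        if members not in seen:
            seen.add(members)
            out.append(members)
    return ComplexSet(out)


def group_union(cs: ComplexSet, threshold: float = 0.8) -> ComplexSet:
    """Merge complexes with pairwise OS > threshold into component unions."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(range(len(cs)))
    cl = cs.complexes
    for i in range(len(cl)):
        for j in range(i + 1, len(cl)):
            if overlap_score(cl[i], cl[j]) > threshold:
                g.add_edge(i, j)
    merged: list[frozenset[str]] = []
    for comp in nx.connected_components(g):
        union: frozenset[str] = frozenset()
        for i in comp:
            union |= cl[i]
        merged.append(union)
    # component order is not meaningful; fix a deterministic one
    merged.sort(key=lambda c: sorted(c))
    return ComplexSet(merged).deduplicated()


def predict(net: PPINetwork, cfg: PredictConfig = PredictConfig()) -> ComplexSet:
    """Predict protein complexes for a PPI network under one configuration."""
    mapping = cfg.mapping or build_node_ordering(net, cfg.ordering, cfg.seed)
    relabeled = net.relabel(mapping)
    dapg = build_dapg_from_network(relabeled, phi=cfg.mining.phi)
    dsgs = mine_all(dapg, cfg.mining, relabeled)
    cs = candidates_from_dsgs(dsgs, cfg.min_size, relabeled.names)
    if cfg.grouping is Grouping.UNION:
        cs = group_union(cs, cfg.union_threshold)
    return cs
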