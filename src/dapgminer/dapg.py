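"""Directed Acyclic Prefix Graph (DAPG) construction.

The DAPG is built from the *closed* adjacency lists of the interaction graph
(each vertex listed in its own neighborhood), all sorted under one total
order phi.  Its nodes are the vertices appearing in the lists; an arc links
every pair of entries that are consecutive in some list.  Sorting every list
under the same total order guarantees acyclicity, so the walk machinery can
rely on topological structure.

Two total orders are supported: ID (ascending numeric id) and FREQUENCY
(descending indegree, i.e. number of appearances over all closed lists,
ties by ascending id).  Each node carries ``vertex_set(u)`` — the vertices
whose lists contain u, which for closed lists is the closed neighborhood of
u — and ``max_depth(u)``, the length of the longest root-to-u path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx

from .network import NodeMapping, PPINetwork

__all__ = ["Phi", "Dapg", "sorted_adjacency", "build_dapg", "compute_max_depth",
           "build_dapg_from_network", "dump_dapg"]


class Phi(str, Enum):
    """Total order used to sort adjacency lists."""

    ID = "ID"
    FREQUENCY = "FREQUENCY"


@dataclass
class Dapg:
    """The prefix DAG: nodes, arcs, per-node vertex sets and depths."""

    nodes: tuple[int, ...]
    arcs: frozenset[tuple[int, int]]
    vertex_set: dict[int, frozenset[int]]
    parents: dict[int, tuple[int, ...]]
    phi: Phi
    source_count: int
    max_depth: dict[int, int] = field(default_factory=dict)

    def roots(self) -> list[int]:
        return [u for u in self.nodes if not self.parents[u]]

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_arcs(self) -> int:
        return len(self.arcs)


def sorted_adjacency(
    net: PPINetwork,
    mapping: NodeMapping | None = None,
    phi: Phi = Phi.ID,
) -> dict[int, list[int]]:
    """Closed adjacency lists of *net*, sorted under the total order *phi*.

    If *mapping* is given the network is first relabelled so ids follow it;
    pass ``None`` when ids already carry the intended order.  Every vertex v
    contributes the list ``sorted({v} | neighbors(v))``.
    """
    if mapping is not None:
        net = net.relabel(mapping)
    phi = Phi(phi)
    closed = {v: set(net.neighbors(v)) | {v} for v in range(net.num_vertices)}
    if phi is Phi.ID:
        key = lambda u: u
    else:
        # indegree of u = number of closed lists containing u = deg(u) + 1
        indeg = {u: net.degree(u) + 1 for u in closed}
        key = lambda u: (-indeg[u], u)
    return {v: sorted(members, key=key) for v, members in closed.items()}


def build_dapg(adjlists: dict[int, list[int]], phi: Phi = Phi.ID) -> Dapg:
    """Assemble the DAPG from consistently ordered adjacency lists.

    Arcs are the deduplicated consecutive pairs across all lists;
    ``vertex_set(u)`` collects the list owners containing u.  A cycle in the
    result means the lists were not sorted under one total order and is
    reported as an error.
    """
    nodes: set[int] = set()
    arcs: set[tuple[int, int]] = set()
    vset: dict[int, set[int]] = {}
    for owner, lst in adjlists.items():
        for u in lst:
            nodes.add(u)
            vset.setdefault(u, set()).add(owner)
        for u1, u2 in zip(lst, lst[1:]):
            arcs.add((u1, u2))
    dg = nx.DiGraph()
    dg.add_nodes_from(nodes)
    dg.add_edges_from(arcs)
    if not nx.is_directed_acyclic_graph(dg):
        raise ValueError("adjacency lists are not consistently ordered: DAPG has a cycle")
    parents: dict[int, tuple[int, ...]] = {
        u: tuple(sorted(dg.predecessors(u))) for u in nodes
    }
    dapg = Dapg(
        nodes=tuple(sorted(nodes)),
        arcs=frozenset(arcs),
        vertex_set={u: frozenset(s) for u, s in vset.items()},
        parents=parents,
        phi=Phi(phi),
        source_count=len(adjlists),
    )
    return compute_max_depth(dapg)


def compute_max_depth(dapg: Dapg) -> Dapg:
    """Annotate each node with the length of the longest path from a root.

    Roots get depth 1; any other node gets 1 + the maximum over its parents,
    computed in topological order.
    """
    dg = nx.DiGraph()
    dg.add_nodes_from(dapg.nodes)
    dg.add_edges_from(dapg.arcs)
    depth: dict[int, int] = {}
    for u in nx.topological_sort(dg):
        ps = dapg.parents[u]
        depth[u] = 1 if not ps else 1 + max(depth[p] for p in ps)
    dapg.max_depth = depth
    return dapg


def build_dapg_from_network(
    net: PPINetwork, mapping: NodeMapping | None = None, phi: Phi = Phi.ID
) -> Dapg:
    """Convenience: sorted_adjacency -> build_dapg -> compute_max_depth."""
    return build_dapg(sorted_adjacency(net, mapping, phi), phi)


def dump_dapg(dapg: Dapg, arc_path: str | Path, node_path: str | Path) -> None:
    """Debug dump: two-column arc list plus a node-attribute TSV."""
    with open(arc_path, "w") as fh:
        for u, v in sorted(dapg.arcs):
            fh.write(f"{u}\t{v}\n")
    with open(node_path, "w") as fh:
        fh.write("label\tvertex_set_size\tmax_depth\n")
        for u in dapg.nodes:
            fh.write(f"{u}\t{len(dapg.vertex_set[u])}\t{dapg.max_depth.get(u, '')}\n")
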