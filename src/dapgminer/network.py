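"""Protein-protein interaction networks, complex sets, and node orderings.

A PPI network is an undirected graph whose vertices are proteins and whose
edges are experimentally supported interactions, optionally carrying a
confidence weight in [0, 1].  Proteins are mapped to dense numeric ids; all
downstream machinery (prefix-graph construction, mining) works on ids and
translates back to protein names only when complexes are reported.

Supported edge-list dialect: two or three whitespace-separated columns per
line (``protein_a protein_b [weight]``), ``#`` comments, blank lines ignored.
Self-interactions are dropped and duplicate/reversed lines collapse to a
single undirected edge.
"""
from __future__ import annotations

import logging
import random
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "GraphType",
    "OrderingScheme",
    "PPINetwork",
    "NodeMapping",
    "ComplexSet",
    "PPIParseError",
    "read_ppi",
    "build_node_ordering",
    "read_complex_set",
    "write_complex_set",
    "merge_references",
    "read_mapping",
    "write_mapping",
]


class PPIParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


class GraphType(str, Enum):
    """Undirected-unweighted (UNONE) vs undirected-weighted (USYM) networks."""

    UNONE = "UNONE"
    USYM = "USYM"


class OrderingScheme(str, Enum):
    """Node-ordering algorithms for mapping protein names to numeric ids."""

    FIRST = "first"
    LEXICOGRAPHIC = "lex"
    DEGREE = "degree"
    RANDOM = "random"
    BFS = "bfs"
    DFS = "dfs"


class PPINetwork:
    """Undirected (optionally weighted) interaction graph over protein ids.

    Vertices are consecutive integer ids ``0..n-1``; ``names[i]`` is the
    protein name of vertex ``i`` (a bijection).  Edges are stored once per
    unordered pair with a weight in [0, 1] (1.0 when unweighted).
    """

    def __init__(self, graph_type: GraphType = GraphType.UNONE):
        self.graph_type = GraphType(graph_type)
        self.graph = nx.Graph()
        self.names: list[str] = []
        self.name_to_id: dict[str, int] = {}

    # -- construction -----------------------------------------------------

    def add_protein(self, name: str) -> int:
        """Register *name* (id assigned in encounter order); idempotent."""
        pid = self.name_to_id.get(name)
        if pid is None:
            pid = len(self.names)
            self.name_to_id[name] = pid
            self.names.append(name)
            self.graph.add_node(pid)
        return pid

    def add_interaction(self, a: str, b: str, weight: float = 1.0) -> None:
        """Add the undirected edge {a, b}; first-seen weight wins; no self-edges."""
        if a == b:
            return
        u, v = self.add_protein(a), self.add_protein(b)
        if not self.graph.has_edge(u, v):
            self.graph.add_edge(u, v, weight=float(weight))

    # -- queries ----------------------------------------------------------

    @property
    def num_vertices(self) -> int:
        return len(self.names)

    @property
    def num_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[int, int]]:
        return iter(self.graph.edges())

    def has_edge(self, u: int, v: int) -> bool:
        return self.graph.has_edge(u, v)

    def weight(self, u: int, v: int) -> float:
        if self.graph_type is GraphType.UNONE:
            return 1.0
        return self.graph.edges[u, v]["weight"]

    def neighbors(self, u: int) -> Iterable[int]:
        return self.graph.neighbors(u)

    def degree(self, u: int) -> int:
        return self.graph.degree(u)

    def protein_set(self) -> frozenset[str]:
        return frozenset(self.names)

    def relabel(self, mapping: "NodeMapping") -> "PPINetwork":
        """Return a copy whose vertex ids follow *mapping* (id = rank in order)."""
        out = PPINetwork(self.graph_type)
        for name in mapping.order:
            out.add_protein(name)
        for u, v, data in self.graph.edges(data=True):
            out.add_interaction(self.names[u], self.names[v], data["weight"])
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PPINetwork({self.graph_type.value}, {self.num_vertices} proteins, "
            f"{self.num_edges} interactions)"
        )


@dataclass(frozen=True)
class NodeMapping:
    """A permutation of protein names defining the name -> id assignment."""

    scheme: OrderingScheme
    order: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("node ordering contains duplicate names")

    def id_of(self, name: str) -> int:
        return self._index[name]

    @property
    def _index(self) -> dict[str, int]:
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {n: i for i, n in enumerate(self.order)}
            self.__dict__["_index_cache"] = idx
        return idx


@dataclass
class ComplexSet:
    """A collection of protein complexes (predicted or reference).

    ``complexes[i]`` is a frozenset of protein names; ``labels[i]`` is an
    optional complex name (gold standards such as CYC2008 carry them).
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if any(not c for c in self.complexes):
            raise ValueError("empty complex in ComplexSet")
        if self.labels is not None and len(self.labels) != len(self.complexes):
            raise ValueError("labels/complexes length mismatch")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def member_sets(self) -> set[frozenset[str]]:
        return set(self.complexes)

    def deduplicated(self) -> "ComplexSet":
        """Drop exact-duplicate member sets, preserving first-seen order."""
        seen: set[frozenset[str]] = set()
        cs: list[frozenset[str]] = []
        labels: list[str] | None = [] if self.labels is not None else None
        for i, c in enumerate(self.complexes):
            if c in seen:
                continue
            seen.add(c)
            cs.append(c)
            if labels is not None:
                labels.append(self.labels[i])  # type: ignore[index]
        return ComplexSet(cs, labels)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_ppi(path: str | Path, graph_type: GraphType = GraphType.UNONE) -> PPINetwork:
    """Parse an edge-list file into a :class:`PPINetwork`.

    Raises :class:`PPIParseError` naming the offending line for malformed
    rows or weights outside [0, 1].  With ``graph_type=UNONE`` any weight
    column is ignored (logged once).
    """
    net = PPINetwork(graph_type)
    warned_weight = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise PPIParseError(
                    f"{path}: line {lineno}: expected at least two columns, got {line!r}"
                )
            a, b = parts[0], parts[1]
            w = 1.0
            if len(parts) >= 3 and graph_type is GraphType.USYM:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise PPIParseError(
                        f"{path}: line {lineno}: weight {parts[2]!r} is not a number"
                    ) from exc
                if not 0.0 <= w <= 1.0:
                    raise PPIParseError(
                        f"{path}: line {lineno}: weight {w} outside [0, 1]"
                    )
            elif len(parts) >= 3 and not warned_weight:
                log.info("%s: weight column ignored for unweighted graph type", path)
                warned_weight = True
            if a == b:
                continue  # self-interaction
            net.add_interaction(a, b, w)
    return net


def build_node_ordering(
    net: PPINetwork, scheme: OrderingScheme, seed: int = 0
) -> NodeMapping:
    """Produce the protein-name permutation for one of the six schemes.

    First = encounter order; Lexicographic = sorted names; Degree =
    decreasing degree (ties by name); Random = seeded shuffle; BFS/DFS =
    traversal from the highest-degree vertex (ties by name), neighbors in
    lexicographic order, restarting per component.
    """
    scheme = OrderingScheme(scheme)
    if net.num_vertices == 0:
        raise ValueError("cannot order an empty network")
    names = list(net.names)
    if scheme is OrderingScheme.FIRST:
        order = names
    elif scheme is OrderingScheme.LEXICOGRAPHIC:
        order = sorted(names)
    elif scheme is OrderingScheme.DEGREE:
        order = sorted(names, key=lambda n: (-net.degree(net.name_to_id[n]), n))
    elif scheme is OrderingScheme.RANDOM:
        order = list(names)
        random.Random(seed).shuffle(order)
    elif scheme in (OrderingScheme.BFS, OrderingScheme.DFS):
        order = _traversal_order(net, depth_first=scheme is OrderingScheme.DFS)
    else:  # pragma: no cover - enum exhausts
        raise ValueError(f"unknown ordering scheme: {scheme}")
    return NodeMapping(scheme=scheme, order=tuple(order), seed=seed)


def _traversal_order(net: PPINetwork, depth_first: bool) -> list[str]:
    # start each component at its unvisited highest-degree vertex (ties by name)
    starts = sorted(range(net.num_vertices), key=lambda u: (-net.degree(u), net.names[u]))
    visited: set[int] = set()
    order: list[str] = []
    for s in starts:
        if s in visited:
            continue
        if depth_first:
            stack = [s]
            while stack:
                u = stack.pop()
                if u in visited:
                    continue
                visited.add(u)
                order.append(net.names[u])
                nbrs = sorted(
                    (v for v in net.neighbors(u) if v not in visited),
                    key=lambda v: net.names[v],
                    reverse=True,  # pop() yields lexicographically first
                )
                stack.extend(nbrs)
        else:
            queue: deque[int] = deque([s])
            visited.add(s)
            while queue:
                u = queue.popleft()
                order.append(net.names[u])
                for v in sorted(net.neighbors(u), key=lambda v: net.names[v]):
                    if v not in visited:
                        visited.add(v)
                        queue.append(v)
    return order


def read_complex_set(path: str | Path) -> ComplexSet:
    """Read one complex per non-empty line (whitespace-separated names)."""
    complexes: list[frozenset[str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            complexes.append(frozenset(parts))
    if not complexes:
        log.warning("%s: empty complex set", path)
    return ComplexSet(complexes).deduplicated()


def write_complex_set(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line, members in lexicographic order."""
    with open(path, "w") as fh:
        for c in cs:
            fh.write(" ".join(sorted(c)) + "\n")


def merge_references(a: ComplexSet, b: ComplexSet) -> ComplexSet:
    """Merge two gold standards, avoiding double-counting.

    A complex of *b* is skipped when its name matches one in *a*, or when its
    member set equals one already present; otherwise it is appended.  When
    either side lacks labels, only member-set identity applies.
    """
    labelled = a.labels is not None and b.labels is not None
    out_cs = list(a.complexes)
    out_labels = list(a.labels) if labelled else None
    seen_sets = set(a.complexes)
    seen_labels = set(a.labels) if labelled else set()
    for i, c in enumerate(b.complexes):
        lbl = b.labels[i] if labelled else None
        if labelled and lbl in seen_labels:
            continue
        if c in seen_sets:
            continue
        out_cs.append(c)
        seen_sets.add(c)
        if labelled:
            out_labels.append(lbl)  # type: ignore[arg-type]
            seen_labels.add(lbl)
    return ComplexSet(out_cs, out_labels)


def read_mapping(path: str | Path, scheme: OrderingScheme = OrderingScheme.FIRST) -> NodeMapping:
    """Read a two-column ``protein_name numeric_id`` table as a NodeMapping."""
    pairs: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise PPIParseError(f"{path}: line {lineno}: expected 'name id'")
            try:
                pairs.append((int(parts[1]), parts[0]))
            except ValueError as exc:
                raise PPIParseError(
                    f"{path}: line {lineno}: id {parts[1]!r} is not an integer"
                ) from exc
    pairs.sort()
    if [i for i, _ in pairs] != list(range(len(pairs))):
        raise PPIParseError(f"{path}: ids are not a permutation of 0..n-1")
    return NodeMapping(scheme=scheme, order=tuple(n for _, n in pairs))


def write_mapping(mapping: NodeMapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(mapping.order):
            fh.write(f"{name} {i}\n")
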