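# Methods

## Model and procedure

The package treats complex prediction as overlapping dense-subgraph
discovery. A PPI network is modeled as an undirected graph with optional
edge confidences in [0, 1]; a dense subgraph is a pair (S, C) with every
cross pair (s, c), s ≠ c, an edge. Because S is maintained as an
intersection of closed neighborhoods of the members of C, validity is an
invariant of the walk, not a post-hoc filter: any (S, C) reachable by the
miner satisfies S × C ⊆ E by construction.

The prefix DAG is built from closed adjacency lists sorted under one total
order. Closed lists (each vertex listed in its own neighborhood) are a
deliberate choice: with open lists, a walk confined to a clique K has
S ∩ C = ∅ at every step, the intersection-size objective is identically
zero, and cliques — the very pattern complexes leave in an interactome —
become undiscoverable. With closed lists, |S ∩ C| reaches |K| exactly when
the walk has assembled the clique.

Every DAPG node seeds one walk to a root. The walk path is fixed by the
traveler function alone; the acceptance rule only chooses which visited
nodes join C. Acceptance requires *strict* objective improvement and a
nonempty intersection; rejected nodes are skipped, not walk-terminating, so
a weakly connected ancestor (e.g. one vertex shared between two cliques)
cannot mask a profitable deeper ancestor.

**Seed-only walks report nothing.** A walk that never accepts a step ends
with S = vertexSet(u), C = {u} — the seed's closed neighborhood, i.e. the
input adjacency restated as a star. Reporting those would let any hub
swallow genuine cliques during maximality filtering: on the toy 7-vertex
network under the FREQUENCY order, the highest-frequency vertex is a DAPG
root, its star covers six of seven vertices, and two of the three planted
cliques would be discarded as "non-maximal". Discarding seed-only walks
("at most one dense subgraph per starting node") restores the intended
output under every ordering; `mine_all(keep_seed_only=True)` exposes the
raw behavior for inspection.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ordering | first | protein-name → id scheme (first/lex/degree/random/bfs/dfs) |
| φ (sorting) | ID | adjacency-list total order; FREQUENCY = descending appearance count, ties by ascending id |
| traveler | deepest | parent choice during the walk; `sharing` maximizes vertex-set overlap |
| objective | UNONE | \|S ∩ C\|; alternatives WDEGREE, WEDGE, FWDEGREE, FWEDGE for weighted runs |
| minSize | 3 | smallest reportable complex (dimers are indistinguishable from single edges) |
| grouping / threshold | NONE / 0.8 | UNION merges complex pairs with OS > 0.8 via connected components |
| match threshold w | 0.25 | OS level declaring a prediction/reference match (0.2 selectable) |
| MMR floor | 0.2 | minimum OS for an edge of the MMR bipartite graph |

Deterministic tie-breaks throughout (smallest id in both travelers;
lexicographic names for degree ties and traversal expansion; BFS/DFS start
at the highest-degree vertex, restarting per component): the source texts
leave these open, and any fixed rule makes runs reproducible. UNION
grouping merges by connected components in a single pass — component
semantics are order-independent, and no fix-point iteration is attempted
after merging.

## Evaluation conventions

- FMeasure follows the conventional TP/FP/FN definitions over OS matches;
  recall divides the number of matched *predictions* by (TP + FN) with FN
  counted over *references*, as is standard in this literature.
- PPV uses the Brohée–van Helden denominator Σ_j Σ_i T_ij by default;
  the per-prediction-size denominator is selectable
  (`accuracy_stats(..., ppv_denominator="size")`). Predictions overlapping
  no reference contribute nothing to either PPV sum under the default.
- MMR is computed by an exact rectangular assignment (scipy's
  `linear_sum_assignment`), not the greedy per-reference argmax; the test
  suite verifies equality with brute-force enumeration over all one-to-one
  mappings on instances up to 6 × 6.
- Reference filtering drops a gold-standard complex when fewer than half of
  its members occur in the network, truncates the rest to present members,
  and drops complexes reduced below two members (a singleton is not a
  complex).
- Overlap histograms support two pair populations: the pairs of the MMR
  matching (default) or all reference × prediction pairs above the floor.

## Synthetic data

`planted_network` emulates the patterns real complexes leave in
interactomes: each planted complex is a clique of 3–6 proteins (defaults),
optionally missing one edge (the near-clique pattern of several curated
tetramers); with probability `overlap_fraction` a complex shares one
protein with its predecessor (multifunctional proteins); background
vertices and seeded Erdős–Rényi edges over currently-absent pairs stand in
for the sparse noisy remainder. It does **not** reproduce degree-sequence
heavy tails, correlated false negatives of affinity-purification screens,
or weight miscalibration — so passing recovery tests demonstrates
correctness of the machinery on clique-like signal plus uniform noise, not
performance on any real interactome.

The robustness check adds 5% and 10% uniformly random extra edges to a
10-complex planted network (background edge probability 0.02, five seeds)
and requires the mean absolute MMR change against the planted truth to stay
below 0.15. The scaling check times the full pipeline on planted networks
of roughly 100, 500 and 2000 proteins (complex count scaled as n/5,
background edge probability 2/n) and asserts a monotone trend only,
consistent with the O(n·e·(h+m)) cost model; these sizes keep the whole
suite in seconds while spanning a 20× range.

## Numerical and degenerate cases

- WEDGE/FWEDGE return 0 when |S ∪ C| < 2 (degenerate denominator).
- Weighted objectives on an unweighted network use w ≡ 1.
- Duplicate edge lines keep the first weight seen; self-interactions are
  dropped at parse time.
- OS thresholds: matches use ≥ w; UNION grouping uses strictly > threshold.
- Empty prediction sets evaluate to an all-zero report rather than an error.

## Known limitations

- The miner is a greedy heuristic: one walk per node, no backtracking, no
  guarantee of finding the best R ⊆ P on a path (that subset search is
  exponential). Planted-clique completeness holds empirically on disjoint
  unions (tested against an exhaustive clique enumerator) but is not a
  theorem for arbitrary graphs.
- FREQUENCY-order behavior depends on the descending-count convention
  adopted here; the ascending variant yields different (generally worse)
  prefix sharing.
- The false-positive screen requires only a shared PDB id, not shared
  chains, and treats "part of a gold-standard complex" as member-set
  inclusion — the most conservative reading.
- Gold-standard merging trusts complex labels: identical labels collapse to
  the first catalog's member set even when the sets differ.
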