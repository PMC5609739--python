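# dapgminer

Protein complex prediction from protein–protein interaction (PPI) networks by
mining **overlapping dense subgraphs** over a Directed Acyclic Prefix Graph
(DAPG), with a full clustering-evaluation suite and a structural screening
step for false positives.

## Who this is for

Computational biologists who have a PPI network as an edge list (Collins,
Krogan, Gavin, DIP, BioGRID, HPRD or anything in that shape) and want
candidate protein complexes — including complexes that *share* proteins,
which partition-based clustering (e.g. MCL) cannot report — plus the standard
benchmark metrics against gold-standard catalogs such as CYC2008, SGD, MIPS,
CORUM or PCDq.

## The method

A PPI network is a graph G = (V, E, w), w: E → [0, 1] the confidence that an
interaction is real. A **dense subgraph** (DSG) is a pair (S, C) of vertex
sets with S × C ⊆ E (self-pairs excluded); it generalizes cliques (S = C) and
bicliques (S ∩ C = ∅). The pipeline:

1. **Node ordering.** Protein names are mapped to numeric ids by one of six
   schemes: first-seen, lexicographic, decreasing degree, seeded random, BFS
   or DFS traversal order.
2. **DAPG construction.** Each vertex contributes its *closed* adjacency list
   (itself included), sorted under a total order φ — ascending id (`ID`) or
   descending appearance count (`FREQUENCY`). DAPG nodes are the list
   entries; an arc joins each consecutive pair. One consistent total order
   guarantees acyclicity. Each node u carries `vertexSet(u)` (the vertices
   whose lists contain u — its closed neighborhood) and `maxDepth(u)` (the
   longest root-to-u path).
3. **Greedy mining.** Every DAPG node seeds one walk toward a root, steered
   by an *inverse traveler function* (`Deepest`: follow the longest-path
   parent; `Sharing`: follow the parent with the largest vertexSet overlap).
   Starting from S = vertexSet(u), C = {u}, each visited node p is accepted
   (S ← S ∩ vertexSet(p), C ← C ∪ {p}) exactly when it strictly improves the
   objective — intersection size |S ∩ C| by default, or weighted
   degree/edge density (`WDEGREE`, `WEDGE`, and `FWDEGREE`/`FWEDGE` over the
   induced subgraph of S ∪ C). Walks that never improve on their seed report
   nothing; the rest yield one DSG each, and only the maximal ones (under
   inclusion of S ∪ C) survive.
4. **Complex formation.** Each maximal DSG becomes the candidate complex
   S ∪ C if it has at least `minSize` (default 3) proteins; optional `UNION`
   grouping merges candidate pairs whose overlap score exceeds 0.8.

**Evaluation.** Overlap score OS(pc, rc) = |pc ∩ rc|² / (|pc|·|rc|);
FMeasure from OS-matched predictions at threshold w (0.25 default);
Sn/PPV/Acc from the reference × prediction overlap matrix (Brohée–van Helden
convention); **MMR** — the total OS of an exact maximum-weight one-to-one
matching between reference and predicted complexes, divided by the number of
reference complexes; perfect-match counts; cumulative overlap histograms;
and ClusterONE-style reference filtering for proteins absent from the
network. `fp_screen` flags predictions absent from every gold standard whose
members co-occur in a purified PDB structure, using local snapshot tables
(no network access).

## Worked example

```bash
python examples/predict_toy_network.py
```

```
network: 7 proteins, 12 interactions
phi=ID: 3 complexes -> ['1 2 3', '3 4 5 6', '4 5 6 7']
phi=FREQUENCY: 3 complexes -> ['1 2 3', '3 4 5 6', '4 5 6 7']
ground truth : ['1 2 3', '3 4 5 6', '4 5 6 7']
```

The toy interactome is the union of three cliques; the miner reports exactly
those three complexes under either adjacency-list order. Note proteins 3–6
each belong to two complexes — the overlap is reported, not averaged away.

From a shell, the same run over files:

```bash
dapgminer predict -i network.txt -o predicted.txt -r ID -f NONE --min-size 3
dapgminer eval --pred predicted.txt --ref cyc2008.txt --filter-ref --ppi network.txt
dapgminer simulate -o sim.txt --truth truth.txt --n-complexes 10 --seed 7
dapgminer fpscreen --pred predicted.txt --ref merged_refs.txt \
    --chains sifts_snapshot.tsv -o potential_complexes.csv
```

Other examples: `simulate_and_evaluate.py` (planted complexes in a noisy
network, full metric battery), `robustness_random_edges.py` (MMR stability
under 5–10% spurious edges), `screen_false_positives.py` (structural
corroboration of a novel prediction).

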