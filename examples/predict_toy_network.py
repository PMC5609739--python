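"""Predict complexes on the 7-vertex toy interactome.

The network is the union of three overlapping cliques; the pipeline builds
the prefix DAG over the id-sorted closed adjacency lists, mines one dense
subgraph per DAG node with the Deepest traveler and the intersection-size
objective, and keeps the maximal results of size >= 3.  The printed sets
are the three cliques — proteins 3, 4, 5 and 6 sit in two complexes each,
which partition-based clustering could not report.
"""
from dapgminer import MiningConfig, Phi, PredictConfig, fig1_fixture, predict

net, truth = fig1_fixture()
print(f"network: {net.num_vertices} proteins, {net.num_edges} interactions")

for phi in (Phi.ID, Phi.FREQUENCY):
    cfg = PredictConfig(mining=MiningConfig(phi=phi))
    complexes = predict(net, cfg)
    pretty = sorted(" ".join(sorted(c)) for c in complexes)
    print(f"phi={phi.value}: {len(complexes)} complexes -> {pretty}")

print("ground truth :", sorted(" ".join(sorted(c)) for c in truth))
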