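"""Infer signaling cascades linking source genes to target genes.

Runs the iterative shortest-path linker on a synthetic graph with a planted
cascade. Passing a SIF file as the first argument instead runs the
TNF-receptor demo: the bundled GMT fixtures hold three upregulated
TNF-family receptors (sources) and the upregulated apoptosis / TNF-pathway
genes (targets); supply your own directed signaling network to trace how the
receptors reach the apoptosis effectors.
"""

import sys

import weaknet as wn
from weaknet.cascade import CascadePartition

if len(sys.argv) > 1:  # user-supplied signaling graph: TNF receptor demo
    graph = wn.read_sif(sys.argv[1])
    sources = wn.read_gmt("examples/data/tnf_receptor_sources.gmt")["tnf_receptors_up"]
    targets_gmt = wn.read_gmt("examples/data/tnf_apoptosis_targets.gmt")
    targets = targets_gmt["apoptosis_up"] | targets_gmt["tnf_signaling_up"]
else:
    cfg = wn.SimulationConfig(seed=1, n_planted_cascades=2)
    graph, truth = wn.generate_signaling_graph(cfg)
    sources, targets = truth.planted_sources, truth.planted_targets

partition = CascadePartition.from_sets(sources, targets, graph)
net = wn.infer_cascades(graph, partition, max_depth=6, tie_policy="all")

print(f"inferred network: {len(net.nodes)} nodes, {len(net.edges)} edges")
print("roles:", net.role_counts())
for it in net.iteration_log:
    pairs = ", ".join(
        f"{p['source']}->{p['target']} ({p['length']} hops, {p['n_paths']} paths)"
        for p in it["pairs"]
    )
    print(f"iteration {it['iteration']}: promoted {it['promoted']}; {pairs}")
if net.unreachable_targets:
    print("unreachable targets:", sorted(net.unreachable_targets))
print(wn.summarize_network(net).to_string(index=False))
# Targets found on a shortest path are promoted to sources and can seed the
# next iteration; linker genes are the intermediate cascade members.
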