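"""Generate a synthetic two-cohort weak-activation study.

Builds a directed signaling graph with overlapping pathways, plants two
weakly activated pathways (fold changes 1.1-1.5) and one 3-hop signaling
cascade, and simulates two independent case/control expression cohorts.
"""

from pathlib import Path

import weaknet as wn

cfg = wn.SimulationConfig(seed=1)
graph, truth = wn.generate_signaling_graph(cfg)
cohorts = wn.generate_expression_cohorts(cfg, graph, truth)
paths = wn.write_simulation(Path("example_output/simulation"), cfg, graph, truth, cohorts)

print(f"graph: {graph.n_nodes()} genes, {graph.n_edges()} directed interactions")
print(f"pathways: {len(graph.pathways)}, activated: {sorted(truth.activated_pathways)}")
print(f"planted cascade: {sorted(truth.planted_cascade_edges)}")
for cohort in cohorts:
    n_ctrl = len(cohort.samples_in_group("control"))
    n_case = len(cohort.samples_in_group("case"))
    print(f"{cohort.cohort}: {n_ctrl} control + {n_case} case samples")
print("written:", ", ".join(sorted(paths)))
# The activated pathways' genes carry true fold changes between 1.1 and 1.5;
# every other gene has fold change exactly 1 - the weak-activation regime.
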