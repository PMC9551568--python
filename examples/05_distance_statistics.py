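"""Compare shortest-distance distributions of gene groups to a target set.

On a well-connected synthetic graph with ten planted 2-hop cascades, the
planted source group sits closer to the targets than the background of all
other signaling genes.
"""

import weaknet as wn

cfg = wn.SimulationConfig(
    seed=1, n_genes=300, n_pathways=12, pathway_size_range=(10, 18),
    edge_density_within=0.10, edge_density_between=0.006,
    n_planted_cascades=10, planted_cascade_length=2,
)
graph, truth = wn.generate_signaling_graph(cfg)

profile = wn.distance_profiles(
    graph, {"sources": truth.planted_sources}, graph.nodes, truth.planted_targets
)
finite = profile[profile["n_reachable_targets"] > 0]
for name, sub in finite.groupby("group"):
    print(f"{name}: {len(sub)} genes reach a target, "
          f"median avg distance {sub['avg_distance'].median():.2f}")

res = wn.compare_groups(profile, "sources", "background")
print(f"Mann-Whitney U = {res['statistic']:.1f}, p = {res['p_value']:.3g} "
      f"(medians {res['median_a']:.2f} vs {res['median_b']:.2f})")
# Unreachable (gene, target) pairs are excluded from each mean rather than
# capped; n_reachable_targets makes that censoring visible per gene.
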