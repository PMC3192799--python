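"""Build expression-weighted interactomes for two conditions.

Generates a small planted interactome with a baseline expression profile and
heat-shock-like fold changes, imputes missing values with the profile
medians, and converts abundances to edge weights by endpoint averaging.
"""

import numpy as np

import stressnet as sn

spec = sn.PlantedNetworkSpec(
    n_modules=4, module_size=30, overlap_nodes_per_pair=3,
    p_intra=0.9, p_inter=0.01, hub_boost=5, seed=1,
)
graph, membership = sn.generate_planted_interactome(spec)
graph = sn.giant_component(graph)
print(f"interactome: {graph.number_of_nodes()} proteins, {graph.number_of_edges()} interactions")

baseline = sn.generate_baseline_profile(graph.nodes(), missing_fraction=0.08, seed=2)
stress = sn.StressSpec(up_modules=frozenset({3}), down_modules=frozenset({0}), seed=3)
fold = sn.generate_stress_foldchanges({n: membership[n] for n in graph.nodes()}, stress)

baseline = sn.impute_missing(baseline, graph.nodes())
fold = sn.impute_missing(fold, graph.nodes())
print(f"imputed {baseline.n_missing_on_network} baseline and {fold.n_missing_on_network} "
      "fold-change values with profile medians")

w_rest = sn.link_weights(graph, baseline, condition_label="unstressed")
w_shock = sn.link_weights(graph, sn.stressed_abundance(baseline, fold),
                          condition_label="stressed")

_, weights_rest = w_rest.edge_weights()
_, weights_shock = w_shock.edge_weights()
print(f"median interaction weight: {np.median(weights_rest):.3f} (unstressed) "
      f"-> {np.median(weights_shock):.3f} (stressed)")
down = [n for n in graph.nodes() if 0 in membership[n]]
down_edges = [w_rest.weight(a, b) / w_shock.weight(a, b) for a, b in graph.edges()
              if a in set(down) and b in set(down)]
print(f"interactions inside the repressed module weakened {np.median(down_edges):.1f}-fold:")
print("both endpoint abundances fall, so every interaction between them loses weight")
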