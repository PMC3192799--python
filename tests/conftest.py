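import networkx as nx
import numpy as np
import pytest

import stressnet as sn
from stressnet.weighting import WeightedInteractome


def unit_weighted(graph: nx.Graph) -> WeightedInteractome:
    g = graph.copy()
    nx.set_edge_attributes(g, 1.0, "weight")
    return WeightedInteractome(graph=g)


@pytest.fixture
def dyad() -> WeightedInteractome:
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0)
    return WeightedInteractome(graph=g)


@pytest.fixture
def two_cliques_bridge() -> tuple[WeightedInteractome, str]:
    """Two K4 cliques plus one bridge node with equal-weight edges to both."""
    g = nx.Graph()
    left = [f"l{i}" for i in range(4)]
    right = [f"r{i}" for i in range(4)]
    for group in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(group[i], group[j], weight=1.0)
    g.add_edge("mm", "l0", weight=0.5)
    g.add_edge("mm", "r0", weight=0.5)
    return WeightedInteractome(graph=g), "mm"


@pytest.fixture
def planted_small():
    """4 planted modules of 30, unit weights, seed 0 (detectable regime)."""
    spec = sn.PlantedNetworkSpec(
        n_modules=4, module_size=30, overlap_nodes_per_pair=0, p_intra=0.9, p_inter=0.01, seed=0
    )
    graph, membership = sn.generate_planted_interactome(spec)
    graph = sn.giant_component(graph)
    return unit_weighted(graph), {n: membership[n] for n in graph.nodes()}


@pytest.fixture
def stress_pair():
    """Small paired unstressed/stressed interactomes with planted up/down modules."""
    spec = sn.PlantedNetworkSpec(
        n_modules=4, module_size=30, overlap_nodes_per_pair=3, p_intra=0.9, p_inter=0.01, seed=11
    )
    graph, membership = sn.generate_planted_interactome(spec)
    graph = sn.giant_component(graph)
    membership = {n: membership[n] for n in graph.nodes()}
    baseline = sn.generate_baseline_profile(graph.nodes(), missing_fraction=0.05, seed=12)
    stress = sn.StressSpec(up_modules=frozenset({3}), down_modules=frozenset({0}), seed=13)
    fold = sn.generate_stress_foldchanges(membership, stress)
    b = sn.impute_missing(baseline, graph.nodes())
    f = sn.impute_missing(fold, graph.nodes())
    w_before = sn.link_weights(graph, b, condition_label="unstressed")
    w_after = sn.link_weights(graph, sn.stressed_abundance(b, f), condition_label="stressed")
    return w_before, w_after, membership


def brute_force_shortest_paths(w: WeightedInteractome, cost_transform: str = "reciprocal") -> dict:
    """Bellman-Ford style relaxation oracle, independent of scipy's Dijkstra."""
    from stressnet.topology import path_cost

    nodes = w.nodes
    w_max = max(d["weight"] for _, _, d in w.graph.edges(data=True))
    dist = {a: {b: np.inf for b in nodes} for a in nodes}
    for a in nodes:
        dist[a][a] = 0.0
    edges = [
        (a, b, path_cost(d["weight"], cost_transform, w_max=w_max))
        for a, b, d in w.graph.edges(data=True)
    ]
    for src in nodes:
        for _ in range(len(nodes) - 1):
            changed = False
            for a, b, c in edges:
                if dist[src][a] + c < dist[src][b]:
                    dist[src][b] = dist[src][a] + c
                    changed = True
                if dist[src][b] + c < dist[src][a]:
                    dist[src][a] = dist[src][b] + c
                    changed = True
            if not changed:
                break
    return dist
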