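"""Weighted topology metrics: effective degrees, hub census, weighted
diameter and shortest-path distribution, extreme-link subnetworks.

The "effective number" of a set of nonnegative values V is

    N_eff(V) = (sum V_i)^2 / (sum V_i^2),

a scale-invariant continuous count: it equals the number of nonzero values
when they are all equal and shrinks towards 1 as the set becomes dominated
by a single value.  Applied to a node's incident edge weights it yields the
effective (weighted) degree.

Shortest paths are run on edge *costs* derived from interaction strengths.
The default transform is the reciprocal, cost = 1/w, so weakening
interactions lengthens paths; ``raw`` (cost = w) and ``neglog``
(cost = -log(w/w_max), always nonnegative) are available as hooks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .weighting import WeightedInteractome

__all__ = [
    "TopologySummary",
    "effective_number",
    "effective_degree",
    "all_effective_degrees",
    "hub_census",
    "path_cost",
    "cost_matrix",
    "pairwise_cost_matrix",
    "weighted_diameter",
    "shortest_path_distribution",
    "extreme_link_subnetwork",
    "topology_summary",
]

COST_TRANSFORMS = ("reciprocal", "raw", "neglog")


@dataclass
class TopologySummary:
    """One-row summary of a weighted interactome (the per-condition report)."""

    condition_label: str
    n_nodes: int
    n_edges: int
    median_weight: float
    weighted_diameter: float
    mean_weighted_shortest_path: float
    median_effective_degree: float
    hub_threshold: float
    n_hubs: int


def effective_number(values) -> float:
    """(sum V)^2 / (sum V^2) for a nonnegative value set with at least one positive entry."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value set")
    if np.any(v < 0):
        raise ValueError("effective number requires nonnegative values")
    ssq = float(np.dot(v, v))
    if ssq == 0.0:
        raise ValueError("effective number undefined for an all-zero value set")
    s = float(v.sum())
    return s * s / ssq


def effective_degree(w: WeightedInteractome, node: str) -> float:
    """Effective number of a node's incident edge weights; 0 for an isolated node."""
    ws = [d["weight"] for _, _, d in w.graph.edges(node, data=True)]
    if not ws:
        return 0.0
    return effective_number(ws)


def all_effective_degrees(w: WeightedInteractome) -> dict[str, float]:
    return {n: effective_degree(w, n) for n in w.graph.nodes()}


def hub_census(
    w_reference: WeightedInteractome,
    w_query: WeightedInteractome,
    top_fraction: float = 0.01,
) -> tuple[float, int]:
    """Hub threshold from the reference condition; hub count in the query.

    The threshold is the largest effective degree *not* in the reference's top
    ``top_fraction`` (rank-based, exclusive: a hub must strictly exceed it),
    so calling with the reference as its own query returns the reference hub
    count.  ``top_fraction=1`` degenerates to "every node is a hub".
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if set(w_reference.graph.nodes()) != set(w_query.graph.nodes()):
        raise ValueError("reference and query must share a node set")
    ref = np.array(sorted(all_effective_degrees(w_reference).values(), reverse=True))
    n = ref.size
    k = int(np.floor(top_fraction * n))
    k = max(k, 1)
    threshold = -np.inf if k >= n else float(ref[k])
    q = np.fromiter(all_effective_degrees(w_query).values(), dtype=float)
    return threshold, int(np.sum(q > threshold))


def path_cost(weight: float, transform: str = "reciprocal", w_max: float | None = None) -> float:
    """Strength-to-cost transform for shortest paths (default cost = 1/w)."""
    if weight <= 0:
        raise ValueError("path cost requires a positive weight")
    if transform == "reciprocal":
        return 1.0 / weight
    if transform == "raw":
        return float(weight)
    if transform == "neglog":
        if w_max is None:
            raise ValueError("neglog transform requires w_max")
        return float(np.log(w_max / weight))
    raise ValueError(f"unknown cost transform {transform!r}; expected one of {COST_TRANSFORMS}")


def cost_matrix(w: WeightedInteractome, cost_transform: str = "reciprocal") -> tuple[list[str], csr_matrix]:
    """Sparse symmetric edge-cost matrix over the canonical (sorted) node order."""
    nodes = w.nodes
    index = {n: i for i, n in enumerate(nodes)}
    w_max = max((d["weight"] for _, _, d in w.graph.edges(data=True)), default=1.0)
    rows, cols, data = [], [], []
    for a, b, d in w.graph.edges(data=True):
        c = path_cost(d["weight"], cost_transform, w_max=w_max)
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        data += [c, c]
    n = len(nodes)
    return nodes, csr_matrix((data, (rows, cols)), shape=(n, n))


def pairwise_cost_matrix(w: WeightedInteractome, cost_transform: str = "reciprocal") -> tuple[list[str], np.ndarray]:
    """All-pairs weighted shortest-path costs (exact all-sources Dijkstra)."""
    nodes, costs = cost_matrix(w, cost_transform)
    dist = dijkstra(costs, directed=False)
    if np.isinf(dist).any():
        raise ValueError("graph is disconnected; extract the giant component first")
    return nodes, dist


def weighted_diameter(w: WeightedInteractome, cost_transform: str = "reciprocal") -> float:
    """Maximum over node pairs of the minimum total path cost (exact)."""
    _, dist = pairwise_cost_matrix(w, cost_transform)
    return float(dist.max())


def shortest_path_distribution(w: WeightedInteractome, cost_transform: str = "reciprocal") -> tuple[np.ndarray, float]:
    """All n(n-1)/2 unordered-pair shortest-path costs and their mean."""
    _, dist = pairwise_cost_matrix(w, cost_transform)
    iu = np.triu_indices(dist.shape[0], k=1)
    pair_costs = dist[iu]
    return pair_costs, float(pair_costs.mean())


def extreme_link_subnetwork(
    w: WeightedInteractome,
    fraction: float = 0.04,
    side: str = "top",
    highlight_fraction: float = 0.01,
) -> tuple[nx.Graph, nx.Graph]:
    """Subnetwork of the strongest (or weakest) links.

    Edges are ranked by (weight, edge id); the chosen side's ``fraction`` is
    retained and the inner ``highlight_fraction`` flagged with
    ``tier="highlight"`` (the rest get ``tier="retained"``).  Returns the
    subnetwork and, separately, its giant component.  Ranking ties are broken
    by the lexicographic edge id, making the selection deterministic.
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    if not 0 < highlight_fraction <= fraction <= 1:
        raise ValueError("need 0 < highlight_fraction <= fraction <= 1")
    ranked = sorted(
        ((d["weight"], (min(a, b), max(a, b))) for a, b, d in w.graph.edges(data=True)),
        reverse=(side == "top"),
    )
    m = len(ranked)
    n_keep = int(round(fraction * m))
    n_flag = int(round(highlight_fraction * m))
    sub = nx.Graph()
    for rank, (weight, (a, b)) in enumerate(ranked[:n_keep]):
        tier = "highlight" if rank < n_flag else "retained"
        sub.add_edge(a, b, weight=weight, tier=tier)
    if sub.number_of_nodes() == 0:
        return sub, nx.Graph()
    comps = list(nx.connected_components(sub))
    max_size = max(len(c) for c in comps)
    giant_nodes = min((c for c in comps if len(c) == max_size), key=min)
    return sub, sub.subgraph(giant_nodes).copy()


def topology_summary(
    w: WeightedInteractome,
    w_reference: WeightedInteractome | None = None,
    cost_transform: str = "reciprocal",
    hub_fraction: float = 0.01,
) -> TopologySummary:
    """Main weighted-topology attributes of one condition.

    The hub threshold is always taken from ``w_reference`` (the unstressed
    network); by default the network is its own reference.
    """
    ref = w if w_reference is None else w_reference
    _, weights = w.edge_weights()
    pair_costs, mean_sp = shortest_path_distribution(w, cost_transform)
    eff = np.fromiter(all_effective_degrees(w).values(), dtype=float)
    threshold, n_hubs = hub_census(ref, w, top_fraction=hub_fraction)
    return TopologySummary(
        condition_label=w.condition_label,
        n_nodes=w.number_of_nodes(),
        n_edges=w.number_of_edges(),
        median_weight=float(np.median(weights)),
        weighted_diameter=float(pair_costs.max()),
        mean_weighted_shortest_path=mean_sp,
        median_effective_degree=float(np.median(eff)),
        hub_threshold=threshold,
        n_hubs=n_hubs,
    )
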