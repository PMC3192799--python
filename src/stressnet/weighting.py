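"""Expression-derived edge weights for the interactome.

The weighting procedure has two steps.  First, an approximate stressed
abundance is obtained per protein by multiplying its baseline mRNA level by
its stress fold-change ratio.  Second, each interaction weight is the average
(optionally the product) of the abundances of the two interacting proteins.
Proteins without an expression value are imputed with the median of the
observed values of the same profile — the median rather than the mean,
because expression distributions carry extreme values.

The unstressed and stressed networks built this way share the same edge set
and differ only in their weights, which is what makes paired per-edge and
per-node comparisons meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .io import ExpressionProfile

__all__ = [
    "WeightedInteractome",
    "impute_missing",
    "stressed_abundance",
    "link_weights",
    "rescaled_log_weights",
]


@dataclass
class WeightedInteractome:
    """A simple undirected graph whose edges carry positive weights.

    ``graph`` stores the weight on each edge under the ``"weight"`` key;
    ``condition_label`` names the condition (e.g. ``"unstressed"``).
    """

    graph: nx.Graph
    condition_label: str = ""

    def __post_init__(self) -> None:
        for a, b, d in self.graph.edges(data=True):
            w = d.get("weight")
            if w is None or not math.isfinite(w) or w <= 0:
                raise ValueError(f"edge ({a!r},{b!r}) must carry a finite positive weight, got {w}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    def weight(self, a: str, b: str) -> float:
        return float(self.graph[a][b]["weight"])

    def edge_weights(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Edges in a canonical sorted order with their weight vector."""
        edges = sorted((min(a, b), max(a, b)) for a, b in self.graph.edges())
        w = np.array([self.graph[a][b]["weight"] for a, b in edges], dtype=float)
        return edges, w

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def impute_missing(profile: ExpressionProfile, nodes: Iterable[str]) -> ExpressionProfile:
    """Fill network nodes absent from ``profile`` with the profile median.

    The substitution value is the median of *all* observed values in the
    profile (not only those on the network).  The number of imputed network
    nodes is recorded in ``n_missing_on_network``.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("node set is empty")
    if not profile.values:
        raise ValueError("cannot impute from a profile with zero observed values")
    med = float(np.median(list(profile.values.values())))
    values = {n: profile.values[n] for n in nodes if n in profile.values}
    missing = [n for n in nodes if n not in profile.values]
    for n in missing:
        values[n] = med
    return ExpressionProfile(values=values, n_missing_on_network=len(missing))


def stressed_abundance(baseline: ExpressionProfile, foldchange: ExpressionProfile) -> ExpressionProfile:
    """Element-wise product baseline(n) * foldchange(n) over a shared node set."""
    if set(baseline.values) != set(foldchange.values):
        raise ValueError("baseline and fold-change profiles must cover the same node set; impute first")
    values = {n: baseline.values[n] * foldchange.values[n] for n in baseline.values}
    return ExpressionProfile(values=values)


def link_weights(
    network: nx.Graph,
    abundance: ExpressionProfile,
    combine: str = "mean",
    condition_label: str = "",
) -> WeightedInteractome:
    """Turn per-node abundances into per-edge weights.

    ``combine="mean"`` (default) sets w(a,b) = (A(a)+A(b))/2;
    ``combine="product"`` sets w(a,b) = A(a)*A(b).  A zero weight after
    combination signals degenerate input and is rejected rather than dropped,
    because the shortest-path cost transform requires strictly positive
    weights.
    """
    if combine not in ("mean", "product"):
        raise ValueError(f"unknown combine rule {combine!r}")
    missing = [n for n in network.nodes() if n not in abundance.values]
    if missing:
        raise ValueError(f"abundance profile lacks {len(missing)} network nodes (e.g. {sorted(missing)[:3]})")
    g = nx.Graph()
    g.add_nodes_from(network.nodes())
    for a, b in network.edges():
        xa, xb = abundance.values[a], abundance.values[b]
        w = (xa + xb) / 2.0 if combine == "mean" else xa * xb
        if w <= 0:
            raise ValueError(
                f"degenerate zero weight on edge ({a!r},{b!r}): both endpoint abundances are zero; "
                "pre-filter zero-abundance nodes before weighting"
            )
        g.add_edge(a, b, weight=w)
    return WeightedInteractome(graph=g, condition_label=condition_label)


def rescaled_log_weights(w: WeightedInteractome, scale: float = 1000.0) -> WeightedInteractome:
    """Optional log-rescaled weight variant: w -> log10(scale * w).

    The rescaling keeps the transformed weights positive as long as
    ``scale * w > 1`` for every edge; violations are rejected.  Not the
    default weighting — provided as a transform hook.
    """
    g = nx.Graph()
    g.add_nodes_from(w.graph.nodes())
    for a, b, d in w.graph.edges(data=True):
        t = math.log10(scale * d["weight"])
        if t <= 0:
            raise ValueError(f"log-rescaled weight nonpositive on edge ({a!r},{b!r}); increase scale")
        g.add_edge(a, b, weight=t)
    return WeightedInteractome(graph=g, condition_label=w.condition_label + "+log")
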