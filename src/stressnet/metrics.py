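"""Overlap, inter-module connectivity and bridgeness metrics.

Modules are coarse-grained into a module graph whose link weight between
modules i and j sums per-node overlap contributions

    O_ij(n) = 2 * H_i(n) * H_j(n) / c(n),

the factor 2 counting both directions between the modules.  On top of this:

* the *effective number of modules* of a node is the effective number of its
  membership vector {H_i(n)} — its modular overlap;
* the *effective degree of a module* is the effective number of its link
  weights {O_ij} to all neighbouring modules;
* the *bridgeness* of a node sums, over adjacent module pairs (O_ij > 0),
  the smaller of its two memberships — high for saddle-point nodes sitting
  between community hills.

Between-condition dynamics are summarised per node (centrality change group
A-E, bridge dynamics class) and screened for "bridging integrators": nodes
whose modular overlap and community centrality both rise under stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .moduland import ModularDecomposition
from .topology import effective_number

__all__ = [
    "ModuleGraph",
    "NodeDynamics",
    "effective_module_count",
    "module_link_weights",
    "module_effective_degree",
    "bridgeness",
    "all_bridgeness",
    "classify_centrality_change",
    "classify_bridge_dynamics",
    "node_dynamics",
    "node_dynamics_table",
    "screen_bridging_integrators",
]

DEFAULT_CHANGE_THRESHOLDS = (1.0, 100.0, 1000.0)
DEFAULT_BRIDGE_CUT = 10.0
DEFAULT_FOLD_FLAG = 1e5


@dataclass
class ModuleGraph:
    """Coarse-grained network of modules with symmetric link weights O_ij."""

    modules: list[str]  # summit node anchoring each module
    weights: np.ndarray  # (m, m) symmetric, zero diagonal

    def link_weight(self, i: int, j: int) -> float:
        return float(self.weights[i, j])

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Unordered module pairs with positive link weight."""
        iu = np.triu_indices(self.n_modules, k=1)
        return [(int(i), int(j)) for i, j in zip(*iu) if self.weights[i, j] > 0]


@dataclass
class NodeDynamics:
    """Paired per-node metrics for the two conditions."""

    node: str
    c_before: float
    c_after: float
    eff_modules_before: float
    eff_modules_after: float
    bridgeness_before: float
    bridgeness_after: float
    group: str  # A-E or "unclassified"
    bridge_class: str  # induced | persistent | decreased | none
    extreme_bridge_flag: bool


def effective_module_count(decomp: ModularDecomposition, node: str) -> float:
    """Effective number of the node's module membership strengths (its overlap)."""
    return effective_number(decomp.membership_of(node))


def module_link_weights(decomp: ModularDecomposition) -> ModuleGraph:
    """Module graph with O_ij = sum_n 2 H_i(n) H_j(n) / c(n)."""
    h = decomp.membership
    c = np.array([decomp.centrality_of(n) for n in decomp.node_order])
    scaled = h / np.sqrt(c)[:, np.newaxis]  # so scaled.T @ scaled has entries sum H_i H_j / c
    o = 2.0 * (scaled.T @ scaled)
    np.fill_diagonal(o, 0.0)
    return ModuleGraph(modules=list(decomp.modules), weights=o)


def module_effective_degree(module_graph: ModuleGraph, module: int) -> float:
    """Effective number of the module's links to neighbouring modules; 0 if isolated."""
    row = np.delete(module_graph.weights[module], module)
    if not np.any(row > 0):
        return 0.0
    return effective_number(row)


def bridgeness(decomp: ModularDecomposition, module_graph: ModuleGraph, node: str) -> float:
    """Sum over adjacent module pairs of min(H_i(n), H_j(n))."""
    h = decomp.membership_of(node)
    return float(sum(min(h[i], h[j]) for i, j in module_graph.adjacent_pairs()))


def all_bridgeness(decomp: ModularDecomposition, module_graph: ModuleGraph | None = None) -> dict[str, float]:
    if module_graph is None:
        module_graph = module_link_weights(decomp)
    pairs = module_graph.adjacent_pairs()
    if not pairs:
        return {n: 0.0 for n in decomp.node_order}
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    h = decomp.membership
    b = np.minimum(h[:, ii], h[:, jj]).sum(axis=1)
    return dict(zip(decomp.node_order, b.tolist()))


def classify_centrality_change(
    c_before: float,
    c_after: float,
    thresholds: tuple[float, float, float] = DEFAULT_CHANGE_THRESHOLDS,
) -> str:
    """Centrality-change group A-E.

    With thresholds (t_low, t_high, t_extra): A small -> large; B large in
    both; C extra-large -> slightly smaller; D large -> small; E small in
    both; anything else is unclassified.  The boundaries are parameters, not
    measurements — the groups were drawn by eye in the source analysis, and
    any report should state the thresholds used.
    """
    t_low, t_high, t_extra = thresholds
    if not t_low < t_high < t_extra:
        raise ValueError("thresholds must satisfy t_low < t_high < t_extra")
    if c_before < t_low and c_after > t_high:
        return "A"
    if t_high <= c_before <= t_extra and t_high <= c_after <= t_extra:
        return "B"
    if c_before > t_extra and t_high <= c_after < c_before:
        return "C"
    if c_before > t_high and c_after < t_low:
        return "D"
    if c_before < t_low and c_after < t_low:
        return "E"
    return "unclassified"


def classify_bridge_dynamics(
    b_before: float,
    b_after: float,
    high: float = DEFAULT_BRIDGE_CUT,
    fold_flag: float = DEFAULT_FOLD_FLAG,
) -> tuple[str, bool]:
    """Bridge dynamics class and an extreme-fold-change flag.

    Nodes with zero bridgeness in either condition are excluded (class
    ``none``).  A bridge is ``induced`` if it rises above ``high`` under
    stress, ``decreased`` if it falls from above to at-or-below, and
    ``persistent`` if above in both conditions.  The flag marks inductions or
    reductions of more than ``fold_flag``-fold.
    """
    if b_before < 0 or b_after < 0:
        raise ValueError("bridgeness values must be nonnegative")
    if b_before == 0 or b_after == 0:
        return "none", False
    flag = max(b_after / b_before, b_before / b_after) > fold_flag
    if b_after > high and b_before <= high:
        return "induced", flag
    if b_before > high and b_after <= high:
        return "decreased", flag
    if b_before > high and b_after > high:
        return "persistent", flag
    return "none", flag


def node_dynamics(
    decomp_before: ModularDecomposition,
    decomp_after: ModularDecomposition,
    change_thresholds: tuple[float, float, float] = DEFAULT_CHANGE_THRESHOLDS,
    bridge_cut: float = DEFAULT_BRIDGE_CUT,
    fold_flag: float = DEFAULT_FOLD_FLAG,
) -> list[NodeDynamics]:
    """Per-node paired dynamics between two decompositions of the same network."""
    if decomp_before.node_order != decomp_after.node_order and set(decomp_before.node_order) != set(
        decomp_after.node_order
    ):
        raise ValueError("decompositions cover different node sets")
    mg_before = module_link_weights(decomp_before)
    mg_after = module_link_weights(decomp_after)
    b_before = all_bridgeness(decomp_before, mg_before)
    b_after = all_bridgeness(decomp_after, mg_after)
    out = []
    for n in sorted(decomp_before.node_order):
        cb = decomp_before.centrality_of(n)
        ca = decomp_after.centrality_of(n)
        bb, ba = b_before[n], b_after[n]
        bridge_class, flag = classify_bridge_dynamics(bb, ba, high=bridge_cut, fold_flag=fold_flag)
        out.append(
            NodeDynamics(
                node=n,
                c_before=cb,
                c_after=ca,
                eff_modules_before=effective_module_count(decomp_before, n),
                eff_modules_after=effective_module_count(decomp_after, n),
                bridgeness_before=bb,
                bridgeness_after=ba,
                group=classify_centrality_change(cb, ca, change_thresholds),
                bridge_class=bridge_class,
                extreme_bridge_flag=flag,
            )
        )
    return out


def node_dynamics_table(dyn: list[NodeDynamics]) -> pd.DataFrame:
    """NodeDynamics collection as a DataFrame (one row per node)."""
    return pd.DataFrame([vars(d) for d in dyn]).set_index("node")


def screen_bridging_integrators(dyn: list[NodeDynamics], min_centrality_ratio: float = 100.0) -> pd.DataFrame:
    """Nodes whose overlap and centrality both increase under stress.

    Keeps nodes with overlap ratio (after/before effective module count) > 1
    and centrality ratio >= ``min_centrality_ratio``; rows are sorted by
    centrality ratio, descending.  Nodes with a zero denominator are
    excluded (their ratios are undefined).
    """
    rows = []
    for d in dyn:
        if d.eff_modules_before <= 0 or d.c_before <= 0:
            continue
        overlap_ratio = d.eff_modules_after / d.eff_modules_before
        centrality_ratio = d.c_after / d.c_before
        if overlap_ratio > 1.0 and centrality_ratio >= min_centrality_ratio:
            rows.append(
                {
                    "node": d.node,
                    "overlap_ratio": overlap_ratio,
                    "centrality_ratio": centrality_ratio,
                    "c_before": d.c_before,
                    "c_after": d.c_after,
                }
            )
    df = pd.DataFrame(rows, columns=["node", "overlap_ratio", "centrality_ratio", "c_before", "c_after"])
    return df.sort_values("centrality_ratio", ascending=False, ignore_index=True)
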