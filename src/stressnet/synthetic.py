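"""Synthetic interactomes with planted overlapping modules, and paired
baseline/stress expression profiles.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any download:

* a block-structured interactome: ``n_modules`` planted modules of
  ``module_size`` nodes, consecutive (by index) module pairs sharing
  ``overlap_nodes_per_pair`` nodes that belong to exactly two modules;
  node pairs sharing a module are linked with probability ``p_intra``,
  all other pairs with ``p_inter``; optional ``hub_boost`` extra random
  edges on the top-degree node of each module give a heavier-tailed
  degree distribution;
* a heavy-tailed baseline profile: i.i.d. log-normal abundances with a
  configurable fraction of genes missing (absent ids, not sentinels, so
  median imputation is exercised);
* stress fold-changes: genes of designated "stress" modules are
  up-regulated by a ratio drawn from ``up_fold_range``, genes of
  "ribosome-like" modules down-regulated from ``down_fold_range``, all
  other genes sit at ratio 1; every ratio then receives multiplicative
  log-normal noise (median 1) and a fraction of genes goes missing.

All outputs are bit-identical across calls with equal specs and seeds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .io import ExpressionProfile

__all__ = [
    "PlantedNetworkSpec",
    "StressSpec",
    "generate_planted_interactome",
    "generate_baseline_profile",
    "generate_stress_foldchanges",
    "write_membership",
]

logger = logging.getLogger(__name__)

#: Default baseline log-normal location: median abundance 0.8, matching the
#: scale of absolute mRNA-level datasets where the observed median is 0.8.
DEFAULT_LOGNORMAL_MU = math.log(0.8)
DEFAULT_LOGNORMAL_SIGMA = 1.0


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the planted-overlapping-module interactome."""

    n_modules: int
    module_size: int
    overlap_nodes_per_pair: int = 0
    p_intra: float = 0.9
    p_inter: float = 0.01
    hub_boost: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.module_size < 1:
            raise ValueError("n_modules and module_size must be >= 1")
        if not 0 <= self.p_inter < self.p_intra <= 1:
            raise ValueError("need 0 <= p_inter < p_intra <= 1")
        if not 0 <= self.overlap_nodes_per_pair < self.module_size:
            raise ValueError("overlap_nodes_per_pair must be < module_size")
        if self.n_modules >= 3 and 2 * self.overlap_nodes_per_pair >= self.module_size:
            raise ValueError(
                "with >= 3 chained modules, 2*overlap_nodes_per_pair must be < module_size "
                "so overlap blocks stay disjoint (every overlap node in exactly two modules)"
            )
        if self.hub_boost < 0:
            raise ValueError("hub_boost must be >= 0")

    @property
    def n_nodes(self) -> int:
        return self.n_modules * self.module_size - (self.n_modules - 1) * self.overlap_nodes_per_pair


@dataclass(frozen=True)
class StressSpec:
    """Parameters of the emulated stress (heat-shock-like) fold-change profile.

    Defaults emulate a 15-minute severe heat shock: stress genes induced
    4-8-fold, ribosome-like genes repressed 4-8-fold, moderate multiplicative
    noise, and a small fraction of genes unmeasured.
    """

    up_modules: frozenset[int] = frozenset()
    down_modules: frozenset[int] = frozenset()
    up_fold_range: tuple[float, float] = (4.0, 8.0)
    down_fold_range: tuple[float, float] = (0.125, 0.25)
    noise_sd: float = 0.2
    missing_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_modules", frozenset(self.up_modules))
        object.__setattr__(self, "down_modules", frozenset(self.down_modules))
        lo_u, hi_u = self.up_fold_range
        lo_d, hi_d = self.down_fold_range
        if not 1.0 < lo_u <= hi_u:
            raise ValueError("up_fold_range must be a well-ordered interval of ratios > 1")
        if not 0.0 < lo_d <= hi_d < 1.0:
            raise ValueError("down_fold_range must be a well-ordered interval inside (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")


def _node_name(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def generate_planted_interactome(
    spec: PlantedNetworkSpec,
) -> tuple[nx.Graph, dict[str, frozenset[int]]]:
    """Generate the planted network and its ground-truth membership table.

    Returns an unweighted simple graph and a mapping node -> set of planted
    module indices (overlap nodes belong to exactly two consecutive modules).
    """
    n = spec.n_nodes
    has_intra_pairs = spec.module_size >= 2
    has_inter_pairs = spec.n_modules >= 2 and spec.p_inter > 0
    if not has_intra_pairs and not has_inter_pairs and spec.hub_boost == 0:
        raise ValueError("spec generates an empty graph (no node pair has positive edge probability)")
    width = max(4, len(str(n)))
    names = [_node_name(i, width) for i in range(n)]

    # membership matrix: module k owns a contiguous block, consecutive blocks
    # share the trailing `overlap` nodes of the previous block
    member = np.zeros((n, spec.n_modules), dtype=bool)
    start = 0
    for k in range(spec.n_modules):
        member[start : start + spec.module_size, k] = True
        start += spec.module_size - spec.overlap_nodes_per_pair

    rng = np.random.default_rng(spec.seed)
    # A node splits its intra-module linking propensity equally among its
    # modules, so overlap nodes keep an interior-like expected degree instead
    # of doubling it: the pairwise intra probability through one shared module
    # is p_intra / (|M(u)| * |M(v)|), combined independently across shared
    # modules.  Non-sharing pairs link with p_inter.
    n_shared = (member @ member.T).astype(float)
    n_own = member.sum(axis=1).astype(float)
    per_module = spec.p_intra / np.outer(n_own, n_own)
    with np.errstate(invalid="ignore"):
        prob_intra = 1.0 - (1.0 - per_module) ** n_shared
    prob = np.where(n_shared > 0, prob_intra, spec.p_inter)
    draws = rng.random((n, n))
    iu = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu] = draws[iu] < prob[iu]

    g = nx.Graph()
    g.add_nodes_from(names)
    ii, jj = np.nonzero(adj)
    g.add_edges_from((names[i], names[j]) for i, j in zip(ii.tolist(), jj.tolist()))

    if spec.hub_boost > 0:
        for k in range(spec.n_modules):
            members_k = [names[i] for i in np.nonzero(member[:, k])[0]]
            hub = max(members_k, key=lambda x: (g.degree(x), x))
            candidates = sorted(set(names) - set(g.neighbors(hub)) - {hub})
            n_extra = min(spec.hub_boost, len(candidates))
            if n_extra:
                picks = rng.choice(len(candidates), size=n_extra, replace=False)
                g.add_edges_from((hub, candidates[int(p)]) for p in sorted(picks))

    membership = {
        names[i]: frozenset(int(k) for k in np.nonzero(member[i])[0]) for i in range(n)
    }
    return g, membership


def generate_baseline_profile(
    nodes,
    lognormal_mu: float = DEFAULT_LOGNORMAL_MU,
    lognormal_sigma: float = DEFAULT_LOGNORMAL_SIGMA,
    missing_fraction: float = 0.08,
    seed: int = 0,
) -> ExpressionProfile:
    """Heavy-tailed (log-normal) baseline abundances with missing entries."""
    nodes = sorted(nodes)
    if not nodes:
        raise ValueError("empty node set")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    values = np.exp(lognormal_mu + lognormal_sigma * rng.standard_normal(len(nodes)))
    n_missing = int(round(missing_fraction * len(nodes)))
    missing_idx = set(rng.choice(len(nodes), size=n_missing, replace=False).tolist())
    return ExpressionProfile(
        values={n: float(v) for i, (n, v) in enumerate(zip(nodes, values)) if i not in missing_idx}
    )


def generate_stress_foldchanges(
    membership: dict[str, frozenset[int]],
    stress: StressSpec,
) -> ExpressionProfile:
    """Stress fold-change ratios over the planted membership table.

    Genes of up-modules draw a ratio from ``up_fold_range``, genes of
    down-modules from ``down_fold_range``; a gene in both an up- and a
    down-module takes the product of its sampled ratios.  All other genes sit
    at ratio 1.  Multiplicative log-normal noise (median 1, sd ``noise_sd``
    on the log scale) is then applied, and a fraction of genes is dropped.
    """
    all_modules = set().union(*membership.values()) if membership else set()
    unknown = (stress.up_modules | stress.down_modules) - all_modules
    if unknown:
        raise ValueError(f"stress spec names unknown module indices {sorted(unknown)}")
    both = stress.up_modules & stress.down_modules
    if both:
        logger.warning("modules %s are both up- and down-regulated", sorted(both))

    rng = np.random.default_rng(stress.seed)
    nodes = sorted(membership)
    values: dict[str, float] = {}
    for node in nodes:
        ratio = 1.0
        for k in sorted(membership[node]):
            if k in stress.up_modules:
                ratio *= float(rng.uniform(*stress.up_fold_range))
            if k in stress.down_modules:
                ratio *= float(rng.uniform(*stress.down_fold_range))
        if stress.noise_sd > 0:
            ratio *= float(np.exp(stress.noise_sd * rng.standard_normal()))
        values[node] = ratio
    n_missing = int(round(stress.missing_fraction * len(nodes)))
    missing = set(rng.choice(len(nodes), size=n_missing, replace=False).tolist())
    return ExpressionProfile(values={n: v for i, (n, v) in enumerate(values.items()) if i not in missing})


def write_membership(membership: dict[str, frozenset[int]], path: str | Path) -> None:
    """Planted truth table as (node, module_index) TSV, one row per membership."""
    with Path(path).open("w") as fh:
        for node in sorted(membership):
            for k in sorted(membership[node]):
                fh.write(f"{node}\t{k}\n")
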