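"""Nonparametric between-condition tests and the comparison report.

Both conditions live on the same edge set, so weights, effective degrees and
per-node overlaps are compared with the two-sided Wilcoxon signed-rank test
(paired); module-level effective degrees, whose modules differ between
conditions, use the two-sided Mann-Whitney U test (unpaired).  Exact null
distributions are used at small sample sizes, normal approximations with
continuity (and tie) correction otherwise.  No multiplicity correction is
applied across the handful of report tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats

from .metrics import (
    DEFAULT_BRIDGE_CUT,
    DEFAULT_CHANGE_THRESHOLDS,
    DEFAULT_FOLD_FLAG,
    NodeDynamics,
    effective_module_count,
    module_effective_degree,
    module_link_weights,
    node_dynamics,
)
from .moduland import ModularDecomposition
from .topology import TopologySummary, all_effective_degrees, topology_summary
from .weighting import WeightedInteractome

__all__ = [
    "TestResult",
    "ConditionComparison",
    "wilcoxon_paired",
    "mann_whitney_u",
    "compare_conditions",
    "format_p",
    "write_report",
]

WILCOXON_EXACT_N = 25
MANNWHITNEY_EXACT_N = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    test_name: str
    alternative: str = "two-sided"
    note: str = ""

    def display_p(self) -> str:
        return format_p(self.p_value)


@dataclass
class ConditionComparison:
    """All paired/unpaired between-condition statistics plus per-node dynamics."""

    topology_before: TopologySummary
    topology_after: TopologySummary
    diameter_ratio: float
    weight_test: TestResult
    degree_test: TestResult
    overlap_test: TestResult
    module_degree_test: TestResult
    node_dynamics: list[NodeDynamics] = field(default_factory=list)


def format_p(p: float) -> str:
    """R-style display convention for vanishing p-values."""
    if np.isnan(p):
        return "NA"
    return "< 2.2e-16" if p < 2.2e-16 else f"{p:.4g}"


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def wilcoxon_paired(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped beforehand (at least 6 informative pairs are
    required).  The exact null distribution (sign-flip enumeration, midranks
    under ties) is used for n <= 25; beyond that the normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; the signed-rank test is degenerate")
    if d.size < 6:
        raise ValueError(f"need at least 6 nonzero paired differences, got {d.size}")
    exact = d.size <= WILCOXON_EXACT_N
    method = "exact" if exact else "approx"
    res = scipy.stats.wilcoxon(d, alternative="two-sided", correction=True, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(d.size),),
        test_name="Wilcoxon paired (signed-rank)",
        note="exact" if exact else "normal approximation, continuity corrected",
    )


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U (rank-sum) test on two independent samples.

    Exact null distribution when min(n) <= 20 and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    exact = min(x.size, y.size) <= MANNWHITNEY_EXACT_N and not _has_ties(np.concatenate([x, y]))
    method = "exact" if exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(x.size), int(y.size)),
        test_name="Mann-Whitney U",
        note="exact" if exact else "normal approximation, tie/continuity corrected",
    )


def _paired_or_degenerate(x, y, label: str) -> TestResult:
    try:
        t = wilcoxon_paired(x, y)
        t.test_name = f"{t.test_name}: {label}"
        return t
    except ValueError as exc:
        return TestResult(
            statistic=float("nan"),
            p_value=float("nan"),
            n=(len(x),),
            test_name=f"Wilcoxon paired (signed-rank): {label}",
            note=f"degenerate: {exc}",
        )


def compare_conditions(
    w_before: WeightedInteractome,
    w_after: WeightedInteractome,
    decomp_before: ModularDecomposition,
    decomp_after: ModularDecomposition,
    cost_transform: str = "reciprocal",
    hub_fraction: float = 0.01,
    change_thresholds: tuple[float, float, float] = DEFAULT_CHANGE_THRESHOLDS,
    bridge_cut: float = DEFAULT_BRIDGE_CUT,
    fold_flag: float = DEFAULT_FOLD_FLAG,
) -> ConditionComparison:
    """Full between-condition comparison on a shared edge set.

    The hub threshold of both topology summaries comes from the *before*
    (reference) condition.  Paired tests align edges and nodes by id; the
    module-degree test is unpaired because module sets differ.
    """
    edges_b, weights_b = w_before.edge_weights()
    edges_a, weights_a = w_after.edge_weights()
    if edges_b != edges_a:
        raise ValueError("conditions must share the same edge set")

    topo_b = topology_summary(w_before, cost_transform=cost_transform, hub_fraction=hub_fraction)
    topo_a = topology_summary(w_after, w_reference=w_before, cost_transform=cost_transform, hub_fraction=hub_fraction)

    nodes = sorted(w_before.graph.nodes())
    eff_b = all_effective_degrees(w_before)
    eff_a = all_effective_degrees(w_after)
    emc_b = [effective_module_count(decomp_before, n) for n in nodes]
    emc_a = [effective_module_count(decomp_after, n) for n in nodes]

    mg_b = module_link_weights(decomp_before)
    mg_a = module_link_weights(decomp_after)
    mdeg_b = [module_effective_degree(mg_b, i) for i in range(mg_b.n_modules)]
    mdeg_a = [module_effective_degree(mg_a, i) for i in range(mg_a.n_modules)]
    try:
        module_degree_test = mann_whitney_u(mdeg_b, mdeg_a)
        module_degree_test.test_name += ": module effective degree"
    except ValueError as exc:
        module_degree_test = TestResult(
            statistic=float("nan"),
            p_value=float("nan"),
            n=(len(mdeg_b), len(mdeg_a)),
            test_name="Mann-Whitney U: module effective degree",
            note=f"degenerate: {exc}",
        )

    return ConditionComparison(
        topology_before=topo_b,
        topology_after=topo_a,
        diameter_ratio=topo_a.weighted_diameter / topo_b.weighted_diameter,
        weight_test=_paired_or_degenerate(weights_b, weights_a, "edge weights"),
        degree_test=_paired_or_degenerate([eff_b[n] for n in nodes], [eff_a[n] for n in nodes], "effective degree"),
        overlap_test=_paired_or_degenerate(emc_b, emc_a, "effective number of modules"),
        module_degree_test=module_degree_test,
        node_dynamics=node_dynamics(
            decomp_before,
            decomp_after,
            change_thresholds=change_thresholds,
            bridge_cut=bridge_cut,
            fold_flag=fold_flag,
        ),
    )


def _test_dict(t: TestResult) -> dict:
    return {
        "test": t.test_name,
        "statistic": None if np.isnan(t.statistic) else t.statistic,
        "p_value": None if np.isnan(t.p_value) else t.p_value,
        "p_display": t.display_p(),
        "n": list(t.n),
        "alternative": t.alternative,
        "note": t.note,
    }


def comparison_dict(cmp: ConditionComparison) -> dict:
    """Machine-readable form of a ConditionComparison (JSON-serialisable)."""
    group_counts: dict[str, int] = {}
    bridge_counts: dict[str, int] = {}
    for d in cmp.node_dynamics:
        group_counts[d.group] = group_counts.get(d.group, 0) + 1
        bridge_counts[d.bridge_class] = bridge_counts.get(d.bridge_class, 0) + 1
    return {
        "topology": {
            "before": vars(cmp.topology_before),
            "after": vars(cmp.topology_after),
        },
        "diameter_ratio": cmp.diameter_ratio,
        "tests": {
            "weight": _test_dict(cmp.weight_test),
            "effective_degree": _test_dict(cmp.degree_test),
            "overlap": _test_dict(cmp.overlap_test),
            "module_degree": _test_dict(cmp.module_degree_test),
        },
        "centrality_change_groups": dict(sorted(group_counts.items())),
        "bridge_dynamics_classes": dict(sorted(bridge_counts.items())),
    }


def write_report(cmp: ConditionComparison, json_path: str | Path, text_path: str | Path | None = None) -> None:
    """Write the machine-readable JSON report and an optional text summary."""
    payload = comparison_dict(cmp)
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if text_path is None:
        return
    tb, ta = cmp.topology_before, cmp.topology_after
    lines = [
        "Between-condition comparison",
        "============================",
        f"conditions: {tb.condition_label!r} -> {ta.condition_label!r}",
        f"nodes/edges: {tb.n_nodes}/{tb.n_edges} (shared edge set)",
        "",
        f"median weight:            {tb.median_weight:.6g} -> {ta.median_weight:.6g}",
        f"weighted diameter:        {tb.weighted_diameter:.6g} -> {ta.weighted_diameter:.6g}"
        f"  (ratio {cmp.diameter_ratio:.3g})",
        f"mean weighted path:       {tb.mean_weighted_shortest_path:.6g} -> {ta.mean_weighted_shortest_path:.6g}",
        f"median effective degree:  {tb.median_effective_degree:.6g} -> {ta.median_effective_degree:.6g}",
        f"hubs (threshold {tb.hub_threshold:.6g}): {tb.n_hubs} -> {ta.n_hubs}",
        "",
    ]
    for t in (cmp.weight_test, cmp.degree_test, cmp.overlap_test, cmp.module_degree_test):
        lines.append(f"{t.test_name}: p {t.display_p()}  (n={t.n}, {t.note})")
    Path(text_path).write_text("\n".join(lines) + "\n")
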