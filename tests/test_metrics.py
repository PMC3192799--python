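"""Overlap, module graph, bridgeness, and between-condition classifications."""

import numpy as np
import pytest

import stressnet as sn
from stressnet.metrics import ModuleGraph, all_bridgeness, node_dynamics, node_dynamics_table
from stressnet.moduland import CommunityLandscape, ModularDecomposition


def decomp_from(memberships: dict[str, list[float]]) -> ModularDecomposition:
    """Build a decomposition directly from membership rows (H sums to c)."""
    node_order = sorted(memberships)
    h = np.array([memberships[n] for n in node_order], dtype=float)
    centrality = {n: float(h[i].sum()) for i, n in enumerate(node_order)}
    land = CommunityLandscape(centrality=centrality, alpha=0.8, tol=1e-10)
    modules = [f"core{k}" for k in range(h.shape[1])]
    return ModularDecomposition(modules=modules, node_order=node_order, membership=h, landscape=land)


class TestEffectiveModuleCount:
    @pytest.mark.parametrize(
        "row,expected",
        [([3.0, 0.0, 0.0], 1.0), ([2.0, 2.0], 2.0), ([0.6, 0.4], 1 / 0.52)],
    )
    def test_hand_values(self, row, expected):
        d = decomp_from({"n": row})
        assert sn.effective_module_count(d, "n") == pytest.approx(expected)


class TestModuleLinkWeights:
    def test_single_module_node_contributes_nothing(self):
        d = decomp_from({"n": [5.0, 0.0], "m": [0.0, 3.0]})
        mg = sn.module_link_weights(d)
        assert mg.link_weight(0, 1) == 0.0

    def test_even_split_hand_value(self):
        # node with H = {2, 2}, c = 4 -> O_12(n) = 2*2*2/4 = 2
        d = decomp_from({"n": [2.0, 2.0]})
        mg = sn.module_link_weights(d)
        assert mg.link_weight(0, 1) == pytest.approx(2.0)

    def test_symmetric_zero_diagonal(self):
        d = decomp_from({"a": [1.0, 2.0, 3.0], "b": [2.0, 0.0, 1.0]})
        mg = sn.module_link_weights(d)
        assert np.allclose(mg.weights, mg.weights.T)
        assert np.all(np.diag(mg.weights) == 0)

    def test_disconnected_planted_modules_near_zero_link(self):
        spec = sn.PlantedNetworkSpec(2, 20, 0, 0.9, 0.0, seed=3)
        graph, mem = sn.generate_planted_interactome(spec)
        import networkx as nx

        nx.set_edge_attributes(graph, 1.0, "weight")
        w = sn.WeightedInteractome(graph=graph)
        decomp = sn.decompose(w)
        mg = sn.module_link_weights(decomp)
        # two disconnected blocks: no node carries membership in both
        assert mg.n_modules >= 2
        assert mg.link_weight(0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_enumeration_matches(self, planted_small):
        w, _ = planted_small
        decomp = sn.decompose(w)
        mg = sn.module_link_weights(decomp)
        m = decomp.n_modules
        # exhaustive enumeration: O_ij = sum_n 2 H_i(n) H_j(n) / c(n)
        oracle = np.zeros((m, m))
        for n in decomp.node_order:
            h = decomp.membership_of(n)
            c = decomp.centrality_of(n)
            contrib = 2 * np.outer(h, h) / c
            np.fill_diagonal(contrib, 0.0)
            oracle += contrib
        assert np.allclose(mg.weights, oracle, atol=1e-12)


class TestModuleEffectiveDegree:
    def test_hand_values(self):
        weights = np.array([[0.0, 4.0, 1.0], [4.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        mg = ModuleGraph(modules=["a", "b", "c"], weights=weights)
        assert sn.module_effective_degree(mg, 0) == pytest.approx(25 / 17)
        assert sn.module_effective_degree(mg, 1) == 1.0

    def test_equal_links_count_neighbors(self):
        weights = np.zeros((4, 4))
        for j in (1, 2, 3):
            weights[0, j] = weights[j, 0] = 2.5
        mg = ModuleGraph(modules=list("abcd"), weights=weights)
        assert sn.module_effective_degree(mg, 0) == pytest.approx(3.0)

    def test_isolated_module_zero(self):
        mg = ModuleGraph(modules=["a", "b"], weights=np.zeros((2, 2)))
        assert sn.module_effective_degree(mg, 0) == 0.0


class TestBridgeness:
    def test_single_module_node_zero(self):
        d = decomp_from({"n": [3.0, 0.0], "m": [1.0, 1.0]})
        mg = sn.module_link_weights(d)
        assert sn.bridgeness(d, mg, "n") == 0.0

    def test_even_split_two_adjacent_modules(self):
        d = decomp_from({"n": [0.5, 0.5], "m": [0.2, 0.8]})
        mg = sn.module_link_weights(d)
        assert sn.bridgeness(d, mg, "n") == pytest.approx(0.5)

    def test_three_module_hand_value(self):
        # H = {0.4, 0.4, 0.2}, all three modules pairwise adjacent:
        # min sums: 0.4 + 0.2 + 0.2 = 0.8
        d = decomp_from({"n": [0.4, 0.4, 0.2], "m": [0.3, 0.3, 0.4]})
        mg = sn.module_link_weights(d)
        assert mg.adjacent_pairs() == [(0, 1), (0, 2), (1, 2)]
        assert sn.bridgeness(d, mg, "n") == pytest.approx(0.8)

    def test_brute_force_enumeration_matches(self, planted_small):
        w, _ = planted_small
        decomp = sn.decompose(w)
        mg = sn.module_link_weights(decomp)
        bridges = all_bridgeness(decomp, mg)
        m = decomp.n_modules
        for n in decomp.node_order:
            h = decomp.membership_of(n)
            expected = sum(
                min(h[i], h[j])
                for i in range(m)
                for j in range(i + 1, m)
                if mg.weights[i, j] > 0
            )
            assert bridges[n] == pytest.approx(expected, abs=1e-12)
            assert sn.bridgeness(decomp, mg, n) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_centrality_pairs(self, two_cliques_bridge):
        w, _ = two_cliques_bridge
        decomp = sn.decompose(w, spreading="raw")
        mg = sn.module_link_weights(decomp)
        for n in decomp.node_order:
            h = decomp.membership_of(n)
            m_adj = sum(1 for i, j in mg.adjacent_pairs() if h[i] > 0 or h[j] > 0)
            c = decomp.centrality_of(n)
            assert sn.bridgeness(decomp, mg, n) <= c * max(m_adj - 1, 1) / 2 + 1e-9


class TestClassifyCentralityChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [
            (0.1, 900.0, "A"),
            (500.0, 500.0, "B"),
            (2000.0, 500.0, "C"),
            (500.0, 0.5, "D"),
            (0.5, 0.5, "E"),
            (50.0, 50.0, "unclassified"),
        ],
    )
    def test_groups(self, before, after, expected):
        assert sn.classify_centrality_change(before, after, (1.0, 100.0, 1000.0)) == expected

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            sn.classify_centrality_change(1.0, 1.0, (100.0, 1.0, 1000.0))


class TestClassifyBridgeDynamics:
    @pytest.mark.parametrize(
        "before,after,expected_class,expected_flag",
        [
            (0.01, 50.0, "induced", False),
            (50.0, 60.0, "persistent", False),
            (1e-6, 20.0, "induced", True),   # 2e7-fold induction
            (50.0, 0.5, "decreased", False),
            (0.0, 50.0, "none", False),      # zero in one condition: excluded
            (5.0, 50.0, "induced", False),
            (2.0, 3.0, "none", False),
        ],
    )
    def test_classes(self, before, after, expected_class, expected_flag):
        cls, flag = sn.classify_bridge_dynamics(before, after)
        assert cls == expected_class and flag == expected_flag

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sn.classify_bridge_dynamics(-1.0, 2.0)


class TestScreenBridgingIntegrators:
    def make_dyn(self, node, eb, ea, cb, ca):
        return sn.NodeDynamics(node=node, c_before=cb, c_after=ca, eff_modules_before=eb,
                               eff_modules_after=ea, bridgeness_before=0.0, bridgeness_after=0.0,
                               group="unclassified", bridge_class="none", extreme_bridge_flag=False)

    def test_parallel_increase_included(self):
        dyn = [self.make_dyn("GPH1-like", 1.0, 1.3, 1.0, 7500.0)]
        out = sn.screen_bridging_integrators(dyn, min_centrality_ratio=1000.0)
        assert list(out["node"]) == ["GPH1-like"]
        assert out["overlap_ratio"].iloc[0] == pytest.approx(1.3)
        assert out["centrality_ratio"].iloc[0] == pytest.approx(7500.0)

    def test_decreasing_overlap_excluded(self):
        dyn = [self.make_dyn("x", 1.0, 0.9, 1.0, 1e9)]
        assert sn.screen_bridging_integrators(dyn, min_centrality_ratio=1.0).empty

    def test_empty_input_empty_output(self):
        assert sn.screen_bridging_integrators([], 1.0).empty

    def test_sorted_by_centrality_ratio_desc(self):
        dyn = [self.make_dyn("a", 1.0, 1.2, 1.0, 10.0), self.make_dyn("b", 1.0, 1.5, 1.0, 99.0)]
        out = sn.screen_bridging_integrators(dyn, min_centrality_ratio=2.0)
        assert list(out["node"]) == ["b", "a"]


def test_node_dynamics_table_roundtrip(stress_pair):
    w_before, w_after, _ = stress_pair
    db, da = sn.decompose(w_before), sn.decompose(w_after)
    dyn = node_dynamics(db, da)
    table = node_dynamics_table(dyn)
    assert len(table) == w_before.number_of_nodes()
    assert set(table.columns) >= {"c_before", "c_after", "group", "bridge_class"}
    # O_ij totals bound: sum of inter-module weights <= total centrality mass
    mg = sn.module_link_weights(db)
    assert np.triu(mg.weights, 1).sum() <= sum(db.landscape.centrality.values()) + 1e-9
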