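"""Community landscape, module cores, ProportionalHill memberships."""

import networkx as nx
import numpy as np
import pytest

import stressnet as sn
from stressnet import moduland
from stressnet.weighting import WeightedInteractome

from conftest import unit_weighted


class TestInfluenceFunction:
    def test_dyad_closed_form(self, dyad):
        # geometric series on a 2-node chain: f(a) = (1-a)/(1-a^2) = 2/3 at alpha=0.5
        f = sn.influence_function(dyad, "a", alpha=0.5)
        assert f["a"] == pytest.approx(2 / 3, abs=1e-8)
        assert f["b"] == pytest.approx(1 / 3, abs=1e-8)

    def test_normalized_and_nonnegative(self, two_cliques_bridge):
        w, _ = two_cliques_bridge
        f = sn.influence_function(w, "l0")
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-8)
        assert all(v >= 0 for v in f.values())

    def test_small_alpha_concentrates_on_seed(self, two_cliques_bridge):
        w, _ = two_cliques_bridge
        f = sn.influence_function(w, "l1", alpha=0.01)
        assert f["l1"] > 0.98
        assert f["l1"] == max(f.values())

    def test_star_center_spreads_equally_to_leaves(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: ("hub" if i == 0 else f"leaf{i}") for i in g.nodes()})
        nx.set_edge_attributes(g, 1.0, "weight")
        f = sn.influence_function(WeightedInteractome(graph=g), "hub", alpha=0.5)
        leaf_values = [v for k, v in f.items() if k.startswith("leaf")]
        assert np.allclose(leaf_values, leaf_values[0])

    def test_invalid_alpha_rejected(self, dyad):
        with pytest.raises(ValueError):
            sn.influence_function(dyad, "a", alpha=1.0)


class TestCommunityCentrality:
    def test_vertex_transitive_cycle_is_flat(self):
        g = nx.cycle_graph(7)
        land = sn.community_centrality(unit_weighted(g))
        values = list(land.centrality.values())
        assert np.allclose(values, 1.0, atol=1e-8)

    def test_star_center_dominates_and_matches_seed_sum(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        w = unit_weighted(g)
        land = sn.community_centrality(w, alpha=0.6)
        # direct summation oracle over per-seed influence vectors
        total = {n: 0.0 for n in w.graph.nodes()}
        for s in w.graph.nodes():
            for n, v in sn.influence_function(w, s, alpha=0.6).items():
                total[n] += v
        for n in total:
            assert land.centrality[n] == pytest.approx(total[n], abs=1e-6)
        assert max(land.centrality, key=land.centrality.get) == "n0"

    def test_mass_equals_node_count(self, two_cliques_bridge, planted_small):
        for w in (two_cliques_bridge[0], planted_small[0]):
            land = sn.community_centrality(w)
            assert land.total_mass() == pytest.approx(w.number_of_nodes(), abs=1e-6)


class TestFindModuleCores:
    def test_two_cliques_weak_edge_two_cores(self):
        g = nx.Graph()
        for grp in ("abcd", "wxyz"):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    g.add_edge(u, v, weight=1.0)
        g.add_edge("a", "w", weight=0.05)
        w = WeightedInteractome(graph=g)
        land = sn.community_centrality(w)
        cores = sn.find_module_cores(w, land)
        # brute-force local-max oracle
        expected = [
            n for n in g.nodes()
            if all((land.centrality[j], j) < (land.centrality[n], n) for j in g.neighbors(n))
        ]
        assert sorted(cores) == sorted(expected)
        # the full detector excludes the structurally unsupported bridge from
        # the summit-acceptance neighbour relation: one summit per clique
        assert sn.decompose(w).n_modules == 2

    def test_uniform_cycle_plateau_single_core(self):
        g = nx.cycle_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        w = unit_weighted(g)
        land = sn.community_centrality(w)
        cores = sn.find_module_cores(w, land)
        assert cores == ["n5"]  # plateau: the largest id wins

    def test_dominant_star_center_single_core(self):
        g = nx.star_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        w = unit_weighted(g)
        land = sn.community_centrality(w)
        assert sn.find_module_cores(w, land) == ["n0"]


class TestProportionalHill:
    def test_bridge_node_splits_half_half(self, two_cliques_bridge):
        w, bridge = two_cliques_bridge
        decomp = sn.decompose(w, spreading="raw")
        h = decomp.membership_of(bridge)
        c = decomp.centrality_of(bridge)
        positive = sorted(h[h > 0])
        assert len(positive) == 2
        assert positive[0] == pytest.approx(c / 2, rel=1e-9)
        assert positive[1] == pytest.approx(c / 2, rel=1e-9)

    def test_single_module_graph_everything_in_it(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        decomp = sn.decompose(unit_weighted(g))
        assert decomp.n_modules == 1
        for n in decomp.node_order:
            assert decomp.membership_of(n)[0] == pytest.approx(decomp.centrality_of(n))

    def test_single_uphill_neighbor_inherits_proportions(self, two_cliques_bridge):
        w, bridge = two_cliques_bridge
        # hang a pendant node under the bridge: its only uphill route is the bridge
        g = w.graph.copy()
        g.add_edge("aaa_pendant", bridge, weight=0.01)
        w2 = WeightedInteractome(graph=g)
        decomp = sn.decompose(w2, spreading="raw")
        hp = decomp.membership_of("aaa_pendant")
        hb = decomp.membership_of(bridge)
        cp, cb = decomp.centrality_of("aaa_pendant"), decomp.centrality_of(bridge)
        assert np.allclose(hp / cp, hb / cb, atol=1e-9)

    def test_conservation_on_varied_graphs(self, two_cliques_bridge, planted_small):
        graphs = [two_cliques_bridge[0], planted_small[0],
                  unit_weighted(nx.cycle_graph(9)), unit_weighted(nx.star_graph(7))]
        for w in graphs:
            for spreading in ("raw", "reinforced"):
                decomp = sn.decompose(w, spreading=spreading)
                for n in decomp.node_order:
                    assert decomp.membership_of(n).sum() == pytest.approx(
                        decomp.centrality_of(n), abs=1e-9
                    )

    def test_hand_recursion_on_path(self):
        # path a-b-c with increasing weights: c is the single summit, every
        # membership vector is 100% module 0; hand recursion is trivial
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=2.0)
        w = WeightedInteractome(graph=g)
        land = sn.community_centrality(w, alpha=0.5)
        decomp = moduland.proportional_hill_membership(w, land)
        assert decomp.n_modules == 1
        for n in "abc":
            assert decomp.membership_of(n)[0] == pytest.approx(decomp.centrality_of(n))


class TestCoreProteinsAndCentralModules:
    def test_small_module_returns_all_with_warning(self):
        g = nx.complete_graph(3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        decomp = sn.decompose(unit_weighted(g))
        with pytest.warns(UserWarning, match="only 3 members"):
            cores = sn.module_core_proteins(decomp, 0, k=5)
        assert len(cores) == 3

    def test_ranking_matches_sort_oracle(self, planted_small):
        w, _ = planted_small
        decomp = sn.decompose(w)
        module = 0
        members = [n for n in decomp.node_order if decomp.membership_of(n)[module] > 0]
        oracle = sorted(members, key=lambda n: (-decomp.centrality_of(n), n))[:5]
        assert sn.module_core_proteins(decomp, module, k=5) == oracle

    def test_extended_core_size(self, planted_small):
        w, _ = planted_small
        decomp = sn.decompose(w)
        assert len(sn.module_core_proteins(decomp, 0, extended=True)) == 8

    def test_central_modules_threshold_filter(self, planted_small):
        w, _ = planted_small
        decomp = sn.decompose(w)
        assert sn.central_modules(decomp, centrality_threshold=0.0) == list(range(decomp.n_modules))
        assert sn.central_modules(decomp, centrality_threshold=1e9) == []
        mid = np.median([decomp.centrality_of(c) for c in decomp.modules])
        expected = [k for k, core in enumerate(decomp.modules) if decomp.centrality_of(core) > mid]
        assert sn.central_modules(decomp, centrality_threshold=mid) == expected


class TestDetectionProperties:
    def test_planted_two_module_overlap_nodes_have_higher_overlap(self):
        spec = sn.PlantedNetworkSpec(4, 30, 3, 0.9, 0.01, seed=7)
        graph, mem = sn.generate_planted_interactome(spec)
        graph = sn.giant_component(graph)
        w = unit_weighted(graph)
        decomp = sn.decompose(w)
        emc = {n: sn.effective_module_count(decomp, n) for n in decomp.node_order}
        overlap = [emc[n] for n in decomp.node_order if len(mem[n]) == 2]
        interior = [emc[n] for n in decomp.node_order if len(mem[n]) == 1]
        assert np.mean(overlap) > np.mean(interior)

    def test_downweighting_inter_module_edges_reduces_mean_overlap(self):
        for seed in (0, 1, 2):
            spec = sn.PlantedNetworkSpec(4, 30, 3, 0.9, 0.01, seed=seed)
            graph, mem = sn.generate_planted_interactome(spec)
            graph = sn.giant_component(graph)
            w1 = unit_weighted(graph)
            g2 = w1.graph.copy()
            for a, b in g2.edges():
                if not (mem[a] & mem[b]):
                    g2[a][b]["weight"] = 0.1
            w2 = WeightedInteractome(graph=g2)
            d1, d2 = sn.decompose(w1), sn.decompose(w2)
            m1 = np.mean([sn.effective_module_count(d1, n) for n in d1.node_order])
            m2 = np.mean([sn.effective_module_count(d2, n) for n in d2.node_order])
            assert m2 < m1

    def test_decomposition_deterministic(self, planted_small):
        w, _ = planted_small
        d1 = sn.decompose(w)
        d2 = sn.decompose(w)
        assert d1.modules == d2.modules
        assert np.array_equal(d1.membership, d2.membership)

    def test_unknown_spreading_mode_rejected(self, dyad):
        with pytest.raises(ValueError):
            sn.decompose(dyad, spreading="fancy")
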