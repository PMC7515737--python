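"""Seed sub-networks, candidate extension and entropy connectedness."""

import math

import networkx as nx
import numpy as np
import pytest

import corewalk as cw

from conftest import make_result, random_connected_graph


class TestSeedSubnetwork:
    def test_components_of_partially_connected_seeds(self):
        net = nx.Graph([("a", "b"), ("b", "x"), ("x", "c")])
        seeds = cw.SeedSet(frozenset({"a", "b", "c"}))
        ms = cw.seed_subnetwork(net, seeds)
        comps = {m.nodes for m in ms.modules}
        assert comps == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_clique_seeds_form_one_component(self):
        net = nx.relabel_nodes(nx.complete_graph(5), str)
        seeds = cw.SeedSet(frozenset(net.nodes()))
        ms = cw.seed_subnetwork(net, seeds)
        assert len(ms) == 1 and ms.largest().size == 5

    def test_sparse_seed_layout_has_small_components(self):
        # 78 seeds connected by only 14 edges (a typical GWAS seed
        # sub-network shape): component sizes stay between 1 and 5
        rng = np.random.default_rng(0)
        net = random_connected_graph(400, rng_seed=0)
        background = sorted(net.nodes())
        seeds = [f"s{i:02d}" for i in range(78)]
        for s in seeds:  # each seed hangs off the background only
            net.add_edge(s, str(rng.choice(background)))
        # 14 interconnecting seed-seed edges: two 5-paths, two 3-paths,
        # two pairs; the other 58 seeds stay isolated among themselves
        chains = [seeds[0:5], seeds[5:10], seeds[10:13], seeds[13:16],
                  seeds[16:18], seeds[18:20]]
        for chain in chains:
            net.add_edges_from(zip(chain, chain[1:]))
        assert net.subgraph(seeds).number_of_edges() == 14
        ms = cw.seed_subnetwork(net, cw.SeedSet(frozenset(seeds)))
        sizes = [m.size for m in ms.modules]
        assert sum(sizes) == 78
        assert min(sizes) >= 1 and max(sizes) <= 5

    def test_empty_intersection_is_error(self):
        net = nx.path_graph(["a", "b"])
        with pytest.raises(ValueError, match="seed"):
            cw.seed_subnetwork(net, cw.SeedSet(frozenset({"zz"})))


class TestWmin:
    def test_percentile_with_linear_interpolation(self):
        res = make_result(
            ["s1", "a", "b", "c", "d"],
            [9.0, 1.0, 2.0, 3.0, 4.0],
            [0.001, 0.001, 0.001, 0.001, 0.001],
        )
        seeds = cw.SeedSet(frozenset({"s1"}))
        assert cw.compute_wmin(res, seeds) == pytest.approx(3.25)

    def test_single_significant_node(self):
        res = make_result(["s1", "a"], [9.0, 2.5], [0.001, 0.001])
        assert cw.compute_wmin(res, cw.SeedSet(frozenset({"s1"}))) == 2.5

    def test_no_significant_non_seed_gives_infinity(self):
        res = make_result(["s1", "a"], [9.0, 2.5], [0.001, 0.5])
        assert cw.compute_wmin(res, cw.SeedSet(frozenset({"s1"}))) == math.inf


class TestExtension:
    def build_two_islands(self):
        # two seed pairs joined only through candidate node "c"
        net = nx.Graph(
            [("s1", "s2"), ("s3", "s4"), ("c", "s2"), ("c", "s3"), ("c", "bg"),
             ("bg", "s1")]
        )
        seeds = cw.SeedSet(frozenset({"s1", "s2", "s3", "s4"}))
        return net, seeds

    def test_candidate_merges_seed_components(self):
        net, seeds = self.build_two_islands()
        res = make_result(
            ["bg", "c", "s1", "s2", "s3", "s4"],
            [0.1, 5.0, 1.0, 1.0, 1.0, 1.0],
            [0.9, 0.0099, 1.0, 1.0, 1.0, 1.0],
        )
        ms = cw.extend_subnetwork(net, seeds, res, w_min=1.0)
        assert len(ms) == 1
        assert ms.largest().nodes == frozenset({"s1", "s2", "s3", "s4", "c"})
        assert ("c", "s2") in {tuple(sorted(e)) for e in ms.largest().edges}
        assert ms.largest().candidates == frozenset({"c"})

    def test_nonsignificant_candidate_excluded_regardless_of_weight(self):
        net, seeds = self.build_two_islands()
        res = make_result(
            ["bg", "c", "s1", "s2", "s3", "s4"],
            [0.1, 99.0, 1.0, 1.0, 1.0, 1.0],
            [0.9, 0.02, 1.0, 1.0, 1.0, 1.0],
        )
        ms = cw.extend_subnetwork(net, seeds, res, w_min=1.0)
        assert all("c" not in m.nodes for m in ms.modules)
        assert len(ms) == 2

    def test_weight_threshold_is_strict(self):
        net, seeds = self.build_two_islands()
        res = make_result(
            ["bg", "c", "s1", "s2", "s3", "s4"],
            [0.1, 1.0, 1.0, 1.0, 1.0, 1.0],
            [0.9, 0.0099, 1.0, 1.0, 1.0, 1.0],
        )
        ms = cw.extend_subnetwork(net, seeds, res, w_min=1.0)  # w == w_min fails
        assert all("c" not in m.nodes for m in ms.modules)

    def test_candidate_needs_a_seed_neighbor(self):
        net = nx.Graph([("s1", "s2"), ("s2", "mid"), ("mid", "far")])
        seeds = cw.SeedSet(frozenset({"s1", "s2"}))
        res = make_result(
            ["far", "mid", "s1", "s2"],
            [9.0, 0.5, 1.0, 1.0],
            [0.0099, 0.9, 1.0, 1.0],
        )
        ms = cw.extend_subnetwork(net, seeds, res, w_min=0.1)
        assert all("far" not in m.nodes for m in ms.modules)

    def test_hub_neighbor_of_disconnected_seeds_makes_one_module(self):
        # 10 pairwise-disconnected seeds, one high-weight hub adjacent to
        # all of them -> a single 11-node module
        seeds_list = [f"s{i}" for i in range(10)]
        net = nx.Graph([("hub", s) for s in seeds_list])
        net.add_edge("hub", "bg")
        res = make_result(
            ["bg", "hub"] + seeds_list,
            [0.0, 7.0] + [1.0] * 10,
            [1.0, 0.0099] + [1.0] * 10,
        )
        ms = cw.extend_subnetwork(
            net, cw.SeedSet(frozenset(seeds_list)), res, w_min=0.5
        )
        assert len(ms) == 1 and ms.largest().size == 11

    def test_candidate_candidate_edges_off_by_default(self):
        net = nx.Graph([("s1", "c1"), ("s1", "c2"), ("c1", "c2")])
        seeds = cw.SeedSet(frozenset({"s1"}))
        res = make_result(
            ["c1", "c2", "s1"], [5.0, 5.0, 1.0], [0.0099, 0.0099, 1.0]
        )
        default = cw.extend_subnetwork(net, seeds, res, w_min=1.0)
        assert ("c1", "c2") not in {
            tuple(sorted(e)) for e in default.largest().edges
        }
        with_cc = cw.extend_subnetwork(
            net, seeds, res, cw.ModuleConfig(include_candidate_edges=True), w_min=1.0
        )
        assert ("c1", "c2") in {tuple(sorted(e)) for e in with_cc.largest().edges}

    def test_filter_monotonicity(self, small_propagated):
        net, _, W, _, observed, seeds = small_propagated
        rng = np.random.default_rng(4)
        res = make_result(W.nodes, observed, rng.uniform(0.005, 1.0, len(W.nodes)))
        loose = cw.extend_subnetwork(
            net, seeds, res, cw.ModuleConfig(p_threshold=0.5, weight_percentile=50.0)
        )
        tight_p = cw.extend_subnetwork(
            net, seeds, res, cw.ModuleConfig(p_threshold=0.1, weight_percentile=50.0)
        )
        tight_w = cw.extend_subnetwork(
            net, seeds, res, cw.ModuleConfig(p_threshold=0.5, weight_percentile=90.0)
        )
        loose_nodes = set().union(*(m.nodes for m in loose.modules))
        assert set().union(*(m.nodes for m in tight_p.modules)) <= loose_nodes
        assert set().union(*(m.nodes for m in tight_w.modules)) <= loose_nodes

    def test_extension_never_smaller_than_seed_subnetwork(self, small_propagated):
        net, _, W, _, observed, seeds = small_propagated
        rng = np.random.default_rng(5)
        res = make_result(W.nodes, observed, rng.uniform(0.005, 0.5, len(W.nodes)))
        base = cw.seed_subnetwork(net, seeds)
        ext = cw.extend_subnetwork(net, seeds, res, cw.ModuleConfig(p_threshold=0.2))
        assert ext.graph.number_of_nodes() >= base.graph.number_of_nodes()
        assert ext.graph.number_of_edges() >= base.graph.number_of_edges()
        for m in ext.modules:  # modules are maximal connected components
            assert nx.is_connected(ext.graph.subgraph(m.nodes))


class TestTopWeightFallback:
    def test_top_k_with_lexicographic_tie_break(self):
        weights = {"b": 2.0, "a": 2.0, "c": 3.0, "d": 1.0}
        seeds = cw.top_weight_seeds(weights, k=2)
        assert seeds.genes == frozenset({"c", "a"})
        assert "top-2" in seeds.provenance


class TestConnectedness:
    def two_module_set(self, groups, all_seeds):
        mods = tuple(
            cw.Module(nodes=frozenset(g), edges=frozenset(), seeds=frozenset(g))
            for g in groups
        )
        return mods, cw.SeedSet(frozenset(all_seeds))

    def test_all_seeds_in_one_module(self):
        mods, seeds = self.two_module_set([["a", "b", "c", "d"]], ["a", "b", "c", "d"])
        rep = cw.connectedness(mods, seeds)
        assert rep.entropy == pytest.approx(0.0)
        assert rep.connectedness == pytest.approx(math.log(4))

    def test_all_seeds_isolated(self):
        mods, seeds = self.two_module_set([], ["a", "b", "c"])
        rep = cw.connectedness(mods, seeds)
        assert rep.connectedness == pytest.approx(0.0)
        assert rep.entropy == pytest.approx(rep.max_entropy)

    def test_two_plus_two_split(self):
        mods, seeds = self.two_module_set(
            [["a", "b"], ["c", "d"]], ["a", "b", "c", "d"]
        )
        rep = cw.connectedness(mods, seeds)
        assert rep.entropy == pytest.approx(math.log(2))
        assert rep.connectedness == pytest.approx(math.log(4) - math.log(2))

    def test_uncovered_seeds_count_as_singletons(self):
        mods, seeds = self.two_module_set([["a", "b"]], ["a", "b", "c", "d"])
        rep = cw.connectedness(mods, seeds)
        # distribution {2, 1, 1} over n = 4
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert rep.entropy == pytest.approx(expected)

    def test_fewer_than_two_seeds_rejected(self):
        mods, seeds = self.two_module_set([["a"]], ["a"])
        with pytest.raises(ValueError, match="at least 2"):
            cw.connectedness(mods, seeds)
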