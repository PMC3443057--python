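import math

import networkx as nx
import numpy as np
import pytest

from coremod.io_prep import InteractionNetwork
from coremod.topology import (
    all_closeness,
    build_mutated_gene_network,
    cancer_type_score,
    classify_mutated_genes,
    closeness,
    closeness_vs_types_regression,
    topology_summary,
)


class TestTopologySummary:
    def test_complete_graph_density_one(self):
        s = topology_summary(nx.complete_graph(8))
        assert s.density == pytest.approx(1.0)

    def test_edgeless_graph_density_zero(self):
        s = topology_summary(nx.empty_graph(8))
        assert s.density == 0.0

    def test_star_centralization_one(self):
        s = topology_summary(nx.star_graph(9))  # 10 nodes
        assert s.centralization == pytest.approx(1.0)

    def test_regular_graph_heterogeneity_zero_cycle_centralization_zero(self):
        s = topology_summary(nx.cycle_graph(7))
        assert s.heterogeneity == 0.0
        assert s.centralization == pytest.approx(0.0)

    def test_star4_heterogeneity_population_variance(self):
        # degrees [3,1,1,1]: popvar = 0.75, mean = 1.5 -> 0.5
        s = topology_summary(nx.star_graph(3))
        assert s.heterogeneity == pytest.approx(0.5)

    def test_sample_variance_flag(self):
        s = topology_summary(nx.star_graph(3), population_variance=False)
        assert s.heterogeneity == pytest.approx(1.0 / 1.5)

    def test_centralization_undefined_below_three_nodes(self):
        s = topology_summary(nx.path_graph(2))
        assert math.isnan(s.centralization)

    def test_clustering_only_over_degree_ge_two(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        s = topology_summary(g)
        # a, b, c form a triangle; d has degree 1 and is excluded
        assert s.n_low_degree == 1
        assert s.mean_clustering == pytest.approx((1 + 1 + 1 / 3) / 3)

    @pytest.mark.parametrize("seed", range(4))
    def test_density_identity(self, seed):
        # sum(a_ij)/(N(N-1)) == mean(k)/(N-1) on any generated graph
        g = nx.gnp_random_graph(25, 0.2, seed=seed)
        n = g.number_of_nodes()
        lhs = 2 * g.number_of_edges() / (n * (n - 1))
        assert topology_summary(g).density == pytest.approx(lhs)


class TestCloseness:
    def test_star_center(self):
        assert closeness(nx.star_graph(3), 0) == pytest.approx(1 / 3)

    def test_star_leaf(self):
        # distances from a leaf: 1 (hub), 2, 2
        assert closeness(nx.star_graph(3), 1) == pytest.approx(1 / 5)

    def test_path_middle(self):
        g = nx.path_graph(["A", "B", "C"])
        assert closeness(g, "B") == pytest.approx(0.5)

    def test_isolated_node_zero(self):
        g = nx.empty_graph(3)
        assert closeness(g, 0) == 0.0

    def test_disconnected_within_component_only(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        assert closeness(g, "a") == pytest.approx(1.0)

    def test_missing_node_errors(self):
        with pytest.raises(KeyError):
            closeness(nx.path_graph(3), 99)

    @pytest.mark.parametrize("seed", range(3))
    def test_tree_internal_nodes_dominate_leaf_minimum(self, seed):
        tree = nx.random_labeled_tree(12, seed=seed)
        clos = all_closeness(tree)
        leaves = [v for v in tree if tree.degree(v) == 1]
        internals = [v for v in tree if tree.degree(v) > 1]
        if internals:
            assert min(clos[v] for v in internals) >= min(
                clos[v] for v in leaves
            )


class TestCancerTypeScore:
    TYPES = {"colon1": "colon", "colon2": "colon", "mel1": "melanoma",
             "breast1": "breast", "breast2": "breast"}

    def test_both_datasets_of_a_type(self):
        n = cancer_type_score(
            "g", {"colon1": True, "colon2": True}, self.TYPES
        )
        assert n == 1.0

    def test_half_credit(self):
        n = cancer_type_score("g", {"colon1": True}, self.TYPES)
        assert n == 0.5

    def test_additivity(self):
        # melanoma (single dataset) + one of two breast datasets -> 1.5
        n = cancer_type_score(
            "g", {"mel1": True, "breast1": True}, self.TYPES
        )
        assert n == 1.5

    def test_absent_gene_scores_zero(self):
        assert cancer_type_score("g", {}, self.TYPES) == 0.0

    def test_three_dataset_type_unsupported(self):
        types = {"d1": "t", "d2": "t", "d3": "t"}
        with pytest.raises(ValueError):
            cancer_type_score("g", {"d1": True}, types)


class TestMutatedGeneNetwork:
    def _network(self):
        interactions = InteractionNetwork.from_edge_pairs(
            [("a", "b"), ("b", "c"), ("c", "d"), ("a", "x")]
        )
        core_mutated = {"colon1": {"a", "b"}, "colon2": {"a"}, "mel1": {"c"}}
        types = {"colon1": "colon", "colon2": "colon", "mel1": "melanoma"}
        return build_mutated_gene_network(core_mutated, interactions, types)

    def test_nodes_and_edges(self):
        net = self._network()
        assert set(net.graph.nodes) == {"a", "b", "c"}
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset(("a", "b")), frozenset(("b", "c"))}

    def test_scores(self):
        net = self._network()
        assert net.gene_scores == {"a": 1.0, "b": 0.5, "c": 1.0}


class TestClosenessRegression:
    def _mgn(self, scores, graph):
        from coremod.topology import MutatedGeneNetwork

        return MutatedGeneNetwork(
            graph=graph, gene_datasets={g: set() for g in scores},
            gene_scores=scores, dataset_types={},
        )

    def test_hand_computed_ols(self, monkeypatch):
        # medians (1,0.1),(2,0.2),(3,0.25); normal-equation oracle:
        # slope = 0.075, intercept = 0.0333..., R^2 = cov^2/(varx*vary)
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        net = self._mgn({"a": 1.0, "b": 2.0, "c": 3.0}, g)
        clos = {"a": 0.1, "b": 0.2, "c": 0.25}

        import coremod.topology as topo

        monkeypatch.setattr(topo, "all_closeness", lambda graph: clos)
        slope, intercept, r2 = closeness_vs_types_regression(net)
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.1, 0.2, 0.25])
        sl = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        ic = y.mean() - sl * x.mean()
        ss_res = ((y - (ic + sl * x)) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(sl)
        assert intercept == pytest.approx(ic)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_collinear_medians_r2_one(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        # closeness: a=1/6, b=1/4, c=1/4, d=1/6 -> pick N levels making
        # medians collinear: use two levels only
        net = self._mgn({"a": 1.0, "d": 1.0, "b": 2.0, "c": 2.0}, g)
        slope, intercept, r2 = closeness_vs_types_regression(net)
        assert r2 == pytest.approx(1.0)

    def test_constant_medians_slope_zero(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        net = self._mgn({"a": 1.0, "b": 2.0, "c": 1.0, "d": 2.0}, g)
        slope, intercept, r2 = closeness_vs_types_regression(net)
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_single_level_errors(self):
        g = nx.path_graph(["a", "b"])
        net = self._mgn({"a": 1.0, "b": 1.0}, g)
        with pytest.raises(ValueError):
            closeness_vs_types_regression(net)


class TestClassifyMutatedGenes:
    def test_maximal_separation_is_general(self):
        observed = {"g": 3.0, **{f"x{i}": 1.5 for i in range(9)}}
        permuted = {gene: [0.0] * 20 for gene in observed}
        out = classify_mutated_genes(observed, permuted)
        assert "g" in out.general
        assert not out.unstable

    def test_matching_permutation_is_unstable(self):
        observed = {"g": 2.0}
        permuted = {"g": [2.0] * 20}
        out = classify_mutated_genes(observed, permuted)
        assert out.unstable == {"g"}

    def test_planted_outlier_recovered(self):
        rng = np.random.default_rng(5)
        observed = {f"x{i}": float(v) for i, v in
                    enumerate(1.5 + 0.1 * rng.standard_normal(12))}
        observed["hub"] = 5.0
        permuted = {g: [0.0] * 30 for g in observed}
        out = classify_mutated_genes(observed, permuted)
        assert out.general == {"hub"}

    def test_low_n_group_outlier_is_type_specific(self):
        observed = {f"x{i}": 0.5 for i in range(10)}
        observed["spec"] = 1.0
        # perturb the background so sd > 0
        observed["x0"] = 0.45
        observed["x1"] = 0.55
        permuted = {g: [0.0] * 30 for g in observed}
        out = classify_mutated_genes(observed, permuted)
        assert "spec" in out.type_specific
        assert not out.general

    def test_no_permutations_errors(self):
        with pytest.raises(ValueError):
            classify_mutated_genes({"g": 1.0}, {})
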