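import io
import itertools
import math

import networkx as nx
import numpy as np
import pytest
from Bio import Phylo

from coremod.phylo import (
    DistanceMatrix,
    distance_matrix,
    neighbor_joining,
    relatedness,
    relatedness_matrix,
    write_phylip,
)


def _ref(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestRelatedness:
    def test_identical_sets_cutoff0(self):
        ref = _ref([], nodes=["a", "b"])
        assert relatedness({"a", "b"}, {"a", "b"}, ref, 0) == pytest.approx(1.0)

    def test_disjoint_sets_cutoff0(self):
        ref = _ref([], nodes=["a", "b", "c", "d"])
        assert relatedness({"a", "b"}, {"c", "d"}, ref, 0) == 0.0

    def test_jaccard_reduction(self):
        # {a,b} vs {b,c}: one shared node over three in the union
        ref = _ref([], nodes=["a", "b", "c"])
        assert relatedness({"a", "b"}, {"b", "c"}, ref, 0) == pytest.approx(1 / 3)

    def test_cutoff1_counts_direct_interactions(self):
        # a-c edge links the two singleton networks at cutoff 1
        ref = _ref([("a", "c")], nodes=["a", "c"])
        # pairs within cutoff across {a} x {c}: (a,c) -> N0 = 1
        # union {a,c}: pairs (a,a),(c,c),(a,c) -> N1 = 3
        assert relatedness({"a"}, {"c"}, ref, 1) == pytest.approx(1 / 3)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        ref = nx.gnp_random_graph(20, 0.2, seed=3)
        nodes = list(ref.nodes)
        a = set(rng.choice(nodes, 6, replace=False))
        b = set(rng.choice(nodes, 6, replace=False))
        for cutoff in (0, 1, 2):
            r_ab = relatedness(a, b, ref, cutoff)
            r_ba = relatedness(b, a, ref, cutoff)
            assert r_ab == pytest.approx(r_ba)
            assert 0.0 <= r_ab <= 1.0

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            relatedness({"a"}, {"a"}, _ref([], nodes=["a"]), 3)

    def test_missing_node_errors(self):
        with pytest.raises(ValueError):
            relatedness({"zz"}, {"a"}, _ref([], nodes=["a"]), 0)


class TestDistanceMatrix:
    def test_elementwise_complement(self):
        ref = _ref([], nodes=["a", "b", "c", "d"])
        nets = {"t1": {"a", "b"}, "t2": {"b", "c"}, "t3": {"d"}}
        r = relatedness_matrix(nets, ref, 0)
        d = distance_matrix(r)
        assert d.values[0, 1] == pytest.approx(1 - r.values[0, 1])
        assert np.allclose(np.diag(d.values), 0.0)
        assert np.allclose(d.values, d.values.T)

    def test_quarter(self):
        r = relatedness_matrix(
            {"t1": {"a"}, "t2": {"a", "b", "c", "d"}},
            _ref([], nodes=list("abcd")), 0,
        )
        d = distance_matrix(r)
        assert d.values[0, 1] == pytest.approx(0.75)

    def test_phylip_export(self, tmp_path):
        d = DistanceMatrix(labels=["A", "B", "C"],
                           values=np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        write_phylip(d, tmp_path / "d.phy")
        lines = (tmp_path / "d.phy").read_text().splitlines()
        assert lines[0] == "3"
        assert lines[1].startswith("A")


def _branch_lengths(newick):
    tree = Phylo.read(io.StringIO(newick), "newick")
    return {
        cl.name: cl.branch_length
        for cl in tree.find_clades()
        if cl.name is not None
    }


def _splits(newick, taxa):
    """Non-trivial bipartitions of an unrooted tree, as frozensets."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    taxa = frozenset(taxa)
    splits = set()
    for clade in tree.get_nonterminals():
        for child in clade.clades:
            side = frozenset(t.name for t in child.get_terminals())
            if 1 < len(side) < len(taxa) - 1:
                splits.add(min(side, taxa - side, key=sorted))
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]),
        )
        bl = _branch_lengths(neighbor_joining(d))
        # (d_AB + d_AC - d_BC)/2 etc.
        assert bl["A"] == pytest.approx(0.5)
        assert bl["B"] == pytest.approx(1.5)
        assert bl["C"] == pytest.approx(2.5)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        dm = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0.0],
            ]
        )
        d = DistanceMatrix(labels=["A", "B", "C", "D"], values=dm)
        newick = neighbor_joining(d)
        assert _splits(newick, ["A", "B", "C", "D"]) == {frozenset({"A", "B"})}
        bl = _branch_lengths(newick)
        assert bl["A"] == pytest.approx(1.0)
        assert bl["B"] == pytest.approx(2.0)
        assert bl["C"] == pytest.approx(3.0)
        assert bl["D"] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_additive_recovery_up_to_six_taxa(self, seed):
        # generate a random additive tree, verify topology and path lengths
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        taxa = [f"T{i}" for i in range(n)]
        tree = nx.random_labeled_tree(2 * n - 2, seed=seed)
        # relabel: first n nodes become leaves via matching on degree order
        leaves = sorted(tree.nodes, key=lambda v: tree.degree(v))[:n]
        mapping = {v: taxa[i] for i, v in enumerate(leaves)}
        tree = nx.relabel_nodes(tree, mapping)
        for u, v in tree.edges:
            tree[u][v]["len"] = float(rng.uniform(0.5, 2.0))
        dm = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            dm[i, j] = dm[j, i] = nx.shortest_path_length(
                tree, taxa[i], taxa[j], weight="len"
            )
        newick = neighbor_joining(DistanceMatrix(labels=taxa, values=dm))
        # oracle: recovered tree reproduces all pairwise path lengths
        rec = Phylo.read(io.StringIO(newick), "newick")
        g = nx.Graph()
        counter = itertools.count()

        def add(clade, parent):
            name = clade.name or f"_i{next(counter)}"
            if parent is not None:
                g.add_edge(parent, name, len=clade.branch_length or 0.0)
            for ch in clade.clades:
                add(ch, name)
            return name

        add(rec.root, None)
        for i, j in itertools.combinations(range(n), 2):
            rec_d = nx.shortest_path_length(g, taxa[i], taxa[j], weight="len")
            assert rec_d == pytest.approx(dm[i, j], abs=1e-6)

    def test_equal_distances_star_like(self):
        n = 4
        dm = np.ones((n, n)) - np.eye(n)
        d = DistanceMatrix(labels=list("ABCD"), values=dm)
        bl = _branch_lengths(neighbor_joining(d))
        assert all(v == pytest.approx(0.5) for v in bl.values())

    def test_too_few_taxa_errors(self):
        d = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_nan_distance_errors(self):
        dm = np.zeros((3, 3))
        dm[0, 1] = dm[1, 0] = math.nan
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=list("ABC"), values=dm))

    def test_no_negative_branch_lengths(self):
        # distances violating additivity can produce negative estimates;
        # they must be clamped
        dm = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.05],
                [0.9, 0.9, 0.0, 0.9],
                [0.9, 0.05, 0.9, 0.0],
            ]
        )
        newick = neighbor_joining(DistanceMatrix(labels=list("ABCD"), values=dm))
        tree = Phylo.read(io.StringIO(newick), "newick")
        for cl in tree.find_clades():
            if cl.branch_length is not None:
                assert cl.branch_length >= 0
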