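"""Network construction, centralities, emergent indices, kingdom
statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import bruteforce as bf
from rhizonet import descriptors as desc
from rhizonet import networks as nw
from rhizonet.errors import UndefinedTestError
from rhizonet.io import AbundanceMatrix


def _sparse(type_, entries, otu_ids):
    return desc.SparseInteractionMatrix(
        type=type_,
        host_id="h",
        otu_ids=otu_ids,
        entries=pd.DataFrame(entries, columns=["u", "v", "weight"]),
        threshold=0.95,
    )


class TestBuildNetwork:
    def test_empty_sparse_keeps_isolated_nodes(self, toy_taxonomy):
        G = nw.build_network(_sparse("mutualism", [], [1, 2, 3, 4]), toy_taxonomy)
        assert len(G) == 4 and G.number_of_edges() == 0
        assert not G.is_directed()

    def test_directed_types_and_direction(self, toy_taxonomy):
        G = nw.build_network(
            _sparse("aggression", [(1, 3, 0.99)], [1, 2, 3, 4]), toy_taxonomy
        )
        assert G.is_directed() and G.has_edge(1, 3) and not G.has_edge(3, 1)

    def test_undirected_types(self, toy_taxonomy):
        G = nw.build_network(
            _sparse("mutualism", [(1, 3, 0.99)], [1, 2, 3, 4]), toy_taxonomy
        )
        assert not G.is_directed() and G.has_edge(3, 1)

    def test_unknown_otu_warns(self, toy_taxonomy):
        with pytest.warns(UserWarning):
            G = nw.build_network(
                _sparse("mutualism", [], [1, 2, 99]), toy_taxonomy
            )
        assert G.nodes[99]["kingdom"] == "unknown"


class TestCentralities:
    def test_path_graph_reference_values(self):
        G = nx.path_graph(["a", "b", "c"])
        c = nw.node_centralities(G)
        assert list(c["degree"]) == [1, 2, 1]
        assert c.loc["b", "closeness"] == pytest.approx(1.0)
        assert c.loc["a", "closeness"] == pytest.approx(2 / 3)
        assert c.loc["b", "betweenness"] == pytest.approx(1.0)
        assert c.loc["a", "betweenness"] == 0.0
        assert list(c["eccentricity"]) == [2, 1, 2]

    def test_triangle_symmetry(self):
        c = nw.node_centralities(nx.cycle_graph(3))
        assert np.allclose(c["pagerank"], 1 / 3)
        assert np.allclose(c["eigencentrality"], 1.0)

    def test_edgeless_graph_conventions(self):
        G = nx.empty_graph(5)
        c = nw.node_centralities(G)
        for col in ("closeness", "betweenness", "eccentricity", "eigencentrality"):
            assert (c[col] == 0).all()
        assert np.allclose(c["pagerank"], 1 / 5)

    def test_directed_total_degree(self):
        G = nx.DiGraph([("a", "b"), ("c", "b")])
        c = nw.node_centralities(G)
        assert c.loc["b", "degree"] == 2

    def test_pagerank_sums_to_one_and_eigen_max_one(self, rng):
        A = rng.random((12, 12)) < 0.2
        np.fill_diagonal(A, False)
        G = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
        c = nw.node_centralities(G)
        assert c["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)
        if G.number_of_edges():
            assert c["eigencentrality"].max() == pytest.approx(1.0)
            assert (c["eigencentrality"] >= 0).all()

    def test_matches_bruteforce_on_random_directed_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            A = rng.random((n, n)) < 0.35
            np.fill_diagonal(A, False)
            G = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
            c = nw.node_centralities(G)
            for v, val in bf.closeness_oracle(G).items():
                assert c.loc[v, "closeness"] == pytest.approx(val, abs=1e-12)
            for v, val in bf.betweenness_oracle(G).items():
                assert c.loc[v, "betweenness"] == pytest.approx(val, abs=1e-9)
            for v, val in bf.pagerank_oracle(G).items():
                assert c.loc[v, "pagerank"] == pytest.approx(val, abs=1e-10)


class TestEmergentIndices:
    def test_two_node_single_edge_density(self):
        G = nx.Graph([("a", "b")])
        assert nw.emergent_indices(G)["Con"] == pytest.approx(1.0)

    def test_edgeless(self):
        idx = nw.emergent_indices(nx.empty_graph(4))
        assert idx["Con"] == 0.0 and idx["Closeness"] == 0.0

    def test_triangle_mean_pagerank(self):
        assert nw.emergent_indices(nx.cycle_graph(3))["PageRank"] == pytest.approx(1 / 3)

    def test_density_ignores_weights(self):
        G1 = nx.Graph()
        G1.add_edge("a", "b", weight=0.96)
        G2 = nx.Graph()
        G2.add_edge("a", "b", weight=0.999)
        assert nw.emergent_indices(G1)["Con"] == nw.emergent_indices(G2)["Con"]


class TestIndexTable:
    def _abundance(self, arr, hosts, otus):
        return AbundanceMatrix(
            values=pd.DataFrame(np.asarray(arr, float), index=hosts, columns=otus)
        )

    def test_identical_hosts_identical_rows(self, rng):
        row = rng.lognormal(2, 1, size=8)
        ab = self._abundance([row, row], ["h1", "h2"], list(range(1, 9)))
        idx = nw.index_table(ab)
        assert np.allclose(idx.loc["h1"], idx.loc["h2"])

    def test_otu_permutation_invariance(self, rng):
        arr = rng.lognormal(2, 1, size=(4, 8))
        otus = list(range(1, 9))
        ab1 = self._abundance(arr, list("abcd"), otus)
        perm = rng.permutation(8)
        ab2 = self._abundance(arr[:, perm], list("abcd"), [otus[i] for i in perm])
        pd.testing.assert_frame_equal(
            nw.index_table(ab1), nw.index_table(ab2), check_exact=False, atol=1e-12
        )

    def test_host_permutation_invariance(self, rng):
        arr = rng.lognormal(2, 1, size=(5, 6))
        ab1 = self._abundance(arr, list("abcde"), list(range(6)))
        idx1 = nw.index_table(ab1)
        ab2 = self._abundance(arr[::-1], list("edcba"), list(range(6)))
        idx2 = nw.index_table(ab2)
        pd.testing.assert_frame_equal(idx1.loc[list("abcde")], idx2.loc[list("abcde")])

    def test_degenerate_host_flagged_zero(self):
        ab = self._abundance(
            [[5.0, 3.0, 2.0], [1.0, 0.0, 0.0]], ["ok", "bad"], [1, 2, 3]
        )
        idx = nw.index_table(ab)
        assert (idx.loc["bad"] == 0).all()
        assert idx.attrs["degenerate_hosts"] == ["bad"]

    def test_phenotype_columns_complete(self, small_sim):
        _, _, _, abundance, _ = small_sim
        idx = nw.index_table(abundance)
        assert idx.shape[1] == 24
        assert list(idx.columns) == nw.phenotype_columns()


class TestKingdomStats:
    def test_identical_degree_multisets_null(self, toy_taxonomy):
        G = nx.Graph([(1, 3), (2, 4)])  # each node degree 1
        stat, p, mb, mf = nw.kingdom_degree_test(G, toy_taxonomy)
        assert p > 0.9 and mb == mf == 1.0

    def test_separated_degrees_significant(self):
        tax = pd.DataFrame(
            {
                "otu_id": list(range(1, 21)),
                "kingdom": ["bacteria"] * 10 + ["fungi"] * 10,
                "phylum": ["p"] * 20,
                "class": ["c"] * 20,
            }
        ).set_index("otu_id")
        G = nx.Graph()
        G.add_nodes_from(range(1, 21))
        # bacteria 1..10 all degree 5 (two 5-cliques plus a bit), fungi isolated
        for block in (range(1, 7), range(5, 11)):
            for a in block:
                for b in block:
                    if a < b:
                        G.add_edge(a, b)
        degs = [d for n, d in G.degree() if n <= 10]
        assert min(degs) >= 5
        stat, p, mb, mf = nw.kingdom_degree_test(G, tax)
        assert p < 0.001 and mb > mf

    def test_label_swap_keeps_p(self, toy_taxonomy):
        G = nx.Graph([(1, 2), (1, 3), (1, 4)])
        _, p1, mb, mf = nw.kingdom_degree_test(G, toy_taxonomy)
        swapped = toy_taxonomy.copy()
        swapped["kingdom"] = ["fungi", "fungi", "bacteria", "bacteria"]
        _, p2, mb2, mf2 = nw.kingdom_degree_test(G, swapped)
        assert p1 == pytest.approx(p2)
        assert (mb, mf) == (mf2, mb2)

    def test_missing_kingdom_raises(self):
        tax = pd.DataFrame(
            {"otu_id": [1, 2], "kingdom": ["bacteria"] * 2, "phylum": ["p"] * 2, "class": ["c"] * 2}
        ).set_index("otu_id")
        with pytest.raises(UndefinedTestError):
            nw.kingdom_degree_test(nx.Graph([(1, 2)]), tax)


class TestInterkingdomEdges:
    def test_counts_and_conservation(self, toy_taxonomy):
        G = nx.Graph([(1, 2), (1, 3), (2, 4), (3, 4)])
        inter, within = nw.interkingdom_edges(G, toy_taxonomy)
        assert inter["count"].sum() == 2
        assert within == {"bacteria": 1, "fungi": 1}

    def test_empty_network(self, toy_taxonomy):
        inter, within = nw.interkingdom_edges(nx.Graph(), toy_taxonomy)
        assert inter.empty and within == {"bacteria": 0, "fungi": 0}

    def test_sorted_descending(self, toy_taxonomy):
        G = nx.Graph([(1, 3), (2, 3), (2, 4)])
        inter, _ = nw.interkingdom_edges(G, toy_taxonomy)
        counts = list(inter["count"])
        assert counts == sorted(counts, reverse=True)


def test_consensus_network_is_deterministic(small_sim):
    _, _, tax, abundance, _ = small_sim
    G1 = nw.consensus_network(abundance, tax, "antagonism")
    G2 = nw.consensus_network(abundance, tax, "antagonism")
    assert set(G1.edges) == set(G2.edges)
    assert G1.graph["host_id"] == "consensus"
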