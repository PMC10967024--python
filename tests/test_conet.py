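import networkx as nx
import numpy as np
import pandas as pd
import pytest

from potatonet import conet
from potatonet.conet import (
    DegenerateMarginError,
    build_metanetwork,
    local_properties,
    local_properties_all,
    pair_test,
)
from potatonet.tables_io import CountTable
from _oracles import (
    brute_avg_path_length,
    brute_max_modularity,
    brute_transitivity,
    enumerate_cooccurrence_tails,
)


class TestPairTest:
    def test_full_overlap_matches_enumeration(self):
        """N=10, nA=nB=5, k=5 -> p_more = 1/252 (exhaustive placement count)."""
        presence = np.zeros((10, 2), dtype=bool)
        presence[:5, 0] = True
        presence[:5, 1] = True
        k, expected, p_more, p_less = pair_test(presence, 0, 1)
        assert k == 5
        assert expected == pytest.approx(2.5)
        assert p_more == pytest.approx(1 / 252)
        oracle_more, _ = enumerate_cooccurrence_tails(10, 5, 5, 5)
        assert p_more == pytest.approx(oracle_more, abs=1e-12)

    def test_zero_overlap_symmetric(self):
        presence = np.zeros((10, 2), dtype=bool)
        presence[:5, 0] = True
        presence[5:, 1] = True
        _, _, _, p_less = pair_test(presence, 0, 1)
        assert p_less == pytest.approx(1 / 252)

    @pytest.mark.parametrize("n,na,nb,k", [(6, 3, 2, 2), (8, 4, 4, 1), (12, 7, 5, 4)])
    def test_matches_enumeration(self, n, na, nb, k):
        presence = np.zeros((n, 2), dtype=bool)
        presence[:na, 0] = True
        presence[na - k : na - k + nb, 1] = True  # exactly k overlap
        kk, _, p_more, p_less = pair_test(presence, 0, 1)
        assert kk == k
        om, ol = enumerate_cooccurrence_tails(n, na, nb, k)
        assert p_more == pytest.approx(om, abs=1e-12)
        assert p_less == pytest.approx(ol, abs=1e-12)

    def test_degenerate_margin_skipped(self):
        presence = np.ones((10, 2), dtype=bool)
        presence[3:, 1] = False
        with pytest.raises(DegenerateMarginError):
            pair_test(presence, 0, 1)


def _presence_table(presence: np.ndarray, marker="16S") -> CountTable:
    counts = presence.astype(np.int64) * 10
    return CountTable(
        [f"s{i}" for i in range(presence.shape[0])],
        [f"t{j}" for j in range(presence.shape[1])],
        counts,
        marker,
    )


class TestBuildMetanetwork:
    def test_perfect_exclusion_negative_edge(self):
        rng = np.random.default_rng(0)
        presence = rng.random((40, 10)) < 0.5
        presence[:, 0] = rng.random(40) < 0.5
        presence[:, 1] = ~presence[:, 0]
        # anchor margins away from degeneracy
        presence[:5, :] = True
        presence[:5, 1] = False
        presence[0, 1] = True
        presence[0, 0] = False
        table = _presence_table(presence)
        depth = int(table.sample_totals().min())
        net = build_metanetwork(table, depth=depth, seed=0, min_prevalence=3)
        neg = net.edges[(net.edges["sign"] == "-")]
        assert {"t0", "t1"} in [set(x) for x in zip(neg["node_a"], neg["node_b"])]

    def test_sample_and_taxon_order_invariance(self):
        rng = np.random.default_rng(1)
        presence = rng.random((30, 12)) < 0.5
        t1 = _presence_table(presence)
        perm_s = rng.permutation(30)
        perm_t = rng.permutation(12)
        t2 = CountTable(
            [t1.sample_ids[i] for i in perm_s],
            [t1.taxon_ids[j] for j in perm_t],
            t1.counts[np.ix_(perm_s, perm_t)],
            "16S",
        )
        depth = int(t1.sample_totals().min())
        n1 = build_metanetwork(t1, depth=depth, seed=0, min_prevalence=3)
        n2 = build_metanetwork(t2, depth=depth, seed=0, min_prevalence=3)

        def canon(net):
            return {
                (frozenset((r.node_a, r.node_b)), r.sign, r.k) for r in net.edges.itertuples()
            }

        assert canon(n1) == canon(n2)

    def test_too_few_taxa_after_filter(self):
        presence = np.ones((20, 4), dtype=bool)  # everything degenerate
        with pytest.raises(ValueError, match="fewer than 3"):
            build_metanetwork(_presence_table(presence), depth=40, seed=0)

    def test_permutation_null_agrees_on_strong_signal(self):
        rng = np.random.default_rng(2)
        presence = rng.random((60, 4)) < 0.5
        presence[:, 1] = presence[:, 0]  # perfect co-occurrence
        table = _presence_table(presence)
        net = build_metanetwork(
            table, depth=10, seed=0, min_prevalence=3, null="permutation", n_perm=999
        )
        pos = net.edges[net.edges["sign"] == "+"]
        assert {"t0", "t1"} in [set(x) for x in zip(pos["node_a"], pos["node_b"])]


def _metanet_from_edges(edges, nodes, marker="16S", sign="+"):
    df = pd.DataFrame(
        [(a, b, sign, 1, 0.5, 0.01, 0.01) for a, b in edges],
        columns=["node_a", "node_b", "sign", "k", "expected", "p", "q"],
    )
    return conet.MetaNetwork(marker=marker, nodes=list(nodes), edges=df)


def _one_sample_table(present, all_taxa, marker="16S"):
    counts = np.array([[10 if t in present else 0 for t in all_taxa]])
    return CountTable(["s0"], list(all_taxa), counts, marker)


class TestLocalProperties:
    def test_triangle(self):
        nodes = ["a", "b", "c"]
        net = _metanet_from_edges([("a", "b"), ("b", "c"), ("a", "c")], nodes)
        t = _one_sample_table(set(nodes), nodes)
        lp = local_properties(net, t, "s0", "+", seed=0)
        assert lp.transitivity == 1.0
        assert lp.average_path_length == 1.0
        assert lp.n_edges == 3

    def test_three_node_path(self):
        nodes = ["a", "b", "c"]
        net = _metanet_from_edges([("a", "b"), ("b", "c")], nodes)
        t = _one_sample_table(set(nodes), nodes)
        lp = local_properties(net, t, "s0", "+", seed=0)
        assert lp.transitivity == 0.0
        assert lp.average_path_length == pytest.approx(4 / 3)

    def test_two_disjoint_cliques_q_half(self):
        nodes = list("abcdef")
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]
        net = _metanet_from_edges(edges, nodes)
        t = _one_sample_table(set(nodes), nodes)
        lp = local_properties(net, t, "s0", "+", seed=0, restarts=10)
        assert lp.modularity == pytest.approx(0.5)

    def test_absent_taxon_excluded_from_subgraph(self):
        nodes = ["a", "b", "c"]
        net = _metanet_from_edges([("a", "b"), ("b", "c"), ("a", "c")], nodes)
        t = _one_sample_table({"a", "b"}, nodes)
        lp = local_properties(net, t, "s0", "+", seed=0)
        assert lp.n_nodes == 2 and lp.n_edges == 1

    def test_isolated_taxon_changes_nothing(self):
        nodes = ["a", "b", "c", "iso"]
        net = _metanet_from_edges([("a", "b"), ("b", "c")], nodes)
        with_iso = local_properties(
            net, _one_sample_table({"a", "b", "c", "iso"}, nodes), "s0", "+", seed=0
        )
        without = local_properties(
            net, _one_sample_table({"a", "b", "c"}, nodes), "s0", "+", seed=0
        )
        assert with_iso.transitivity == without.transitivity
        assert with_iso.average_path_length == without.average_path_length
        assert with_iso.modularity == pytest.approx(without.modularity)

    def test_edgeless_subgraph_missing_not_zero(self):
        nodes = ["a", "b", "c"]
        net = _metanet_from_edges([("a", "b")], nodes)
        lp = local_properties(net, _one_sample_table({"c"}, nodes), "s0", "+", seed=0)
        assert np.isnan(lp.modularity)
        assert np.isnan(lp.transitivity)
        assert np.isnan(lp.average_path_length)

    def test_unknown_sample(self):
        net = _metanet_from_edges([("a", "b")], ["a", "b"])
        with pytest.raises(KeyError):
            local_properties(net, _one_sample_table({"a"}, ["a", "b"]), "nope", "+")


class TestLocalPropertiesAll:
    def test_composition_and_determinism(self):
        rng = np.random.default_rng(3)
        nodes = [f"t{j}" for j in range(6)]
        net_edges = [("t0", "t1"), ("t1", "t2"), ("t3", "t4")]
        net = _metanet_from_edges(net_edges, nodes)
        counts = (rng.random((4, 6)) < 0.7).astype(np.int64) * 5
        table = CountTable([f"s{i}" for i in range(4)], nodes, counts, "16S")
        all1 = local_properties_all({"16S": net}, {"16S": table}, seed=9)
        all2 = local_properties_all({"16S": net}, {"16S": table}, seed=9)
        pd.testing.assert_frame_equal(all1, all2)
        assert len(all1) == 4 * 2  # samples x signs
        row = all1[(all1["sample_id"] == "s0") & (all1["sign"] == "co-occurrence")].iloc[0]
        single = local_properties(net, table, "s0", "+", seed=9)
        assert row["n_edges"] == single.n_edges

    def test_empty_coexclusion_all_missing(self):
        nodes = ["a", "b"]
        net = _metanet_from_edges([("a", "b")], nodes)  # only "+" edges
        table = _one_sample_table({"a", "b"}, nodes)
        out = local_properties_all({"16S": net}, {"16S": table}, seed=0)
        ex = out[out["sign"] == "co-exclusion"]
        assert ex["modularity"].isna().all()
        assert ex["transitivity"].isna().all()


class TestGraphPrimitiveOracles:
    """Spot oracle equivalence on random small graphs (the exhaustive sweep
    lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_brute_force(self, seed):
        g = nx.gnp_random_graph(6, 0.5, seed=seed)
        edges, nodes = list(g.edges), list(g.nodes)
        assert conet.graph_transitivity(g) == pytest.approx(
            brute_transitivity(edges, nodes), abs=1e-12
        )
        apl = conet.average_path_length(g)
        oracle = brute_avg_path_length(edges, nodes)
        if np.isnan(oracle):
            assert np.isnan(apl)
        else:
            assert apl == pytest.approx(oracle, abs=1e-12)
        if edges:
            q = conet.best_louvain_q(g, seed=0, restarts=10)
            assert q <= brute_max_modularity(edges, nodes) + 1e-12
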