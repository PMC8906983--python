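"""Graph construction, centralities, ranking, and the heterogeneous network."""

import math

import networkx as nx
import pytest

from herbnet import tables
from herbnet.network import (
    HetNetwork,
    ScoredEdge,
    betweenness_centrality,
    build_didt_network,
    build_ppi,
    centrality_table,
    closeness_centrality,
    compound_importance,
    degree_centrality,
    format_avg_degree,
    load_scored_edges,
    rank_nodes,
    summarize,
    write_scored_edges,
    write_sif,
)
from herbnet.targetsets import TargetSet

from oracles import brute_betweenness, brute_closeness


def simple_net(edges, nodes=()):
    net = HetNetwork()
    for e in edges:
        for v in e:
            if v not in net.graph:
                net.add_node(v)
    for v in nodes:
        if v not in net.graph:
            net.add_node(v)
    for a, b in edges:
        net.add_edge(a, b)
    return net


def from_nx(graph):
    return simple_net(list(graph.edges), nodes=list(graph.nodes))


class TestBuildPPI:
    def test_threshold_arithmetic(self):
        edges = [ScoredEdge("A", "B", 0.9), ScoredEdge("B", "C", 0.3),
                 ScoredEdge("C", "D", 0.41)]
        net = build_ppi(edges, threshold=0.4, drop_isolated=True)
        assert set(net.nodes()) == {"A", "B", "C", "D"}
        assert {frozenset(e) for e in net.edges()} == {
            frozenset(("A", "B")), frozenset(("C", "D"))
        }

    def test_all_below_threshold_gives_empty_network(self):
        net = build_ppi([ScoredEdge("A", "B", 0.1)], threshold=0.4)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_isolated_nodes_kept_when_requested(self):
        net = build_ppi([ScoredEdge("A", "B", 0.1), ScoredEdge("C", "D", 0.9)],
                        drop_isolated=False)
        assert set(net.nodes()) == {"A", "B", "C", "D"}
        assert net.n_edges == 1

    def test_inclusive_vs_strict_boundary(self):
        edges = [ScoredEdge("A", "B", 0.4)]
        assert build_ppi(edges, threshold=0.4).n_edges == 1
        assert build_ppi(edges, threshold=0.4, strict=True).n_edges == 0

    def test_duplicates_collapse_keeping_max_score(self):
        net = build_ppi([ScoredEdge("A", "B", 0.5), ScoredEdge("B", "A", 0.8)])
        assert net.n_edges == 1
        assert net.graph.edges["A", "B"]["score"] == 0.8

    def test_input_self_loop_skipped_not_fatal(self):
        net = build_ppi([("A", "A", 0.9), ("A", "B", 0.9)])
        assert net.n_edges == 1

    def test_zero_threshold_never_yields_fewer_edges(self, paper_cfg):
        from herbnet.fixtures import gen_ppi

        edges = gen_ppi(paper_cfg)
        for threshold in (0.2, 0.4, 0.7, 0.95):
            assert build_ppi(edges, 0.0).n_edges >= build_ppi(edges, threshold).n_edges

    def test_string_dialect_with_integer_scores(self, tmp_path):
        path = tmp_path / "string.tsv"
        path.write_text("protein1 protein2 combined_score\nAKT1 MAPK3 900\nAKT1 CAT 150\n")
        edges = load_scored_edges(path)
        assert edges[0].score == pytest.approx(0.9)
        net = build_ppi(edges, threshold=0.4)
        assert {frozenset(e) for e in net.edges()} == {frozenset(("AKT1", "MAPK3"))}

    def test_native_tsv_roundtrip(self, tmp_path):
        edges = [ScoredEdge("A", "B", 0.55), ScoredEdge("B", "C", 0.2)]
        path = tmp_path / "edges.tsv"
        write_scored_edges(edges, path)
        assert load_scored_edges(path) == edges


class TestSummary:
    def test_40_nodes_233_edges_truncates_to_11_6(self):
        graph = nx.gnm_random_graph(40, 233, seed=1)
        summary = summarize(from_nx(graph))
        assert summary.avg_degree == pytest.approx(2 * 233 / 40)  # 11.65 exactly
        assert format_avg_degree(summary.avg_degree) == "11.6"

    def test_truncation_not_rounding(self):
        assert format_avg_degree(11.69) == "11.6"
        assert format_avg_degree(2.0) == "2.0"

    def test_triangle(self):
        summary = summarize(simple_net([("A", "B"), ("B", "C"), ("A", "C")]))
        assert summary.avg_degree == 2.0

    def test_single_node_no_edges(self):
        assert summarize(simple_net([], nodes=["A"])).avg_degree == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            summarize(HetNetwork())


class TestDegree:
    def test_star(self):
        leaves = [f"L{i}" for i in range(4)]
        net = simple_net([("hub", leaf) for leaf in leaves])
        deg = degree_centrality(net)
        assert deg["hub"] == 4
        assert all(deg[leaf] == 1 for leaf in leaves)

    def test_empty_graph_gives_empty_table(self):
        assert degree_centrality(HetNetwork()) == {}

    def test_degree_sum_is_twice_edges(self, paper_cfg):
        from herbnet.fixtures import gen_ppi

        net = build_ppi(gen_ppi(paper_cfg))
        assert sum(degree_centrality(net).values()) == 2 * net.n_edges


class TestCloseness:
    def test_path_closed_form(self):
        net = simple_net([("A", "B"), ("B", "C")])
        clo = closeness_centrality(net)
        assert clo["B"] == pytest.approx(0.5)
        assert clo["A"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n", range(3, 8))
    def test_complete_graph_closed_form(self, n):
        net = from_nx(nx.complete_graph(n))
        assert all(v == pytest.approx(1 / (n - 1))
                   for v in closeness_centrality(net).values())

    def test_singleton_component_scores_zero(self):
        net = simple_net([("A", "B")], nodes=["C"])
        assert closeness_centrality(net)["C"] == 0.0

    def test_disconnected_uses_within_component_distances(self):
        net = simple_net([("A", "B"), ("C", "D"), ("D", "E")])
        clo = closeness_centrality(net)
        assert clo["A"] == pytest.approx(1.0)   # one neighbour at distance 1
        assert clo["D"] == pytest.approx(0.5)   # distances 1 + 1

    def test_normalized_variant(self):
        net = simple_net([("A", "B"), ("B", "C")])
        clo = closeness_centrality(net, normalized=True)
        assert clo["A"] == pytest.approx(2 / 3)

    def test_matches_bfs_oracle_on_random_connected_graph(self):
        graph = nx.connected_watts_strogatz_graph(20, 4, 0.3, seed=3)
        net = from_nx(graph)
        expected = brute_closeness(net.adjacency())
        got = closeness_centrality(net)
        assert got == pytest.approx(expected)


class TestBetweenness:
    @pytest.mark.parametrize("n", range(3, 11))
    def test_star_center_closed_form(self, n):
        net = simple_net([("hub", f"L{i}") for i in range(n)])
        bet = betweenness_centrality(net)
        assert bet["hub"] == pytest.approx(n * (n - 1) / 2)
        assert all(bet[f"L{i}"] == 0.0 for i in range(n))

    def test_path_of_four(self):
        net = simple_net([("A", "B"), ("B", "C"), ("C", "D")])
        bet = betweenness_centrality(net)
        assert bet["B"] == pytest.approx(2.0)
        assert bet["C"] == pytest.approx(2.0)
        assert bet["A"] == bet["D"] == 0.0

    def test_fractional_accumulation_on_cycle(self):
        # C4: each node lies on one of the two shortest paths of its
        # opposite pair, contributing exactly 1/2
        net = from_nx(nx.cycle_graph(4))
        bet = betweenness_centrality(net)
        assert all(v == pytest.approx(0.5) for v in bet.values())

    def test_leaves_score_zero(self, paper_cfg):
        from herbnet.fixtures import gen_ppi

        net = build_ppi(gen_ppi(paper_cfg))
        bet = betweenness_centrality(net)
        deg = degree_centrality(net)
        for node, d in deg.items():
            if d == 1:
                assert bet[node] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_and_networkx(self, seed):
        graph = nx.gnp_random_graph(18, 0.15, seed=seed)
        net = from_nx(graph)
        got = betweenness_centrality(net)
        expected = brute_betweenness(net.adjacency())
        assert got == pytest.approx(expected, abs=1e-9)
        nx_bc = nx.betweenness_centrality(graph, normalized=False)
        assert got == pytest.approx(nx_bc, abs=1e-9)


class TestRanking:
    def test_tie_broken_by_ascending_id(self):
        net = simple_net([("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"),
                          ("A", "D")])
        # degrees: A=3, B=3, C=2, D=2
        table = centrality_table(net)
        assert rank_nodes(table, "degree", 2) == ["A", "B"]

    def test_metric_aliases(self):
        net = simple_net([("A", "B"), ("B", "C")])
        table = centrality_table(net)
        assert rank_nodes(table, "DC", 1) == rank_nodes(table, "degree", 1) == ["B"]
        assert rank_nodes(table, "BC", 1) == ["B"]

    def test_top_k_exceeding_node_count_returns_all(self):
        net = simple_net([("A", "B")])
        assert rank_nodes(centrality_table(net), "degree", 10) == ["A", "B"]

    def test_single_node_graph(self):
        net = simple_net([], nodes=["A"])
        assert rank_nodes(centrality_table(net), "degree", 1) == ["A"]

    def test_rank_columns_consistent_with_rank_nodes(self):
        net = simple_net([("A", "B"), ("B", "C"), ("B", "D")])
        table = centrality_table(net)
        by_rank = table.sort_values("rank_degree")["node"].tolist()
        assert by_rank == rank_nodes(table, "degree", len(table))


class TestDidtNetwork:
    def test_edge_counting(self):
        disease = TargetSet.from_symbols("disease", ["T1", "T2"])
        net = build_didt_network(
            "drug", ["i1", "i2"], {"i1": {"T1", "T2"}, "i2": {"T2"}},
            "dis", disease,
        )
        assert net.n_nodes == 6
        assert net.n_edges == 7  # 2 drug-ingredient + 3 ingredient-target + 2 disease-target

    def test_ingredient_with_no_targets_connects_only_to_drug(self):
        disease = TargetSet.from_symbols("disease", ["T1"])
        net = build_didt_network("drug", ["i1"], {}, "dis", disease)
        assert degree_centrality(net)["i1"] == 1

    def test_undeclared_ingredient_rejected(self):
        disease = TargetSet.from_symbols("disease", ["T1"])
        with pytest.raises(ValueError, match="undeclared"):
            build_didt_network("drug", ["i1"], {"ghost": {"T1"}}, "dis", disease)

    def test_mapped_target_outside_disease_set_rejected(self):
        disease = TargetSet.from_symbols("disease", ["T1"])
        with pytest.raises(ValueError, match="outside"):
            build_didt_network("drug", ["i1"], {"i1": {"T9"}}, "dis", disease)

    def test_node_types_assigned(self):
        disease = TargetSet.from_symbols("disease", ["T1"])
        net = build_didt_network("drug", ["i1"], {"i1": {"T1"}}, "dis", disease)
        assert net.node_type("drug") == "drug"
        assert net.node_type("i1") == "ingredient"
        assert net.node_type("dis") == "disease"
        assert net.node_type("T1") == "target"


class TestCompoundImportance:
    @pytest.fixture
    def reference_didt(self, reference_targets):
        mapping = tables.compound_target_map()
        return build_didt_network(
            tables.DRUG_ID, sorted(mapping), mapping,
            tables.DISEASE_ID, reference_targets,
        )

    def test_reference_degrees_match_printed_table(self, reference_didt):
        # graph degree = printed compound-target degree + the one drug edge
        deg = degree_centrality(reference_didt)
        for row in tables.compound_centralities():
            assert deg[row.name] == row.degree + 1

    def test_naringenin_ranks_first_by_all_metrics(self, reference_didt):
        table = compound_importance(reference_didt)
        assert table.iloc[0]["node"] == "Naringenin"
        assert int(table.iloc[0]["rank_degree"]) == min(table["rank_degree"])
        full = centrality_table(reference_didt)
        compounds = full[full["node_type"] == "ingredient"]
        for metric in ("degree", "closeness", "betweenness"):
            best = compounds.sort_values([metric, "node"],
                                         ascending=[False, True]).iloc[0]
            assert best["node"] == "Naringenin"

    def test_tied_compounds_order_by_id(self):
        disease = TargetSet.from_symbols("disease", ["T1", "T2"])
        net = build_didt_network(
            "drug", ["b_cpd", "a_cpd"],
            {"a_cpd": {"T1"}, "b_cpd": {"T2"}}, "dis", disease,
        )
        table = compound_importance(net)
        assert table["node"].tolist() == ["a_cpd", "b_cpd"]

    def test_no_ingredient_nodes_rejected(self):
        with pytest.raises(ValueError):
            compound_importance(simple_net([("A", "B")]))


class TestExport:
    def test_sif_lists_edges_and_isolated_nodes(self, tmp_path):
        net = simple_net([("A", "B")], nodes=["C"])
        path = tmp_path / "net.sif"
        write_sif(net, path)
        lines = path.read_text().splitlines()
        assert "A\tpp\tB" in lines and "C" in lines

    def test_graphml_roundtrips_node_types(self, tmp_path):
        disease = TargetSet.from_symbols("disease", ["T1"])
        net = build_didt_network("drug", ["i1"], {"i1": {"T1"}}, "dis", disease)
        path = tmp_path / "net.graphml"
        from herbnet.network import write_graphml

        write_graphml(net, path)
        back = nx.read_graphml(path)
        assert back.nodes["i1"]["node_type"] == "ingredient"
        assert back.number_of_edges() == net.n_edges
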