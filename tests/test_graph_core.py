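"""Interaction parsing, exclusion filtering, graph assembly and hub ranking."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppimod.graph_core import (
    ExclusionList,
    InteractionRecord,
    betweenness_centrality,
    build_graph,
    canonical_edges,
    filter_nonspecific,
    graph_from_pairs,
    map_orthologs,
    normalize_symbol,
    rank_hubs,
    read_interaction_table,
)


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent oracle: enumerate ALL simple paths per node pair, keep the
    shortest ones, and accumulate the fraction passing through each node."""
    bc = dict.fromkeys(g.nodes, 0.0)
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        minimal = [p for p in paths if len(p) == shortest]
        for p in minimal:
            for node in p[1:-1]:
                bc[node] += 1.0 / len(minimal)
    return bc


class TestNormalize:
    @given(st.text(min_size=1).filter(lambda s: s.strip()))
    def test_idempotent(self, raw):
        once = normalize_symbol(raw)
        assert normalize_symbol(once) == once

    @pytest.mark.parametrize("raw,expected", [("cdk2", "CDK2"), (" a \t b ", "A B")])
    def test_canonical_form(self, raw, expected):
        assert normalize_symbol(raw) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_symbol("   ")


class TestReadInteractionTable:
    def test_tsv_rows(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("A\tB\nB\tC\n")
        recs = read_interaction_table(f, "tsv")
        assert [(r.gene_a, r.gene_b) for r in recs] == [("A", "B"), ("B", "C")]

    def test_sif_one_source_many_targets(self, tmp_path):
        f = tmp_path / "net.sif"
        f.write_text("A pp B C\n")
        recs = read_interaction_table(f, "sif")
        assert [(r.gene_a, r.gene_b) for r in recs] == [("A", "B"), ("A", "C")]

    def test_rows_normalized(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("a \t b\n")
        (rec,) = read_interaction_table(f, "tsv")
        assert (rec.gene_a, rec.gene_b) == ("A", "B")

    def test_malformed_row_names_line(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("A\tB\nonly_one_column\n")
        with pytest.raises(ValueError, match="line 2"):
            read_interaction_table(f, "tsv")

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("")
        assert read_interaction_table(f, "tsv") == []


class TestMapOrthologs:
    def test_best_score(self):
        mapped, rep = map_orthologs(["p1"], {"p1": [("X", 0.9), ("Y", 0.7)]})
        assert mapped == ["X"] and rep["n_unmapped"] == 0

    def test_lexicographic_tie_break(self):
        mapped, _ = map_orthologs(["p1"], {"p1": [("Y", 0.8), ("X", 0.8)]})
        assert mapped == ["X"]

    def test_unmapped_dropped_and_counted(self):
        mapped, rep = map_orthologs(["p1", "p2"], {"p1": [("X", 0.5)]})
        assert mapped == ["X"] and rep["n_unmapped"] == 1


class TestFilterNonspecific:
    def test_prefix_rule_removes_ribosomal(self):
        recs = [InteractionRecord.make("A", "RPL3"), InteractionRecord.make("A", "B")]
        out = filter_nonspecific(recs, ExclusionList(prefix_rules={"RPL"}))
        assert [(r.gene_a, r.gene_b) for r in out] == [("A", "B")]

    def test_empty_list_is_identity(self):
        recs = [InteractionRecord.make("A", "B")]
        assert filter_nonspecific(recs, ExclusionList()) == recs

    def test_either_endpoint_suffices(self):
        recs = [InteractionRecord.make("UBC", "CUL1")]
        assert filter_nonspecific(recs, ExclusionList(exact_symbols={"UBC"})) == []

    def test_exclusion_file_roundtrip(self, tmp_path):
        f = tmp_path / "excl.txt"
        f.write_text("# nonspecific\nRPL*\nUBC\n")
        excl = ExclusionList.from_file(f)
        assert excl.matches("RPL7A") and excl.matches("ubc") and not excl.matches("CDK2")


class TestBuildGraph:
    def test_dedup_and_self_loop_removal(self):
        recs = [InteractionRecord.make(*p) for p in [("A", "B"), ("B", "A"), ("A", "A"), ("B", "C")]]
        g = build_graph(recs)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_empty(self):
        g = build_graph([])
        assert g.number_of_nodes() == 0

    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=40))
    def test_idempotent_and_order_invariant(self, pairs):
        named = [(f"N{a}", f"N{b}") for a, b in pairs]
        g = graph_from_pairs(named)
        rebuilt = graph_from_pairs(canonical_edges(g))
        assert canonical_edges(rebuilt) == canonical_edges(g)
        reversed_g = graph_from_pairs(list(reversed(named)))
        assert canonical_edges(reversed_g) == canonical_edges(g)
        assert g.number_of_edges() <= len(named)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)), max_size=40))
    def test_filter_commutes_with_node_deletion(self, pairs):
        recs = [InteractionRecord.make(f"N{a}", f"N{b}") for a, b in pairs]
        excl = ExclusionList(exact_symbols={"N0", "N1"})
        filtered_first = build_graph(filter_nonspecific(recs, excl))
        built_first = build_graph(recs)
        built_first.remove_nodes_from([n for n in list(built_first) if excl.matches(n)])
        built_first.remove_nodes_from(list(nx.isolates(built_first)))
        assert canonical_edges(filtered_first) == canonical_edges(built_first)


class TestBetweenness:
    def test_path_graph_intermediary(self):
        g = graph_from_pairs([("A", "B"), ("B", "C")])
        bc = betweenness_centrality(g, normalized=False)
        assert bc["B"] == pytest.approx(1.0) and bc["A"] == bc["C"] == 0.0

    def test_complete_graph_all_zero(self):
        g = nx.complete_graph(4)
        assert all(v == 0.0 for v in betweenness_centrality(g).values())

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            bc = betweenness_centrality(g, normalized=False)
            oracle = brute_force_betweenness(g)
            for node in g:
                assert bc[node] == pytest.approx(oracle[node], abs=1e-9)


class TestRankHubs:
    def test_star_hub_first_by_degree(self):
        g = nx.star_graph(5)
        table = rank_hubs(nx.relabel_nodes(g, lambda n: f"N{n}"), metric="degree")
        assert table.iloc[0]["gene"] == "N0" and table.iloc[0]["rank"] == 1

    def test_tie_broken_by_other_metric(self):
        # every node has betweenness 0; A has degree 2, B and C degree 1
        g = graph_from_pairs([("A", "X"), ("A", "Y"), ("X", "Y"), ("B", "C")])
        table = rank_hubs(g, metric="betweenness")
        assert table.iloc[0]["gene"] == "A"
        assert list(table["gene"])[-2:] == ["B", "C"]

    def test_ranks_are_dense(self):
        g = nx.path_graph(6)
        table = rank_hubs(nx.relabel_nodes(g, str), metric="degree")
        assert list(table["rank"]) == list(range(1, 7))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            rank_hubs(nx.Graph(), metric="degree")

    def test_planted_kinase_hub_tops_both_metrics(self, pipeline, truth):
        table_deg = rank_hubs(pipeline.graph, metric="degree")
        table_btw = rank_hubs(pipeline.graph, metric="betweenness")
        top_kinase = truth.kinases[0]
        assert top_kinase in set(table_deg.head(3)["gene"])
        assert top_kinase in set(table_btw.head(3)["gene"])
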