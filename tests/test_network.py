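"""Crosstalk-network construction, degree statistics, hub ranking, export."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathcrosstalk.crosstalk_network import (
    CrossRefRecord,
    NetworkError,
    NodeStats,
    adjacency_to_crossrefs,
    build_network,
    export_network,
    import_edge_list,
    interaction_counts,
    rank_hubs,
    read_adjacency_matrix,
)
from pathcrosstalk.redundancy import MergedCollection, PathwayEntry


def pw(name, genes=("X",), p=0.01):
    return PathwayEntry(name=name, union_genes=frozenset(genes), p_value=p)


def coll(name, members, p=0.01):
    return MergedCollection(
        name=name, members=tuple(members), union_genes=frozenset({"X"}),
        dominant_member=members[0], p_value=p,
    )


class TestBuildNetwork:
    def test_empty_crossrefs_give_isolated_nodes(self):
        net = build_network([], [pw("A"), pw("B")])
        assert net.edges == set()
        assert all(s.interaction_count == 0 for s in interaction_counts(net))

    def test_bidirectional_records_collapse_to_one_edge(self):
        records = [CrossRefRecord("A", "B"), CrossRefRecord("B", "A")]
        net = build_network(records, [pw("A"), pw("B"), pw("C")])
        assert net.edges == {frozenset({"A", "B"})}
        counts = {s.name: s.interaction_count for s in interaction_counts(net)}
        assert counts == {"A": 1, "B": 1, "C": 0}

    def test_listed_only_records_never_add_edges(self):
        base = [CrossRefRecord("A", "B")]
        extra = base + [CrossRefRecord("A", "C", context="listed_only")]
        entries = [pw("A"), pw("B"), pw("C")]
        assert build_network(base, entries).edges == build_network(extra, entries).edges

    def test_explicit_exclusion_pairs_dropped(self):
        records = [CrossRefRecord("A", "B"), CrossRefRecord("A", "C")]
        net = build_network(records, [pw("A"), pw("B"), pw("C")],
                            exclusions=[("A", "C")])
        assert net.edges == {frozenset({"A", "B"})}

    def test_member_reference_attaches_to_collection(self):
        entries = [coll("COLL", ["M1", "M2"]), pw("A")]
        net = build_network([CrossRefRecord("A", "M2")], entries)
        assert net.edges == {frozenset({"COLL", "A"})}

    def test_intra_collection_references_make_no_edge(self):
        entries = [coll("COLL", ["M1", "M2"])]
        net = build_network([CrossRefRecord("M1", "M2")], entries)
        assert net.edges == set()

    def test_references_outside_entry_list_ignored(self):
        net = build_network([CrossRefRecord("A", "GHOST")], [pw("A"), pw("B")])
        assert net.edges == set()

    def test_self_reference_record_rejected(self):
        with pytest.raises(NetworkError):
            CrossRefRecord("A", "A")

    def test_collection_absorbs_member_neighbors(self):
        # the collection's degree is at least any single member's degree
        # restricted to non-member neighbors
        records = [CrossRefRecord("A", "M1"), CrossRefRecord("B", "M2")]
        merged = build_network(records, [coll("COLL", ["M1", "M2"]), pw("A"), pw("B")])
        alone = build_network(records, [pw("M1"), pw("A"), pw("B")])
        assert merged.degree("COLL") >= alone.degree("M1")

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_record_order_permutation_invariance_and_degree_sum(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"N{i}" for i in range(6)]
        pairs = [(a, b) for a, b in itertools.permutations(names, 2)]
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=8, replace=False)]
        records = [CrossRefRecord(a, b) for a, b in chosen]
        entries = [pw(n) for n in names]
        net1 = build_network(records, entries)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        net2 = build_network(shuffled, entries)
        assert net1.edges == net2.edges
        counts = interaction_counts(net1)
        assert sum(s.interaction_count for s in counts) == 2 * len(net1.edges)


class TestRankHubs:
    def test_single_node(self):
        ranked = rank_hubs([NodeStats("ONLY", 0)])
        assert ranked[0].name == "ONLY"

    def test_descending_with_name_ties(self):
        stats = [NodeStats("B", 3), NodeStats("A", 3), NodeStats("C", 5)]
        ranked = rank_hubs(stats)
        assert [s.name for s in ranked] == ["C", "A", "B"]

    def test_empty_rejected(self):
        with pytest.raises(NetworkError):
            rank_hubs([])


class TestExportImport:
    def test_empty_network_header_only(self, tmp_path):
        net = build_network([], [])
        path = export_network(net, tmp_path / "empty.tsv", format="edgelist")
        assert path.read_text() == "source\ttarget\n"

    def test_path_graph_edge_list_round_trip(self, tmp_path):
        records = [CrossRefRecord("A", "B"), CrossRefRecord("B", "C")]
        net = build_network(records, [pw("A"), pw("B"), pw("C")])
        path = export_network(net, tmp_path / "path.tsv", format="edgelist")
        assert import_edge_list(path) == net.edges
        assert len(path.read_text().strip().splitlines()) == 3  # header + 2 edges

    def test_sif_lists_isolated_nodes(self, tmp_path):
        net = build_network([CrossRefRecord("A", "B")], [pw("A"), pw("B"), pw("LONE")])
        text = export_network(net, tmp_path / "n.sif", format="sif").read_text()
        assert "A\tcrosstalk\tB" in text and "LONE" in text

    def test_graphml_preserves_node_attributes(self, tmp_path):
        import networkx as nx

        net = build_network(
            [CrossRefRecord("A", "B")],
            [pw("A", p=1e-5), pw("B")],
            node_attrs={"A": {"klass": "function"}},
        )
        path = export_network(net, tmp_path / "n.graphml", format="graphml")
        back = nx.read_graphml(path)
        assert back.nodes["A"]["p_value"] == pytest.approx(1e-5)
        assert back.nodes["A"]["klass"] == "function"

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network([], [pw("A")])
        with pytest.raises(NetworkError):
            export_network(net, tmp_path / "x", format="gexf")


class TestAdjacency:
    def test_round_trip_via_crossrefs(self, tmp_path):
        import pandas as pd

        names = ["A", "B", "C"]
        adj = pd.DataFrame(0, index=names, columns=names)
        adj.loc["A", "B"] = adj.loc["B", "A"] = 1
        path = tmp_path / "adj.tsv"
        adj.to_csv(path, sep="\t")
        records = adjacency_to_crossrefs(read_adjacency_matrix(path))
        net = build_network(records, [pw(n) for n in names])
        assert net.edges == {frozenset({"A", "B"})}

    def test_asymmetric_matrix_rejected(self, tmp_path):
        import pandas as pd

        names = ["A", "B"]
        adj = pd.DataFrame([[0, 1], [0, 0]], index=names, columns=names)
        path = tmp_path / "bad.tsv"
        adj.to_csv(path, sep="\t")
        with pytest.raises(NetworkError, match="symmetric"):
            read_adjacency_matrix(path)
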