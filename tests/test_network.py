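"""Impact-network construction and layer decomposition."""

import pandas as pd
import pytest

from phosnet.network import (
    BOT,
    LAYERS,
    MID,
    OUTGROUP,
    TOP,
    LayerAssignment,
    assign_layers_simple,
    assign_layers_stringent,
    build_network,
    export_attributed_network,
    layer_recovery,
    phosphatase_placement,
    restrict_to_measured,
    subnetwork_by_class,
)

from .conftest import random_digraph
from .oracles import brute_force_layers


class TestBuildNetwork:
    def test_duplicate_edges_collapse(self):
        net = build_network([("A", "B"), ("A", "B")])
        assert net.n_edges == 1
        assert net.n_duplicates_dropped == 1

    def test_self_loops_dropped_and_counted(self):
        net = build_network([("A", "A"), ("A", "B")])
        assert net.edges == [("A", "B")]
        assert net.n_self_loops_dropped == 1
        assert "A" in net  # the looped node itself is kept

    def test_declared_universe_keeps_isolated_nodes(self):
        net = build_network([("A", "B"), ("B", "C"), ("A", "C")],
                            node_universe=["A", "B", "C", "D"])
        assert net.n_nodes == 4
        assert net.n_edges == 3

    def test_missing_endpoint_raises(self):
        with pytest.raises(ValueError, match="edge 1"):
            build_network([("A", "B"), ("A", "")])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            build_network([])


class TestSubnetworkByClass:
    def test_keeps_only_within_class_edges(self, mixed_records):
        net = build_network(
            [("K1", "K2"), ("K2", "K3"), ("K1", "X1"), ("K1", "P1"), ("P1", "X2")]
        )
        sub = subnetwork_by_class(net, mixed_records, "kinase")
        assert sorted(sub.edges) == [("K1", "K2"), ("K2", "K3")]
        assert sorted(sub.nodes) == ["K1", "K2", "K3"]

    def test_no_within_class_edges_leaves_members_isolated(self, mixed_records):
        net = build_network([("K1", "X1"), ("K2", "P1")])
        sub = subnetwork_by_class(net, mixed_records, "kinase")
        assert sub.n_edges == 0
        assert sorted(sub.nodes) == ["K1", "K2"]

    def test_unknown_class_raises(self, mixed_records):
        net = build_network([("K1", "K2")])
        with pytest.raises(ValueError, match="ligase"):
            subnetwork_by_class(net, mixed_records, "ligase")

    def test_matches_brute_force_edge_filter(self, rng, mixed_records):
        ids = list(mixed_records["id"])
        edges = [
            (ids[i], ids[j])
            for i in range(len(ids))
            for j in range(len(ids))
            if i != j and rng.random() < 0.4
        ]
        net = build_network(edges, node_universe=ids)
        sub = subnetwork_by_class(net, mixed_records, "kinase")
        kin = set(mixed_records[mixed_records["enzyme_class"] == "kinase"]["id"])
        expected = {(u, v) for u, v in set(edges) if u in kin and v in kin}
        assert set(sub.edges) == expected


class TestLayerAssignment:
    def test_chain_layers_simple(self):
        net = build_network([("A", "B"), ("B", "C")])
        labels = assign_layers_simple(net).labels
        assert labels == {"A": TOP, "B": MID, "C": BOT}

    def test_isolated_nodes_are_outgroup(self):
        net = build_network([], node_universe=["A", "B"])
        assert set(assign_layers_simple(net).labels.values()) == {OUTGROUP}

    def test_chain_is_all_outgroup_under_stringent(self):
        # every degree is <= 1, so no stringent rule fires
        net = build_network([("A", "B"), ("B", "C")])
        assert set(assign_layers_stringent(net).labels.values()) == {OUTGROUP}

    def test_stringent_top_tolerates_one_incoming_edge(self):
        net = build_network([("A", "B"), ("A", "C"), ("D", "A")])
        assert assign_layers_stringent(net)["A"] == TOP

    @pytest.mark.parametrize("scheme", ["simple", "stringent"])
    def test_labels_match_brute_force_degree_oracle(self, rng, scheme):
        """200 random graphs up to 30 nodes against an independent
        classifier that recomputes degrees from the raw edge list."""
        from phosnet.network import assign_layers_simple, assign_layers_stringent

        assign = {"simple": assign_layers_simple,
                  "stringent": assign_layers_stringent}[scheme]
        for _ in range(200):
            edges, nodes = random_digraph(rng)
            net = build_network(edges, node_universe=nodes)
            got = assign(net).labels
            assert got == brute_force_layers(edges, nodes, scheme)

    def test_partition_covers_all_nodes(self, rng):
        for _ in range(50):
            edges, nodes = random_digraph(rng)
            net = build_network(edges, node_universe=nodes)
            for assign in (assign_layers_simple, assign_layers_stringent):
                counts = assign(net).counts()
                assert sum(counts.values()) == net.n_nodes

    def test_scheme_nesting(self, rng):
        """Stringent TOP implies simple TOP or MID; stringent BOT implies
        simple BOT or MID (thresholds only tighten)."""
        for _ in range(50):
            edges, nodes = random_digraph(rng)
            net = build_network(edges, node_universe=nodes)
            simple = assign_layers_simple(net).labels
            stringent = assign_layers_stringent(net).labels
            for n, label in stringent.items():
                if label == TOP:
                    assert simple[n] in (TOP, MID)
                elif label == BOT:
                    assert simple[n] in (BOT, MID)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown layer"):
            LayerAssignment({"A": "SIDEWAYS"}, "simple")


class TestRestrictToMeasured:
    def test_full_measured_set_is_identity(self):
        net = build_network([("A", "B"), ("B", "C")])
        restricted = restrict_to_measured(net, ["A", "B", "C"])
        assert sorted(restricted.edges) == sorted(net.edges)

    def test_unmeasured_node_removed_with_its_edges(self):
        net = build_network([("A", "B"), ("B", "C")])
        restricted = restrict_to_measured(net, ["B", "C"])
        assert "A" not in restricted
        assert restricted.edges == [("B", "C")]

    def test_assignment_restriction_equals_set_intersection(self, rng):
        edges, nodes = random_digraph(rng)
        net = build_network(edges, node_universe=nodes)
        assign = assign_layers_simple(net)
        measured = [n for n in nodes if rng.random() < 0.6] or nodes[:1]
        restricted = restrict_to_measured(assign, measured)
        assert set(restricted.labels) == set(nodes) & set(measured)
        assert all(restricted.labels[n] == assign.labels[n]
                   for n in restricted.labels)

    def test_empty_intersection_raises(self):
        net = build_network([("A", "B")])
        with pytest.raises(ValueError):
            restrict_to_measured(net, ["Z"])


class TestPhosphatasePlacement:
    @pytest.fixture
    def records(self):
        return pd.DataFrame(
            {
                "id": ["K1", "K2", "K3", "P1", "P2", "P3"],
                "enzyme_class": ["kinase"] * 3 + ["phosphatase"] * 3,
            }
        )

    def test_counts_impacted_kinases_per_layer(self, records):
        full = build_network(
            [("K1", "K2"), ("K2", "K3"), ("P1", "K3"), ("P1", "K2"), ("P1", "P2")]
        )
        kin_layers = assign_layers_simple(
            subnetwork_by_class(full, records, "kinase")
        )
        placement = phosphatase_placement(full, kin_layers, records)
        assert placement.loc["P1", "to_BOT"] == 1  # K3
        assert placement.loc["P1", "to_MID"] == 1  # K2
        assert placement.loc["P1", "pp_out"] == 1
        assert not placement.loc["P1", "outgroup"]

    def test_isolated_phosphatase_flagged_outgroup(self, records):
        full = build_network([("K1", "K2")])
        kin_layers = assign_layers_simple(
            subnetwork_by_class(full, records, "kinase")
        )
        placement = phosphatase_placement(full, kin_layers, records)
        assert placement["outgroup"].all()

    def test_dual_annotated_enzyme_rejected(self):
        records = pd.DataFrame(
            {"id": ["E1", "E1"], "enzyme_class": ["kinase", "phosphatase"]}
        )
        full = build_network([("E1", "E1"), ("E1", "X")])
        with pytest.raises(ValueError):
            phosphatase_placement(full, LayerAssignment({}, "simple"), records)

    def test_matches_brute_force_edge_tally(self, rng, records):
        ids = list(records["id"])
        edges = list(
            {
                (ids[i], ids[j])
                for i in range(len(ids))
                for j in range(len(ids))
                if i != j and rng.random() < 0.5
            }
        )
        full = build_network(edges, node_universe=ids)
        kin_layers = assign_layers_simple(
            subnetwork_by_class(full, records, "kinase")
        )
        placement = phosphatase_placement(full, kin_layers, records)
        kin = {"K1", "K2", "K3"}
        for p in ("P1", "P2", "P3"):
            expect_from_kin = sum(1 for u, v in edges if v == p and u in kin)
            expect_to_kin = sum(1 for u, v in edges if u == p and v in kin)
            got_to_kin = sum(
                placement.loc[p, f"to_{layer}"] for layer in LAYERS
            )
            assert placement.loc[p, "from_kinase"] == expect_from_kin
            assert got_to_kin == expect_to_kin


class TestLayerRecovery:
    def test_identical_assignments_give_one(self):
        a = LayerAssignment({"A": TOP, "B": BOT}, "simple")
        assert layer_recovery(a, a) == 1.0

    def test_fully_permuted_labels_give_zero(self):
        truth = LayerAssignment({"A": TOP, "B": BOT}, "planted")
        wrong = LayerAssignment({"A": BOT, "B": TOP}, "simple")
        assert layer_recovery(truth, wrong) == 0.0

    def test_node_set_mismatch_raises(self):
        a = LayerAssignment({"A": TOP}, "planted")
        b = LayerAssignment({"B": TOP}, "simple")
        with pytest.raises(ValueError, match="node sets"):
            layer_recovery(a, b)


class TestExport:
    def test_round_trip_through_readers(self, tmp_path):
        from phosnet.io import read_edge_list

        net = build_network([("A", "B", "screen1"), ("B", "C")])
        layers = assign_layers_simple(net)
        export_attributed_network(
            net, layers, {"A": 5, "B": 2, "C": 0},
            tmp_path / "edges.tsv", tmp_path / "nodes.tsv",
        )
        edges = read_edge_list(tmp_path / "edges.tsv")
        assert build_network(edges).edges == net.edges
        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
        assert list(nodes["id"]) == ["A", "B", "C"]
        assert list(nodes["impact_breadth"]) == [5, 2, 0]
        assert list(nodes["layer"]) == [TOP, MID, BOT]

    def test_empty_network_writes_headers_only(self, tmp_path):
        net = build_network([], node_universe=["A"])
        export_attributed_network(
            net, assign_layers_simple(net), {},
            tmp_path / "e.tsv", tmp_path / "n.tsv",
        )
        assert pd.read_csv(tmp_path / "e.tsv", sep="\t").empty
        assert len(pd.read_csv(tmp_path / "n.tsv", sep="\t")) == 1
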