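"""Network data model, symbol normalization, and assembly operations."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from regmotif import (
    MirnaTargetRecord,
    RegulatoryNetwork,
    ValidationError,
    annotate_tfs,
    canonical_symbol,
    degree_summary,
    extract_focal_subnetwork,
    generate_random_network,
    integrate_mirna_targets,
    merge_networks,
)


class TestSymbols:
    @pytest.mark.parametrize(
        "raw, key",
        [
            ("sox10", "SOX10"),
            ("MITF", "MITF"),
            ("miR-155", "MIR155"),
            ("MIR155", "MIR155"),
            ("hsa-miR-155", "MIR155"),
            ("miR-155-5p", "MIR1555P"),
            ("let-7c", "LET7C"),
        ],
    )
    def test_canonicalization(self, raw, key):
        assert canonical_symbol(raw) == key

    def test_mir155_spellings_collapse_to_one_node(self):
        net = RegulatoryNetwork()
        net.add_node("miR-155", "MIRNA")
        net.add_node("MIR155", "MIRNA", {"db"})
        assert net.n_nodes == 1
        # first-seen miRNA spelling is kept for display
        assert net.node("MIR155").symbol == "miR-155"
        assert net.node("mir155").origins == {"db"}

    def test_empty_symbol_rejected(self):
        with pytest.raises(ValidationError):
            canonical_symbol("   ")

    @given(st.sampled_from(["SOX10", "miR-155", "hsa-let-7c", "Atf2", "GENE001"]))
    def test_canonicalization_idempotent(self, symbol):
        assert canonical_symbol(canonical_symbol(symbol)) == canonical_symbol(symbol)


class TestEdges:
    def test_self_loop_rejected_by_default(self):
        net = RegulatoryNetwork()
        net.add_node("SOX10", "TF")
        with pytest.raises(ValidationError):
            net.add_edge("SOX10", "SOX10", 1)

    def test_self_loop_allowed_when_opted_in(self):
        net = RegulatoryNetwork(allow_self_loops=True)
        net.add_node("SOX10", "TF")
        net.add_edge("SOX10", "SOX10", 1)
        assert net.n_edges == 1

    def test_mirna_source_forces_post_transcriptional(self, ffl_fixture):
        with pytest.raises(ValidationError):
            ffl_fixture.add_edge("miR-155", "SOX10", -1, "transcriptional")
        # default mechanism for a miRNA source is post-transcriptional
        e = ffl_fixture.add_edge("miR-155", "SOX10", -1)
        assert e.mechanism == "post_transcriptional"

    def test_duplicate_edge_unions_provenance_and_evidence(self):
        net = RegulatoryNetwork()
        net.add_node("SOX10", "TF")
        net.add_node("MITF", "TF")
        net.add_edge("SOX10", "MITF", 1, provenance={"a"}, evidence="chip")
        e = net.add_edge("SOX10", "MITF", 1, provenance={"b"}, evidence="luciferase")
        assert net.n_edges == 1
        assert e.provenance == {"a", "b"}
        assert e.evidence == "chip; luciferase"

    def test_duplicate_edge_with_conflicting_sign_rejected(self):
        net = RegulatoryNetwork()
        net.add_node("SOX10", "TF")
        net.add_node("MITF", "TF")
        net.add_edge("SOX10", "MITF", 1)
        with pytest.raises(ValidationError):
            net.add_edge("SOX10", "MITF", -1)

    def test_parallel_mechanisms_are_distinct_edges(self):
        net = RegulatoryNetwork()
        net.add_node("A", "TF")
        net.add_node("B", "TF")
        net.add_edge("A", "B", 1, "transcriptional")
        net.add_edge("A", "B", -1, "post_transcriptional")
        assert net.n_edges == 2


class TestMerge:
    def _pair(self):
        n1 = RegulatoryNetwork("n1")
        n1.add_node("SOX10", "TF")
        n1.add_node("MITF", "TF")
        n1.add_edge("SOX10", "MITF", 1)
        n2 = RegulatoryNetwork("n2")
        n2.add_node("SOX10", "TF")
        n2.add_node("PAX3", "TF")
        n2.add_edge("PAX3", "SOX10", 1)
        return n1, n2

    def test_disjoint_union(self):
        a = RegulatoryNetwork()
        a.add_node("A", "TF"), a.add_node("B", "PCG")
        a.add_edge("A", "B", 1)
        b = RegulatoryNetwork()
        b.add_node("C", "TF"), b.add_node("D", "PCG")
        b.add_edge("C", "D", -1)
        merged = merge_networks([a, b], ["x", "y"])
        assert merged.n_nodes == 4 and merged.n_edges == 2
        assert all(len(n.origins) == 1 for n in merged.nodes.values())

    def test_shared_node_gets_both_origins(self):
        n1, n2 = self._pair()
        merged = merge_networks([n1, n2], ["melanoma", "pluripotency"])
        assert merged.node("SOX10").origins == {"melanoma", "pluripotency"}
        assert merged.node("MITF").origins == {"melanoma"}

    def test_merge_idempotent_up_to_origin_collapse(self):
        n1, _ = self._pair()
        merged = merge_networks([n1, n1], ["a", "a"])
        reference = merge_networks([n1], ["a"])
        assert merged == reference

    def test_merge_commutative(self):
        n1, n2 = self._pair()
        ab = merge_networks([n1, n2], ["a", "b"])
        ba = merge_networks([n2, n1], ["b", "a"])
        assert ab == ba

    def test_class_conflict_resolved_by_priority(self):
        n1 = RegulatoryNetwork()
        n1.add_node("MITF", "PCG")
        n2 = RegulatoryNetwork()
        n2.add_node("MITF", "TF")
        merged = merge_networks([n1, n2], ["a", "b"])
        assert merged.node("MITF").node_class == "TF"

    def test_class_conflict_without_policy_raises(self):
        n1 = RegulatoryNetwork()
        n1.add_node("MITF", "PCG")
        n2 = RegulatoryNetwork()
        n2.add_node("MITF", "TF")
        with pytest.raises(ValidationError, match="MITF"):
            merge_networks([n1, n2], ["a", "b"], node_class_policy=None)


class TestEgo:
    def test_radius1_of_ffl_fixture_is_whole_fixture(self, ffl_fixture):
        sub = extract_focal_subnetwork(ffl_fixture, "SOX10", 1)
        assert sub == ffl_fixture

    def test_radius0_is_single_node(self, ffl_fixture):
        sub = extract_focal_subnetwork(ffl_fixture, "SOX10", 0)
        assert sub.n_nodes == 1 and sub.n_edges == 0

    def test_isolated_focal(self):
        net = RegulatoryNetwork()
        net.add_node("LONER", "PCG")
        sub = extract_focal_subnetwork(net, "LONER", 1)
        assert sub.n_nodes == 1 and sub.n_edges == 0

    def test_absent_focal_raises_lookup_error(self, ffl_fixture):
        with pytest.raises(KeyError):
            extract_focal_subnetwork(ffl_fixture, "NOPE")

    def test_induced_subgraph_keeps_neighbor_neighbor_edges(self, melanoma_net):
        # the miR-155 -| MITF edge runs between two SOX10 neighbors and
        # must survive the radius-1 extraction
        sub = extract_focal_subnetwork(melanoma_net, "SOX10", 1)
        assert ("MIR155", "MITF", "post_transcriptional") in sub.edges

    @pytest.mark.parametrize("seed", range(5))
    def test_node_set_monotone_in_radius(self, seed):
        net = generate_random_network(5, 3, 8, 0.12, seed=seed)
        focal = sorted(net.nodes)[0]
        previous = set()
        for radius in range(5):
            nodes = set(extract_focal_subnetwork(net, focal, radius).nodes)
            assert previous <= nodes
            previous = nodes

    def test_large_radius_reaches_weak_component(self):
        net = generate_random_network(4, 2, 4, 0.3, seed=11)
        focal = sorted(net.nodes)[0]
        ego = set(extract_focal_subnetwork(net, focal, 50).nodes)
        # independent weak-component computation
        import networkx as nx

        g = net.to_networkx().to_undirected()
        component = nx.node_connected_component(g, focal)
        assert ego == component


class TestMirnaIntegration:
    def test_adds_node_and_repressive_edge(self, ffl_fixture):
        out = integrate_mirna_targets(
            ffl_fixture,
            [MirnaTargetRecord("miR-204", "SOX10", "luciferase assay")],
        )
        assert "miR-204" in out
        e = out.edges[("MIR204", "SOX10", "post_transcriptional")]
        assert e.sign == -1 and "luciferase assay" in e.evidence

    def test_absent_target_skipped_when_restricted(self, ffl_fixture):
        out = integrate_mirna_targets(
            ffl_fixture, [MirnaTargetRecord("miR-9", "NOTTHERE")],
        )
        assert out == ffl_fixture

    def test_absent_target_added_when_unrestricted(self, ffl_fixture):
        out = integrate_mirna_targets(
            ffl_fixture,
            [MirnaTargetRecord("miR-9", "NEWGENE")],
            restrict_to_existing=False,
        )
        assert "NEWGENE" in out and "miR-9" in out

    def test_duplicate_records_concatenate_evidence(self, ffl_fixture):
        out = integrate_mirna_targets(
            ffl_fixture,
            [
                MirnaTargetRecord("miR-204", "SOX10", "qPCR"),
                MirnaTargetRecord("miR-204", "SOX10", "western_blot"),
            ],
        )
        e = out.edges[("MIR204", "SOX10", "post_transcriptional")]
        assert out.n_edges == ffl_fixture.n_edges + 1
        assert "qPCR" in e.evidence and "western_blot" in e.evidence

    def test_empty_field_rejected(self, ffl_fixture):
        with pytest.raises(ValidationError):
            integrate_mirna_targets(ffl_fixture, [MirnaTargetRecord(" ", "SOX10")])

    def test_never_creates_transcriptional_mirna_edge(self, ffl_fixture):
        out = integrate_mirna_targets(
            ffl_fixture,
            [MirnaTargetRecord(f"miR-{i}", "MITF") for i in range(1, 6)],
        )
        for (src, _t, mech), _e in out.edges.items():
            if out.nodes[src].node_class == "MIRNA":
                assert mech == "post_transcriptional"


class TestAnnotateTfs:
    def test_fixture_annotation(self, melanoma_net):
        out = annotate_tfs(melanoma_net, {"SOX10", "MITF", "ATF2"})
        assert out.node("SOX10").node_class == "TF"
        assert out.node("miR-204").node_class == "MIRNA"

    def test_empty_list_makes_all_non_mirnas_pcg(self, melanoma_net):
        out = annotate_tfs(melanoma_net, set())
        classes = {n.node_class for n in out.nodes.values()}
        assert classes == {"PCG", "MIRNA"}

    def test_mirna_in_tf_list_is_ignored(self, melanoma_net):
        out = annotate_tfs(melanoma_net, {"miR-155"})
        assert out.node("miR-155").node_class == "MIRNA"


class TestDegreeSummary:
    def test_ffl_fixture_degrees(self, ffl_fixture):
        frame = degree_summary(ffl_fixture).set_index("symbol")
        assert frame.loc["SOX10", "total_degree"] == 2
        assert frame.loc["MITF", "total_degree"] == 2
        assert frame.loc["miR-155", "total_degree"] == 2

    def test_isolated_node_degree_zero(self):
        net = RegulatoryNetwork()
        net.add_node("X", "PCG")
        frame = degree_summary(net)
        assert frame.iloc[0]["total_degree"] == 0

    def test_star_hub(self):
        net = RegulatoryNetwork()
        net.add_node("HUB", "TF")
        for i in range(5):
            net.add_node(f"T{i}", "PCG")
            net.add_edge("HUB", f"T{i}", 1)
        frame = degree_summary(net)
        assert frame.iloc[0]["symbol"] == "HUB"
        assert frame.iloc[0]["total_degree"] == 5

    @pytest.mark.parametrize("seed", range(4))
    def test_degrees_sum_to_twice_edge_count(self, seed):
        net = generate_random_network(6, 3, 8, 0.15, seed=seed)
        frame = degree_summary(net)
        assert frame["total_degree"].sum() == 2 * net.n_edges
        assert (frame["total_degree"] == frame["in_degree"] + frame["out_degree"]).all()
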