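"""Graph model, matrix/edge-list/GraphML I/O, and symmetry-map derivation."""

import numpy as np
import pytest

from cranionet import (
    AnatomicalNetwork,
    DataError,
    NamingConvention,
    NodeRecord,
    SymmetryMap,
    builtin_head_network,
    derive_symmetry_map,
    read_adjacency_matrix,
    read_edge_list,
    read_graphml,
    read_symmetry_csv,
    write_network,
    write_symmetry_csv,
)


def write_matrix(tmp_path, text, name="m.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadAdjacencyMatrix:
    def test_all_zero_matrix_gives_edgeless_network(self, tmp_path):
        net, report = read_adjacency_matrix(write_matrix(tmp_path, "0,0,0\n0,0,0\n0,0,0\n"))
        assert (net.n, net.m) == (3, 0)
        assert report.asymmetric_cells == [] and report.nonzero_diagonal == []

    def test_blank_cells_read_as_zero(self, tmp_path):
        net, _ = read_adjacency_matrix(write_matrix(tmp_path, ",1,\n1,,\n,,\n"))
        assert net.m == 1 and net.has_edge(1, 2)

    def test_union_policy_keeps_one_sided_edge_and_reports_it(self, tmp_path):
        net, report = read_adjacency_matrix(write_matrix(tmp_path, "0,1\n0,0\n"))
        assert net.m == 1
        assert report.asymmetric_cells == [(1, 2)]

    def test_intersection_policy_drops_one_sided_edge(self, tmp_path):
        net, report = read_adjacency_matrix(
            write_matrix(tmp_path, "0,1\n0,0\n"), policy="intersection"
        )
        assert net.m == 0
        assert report.asymmetric_cells == [(1, 2)]

    def test_strict_policy_refuses_asymmetry(self, tmp_path):
        with pytest.raises(DataError, match="strict"):
            read_adjacency_matrix(write_matrix(tmp_path, "0,1\n0,0\n"), policy="strict")

    def test_nonzero_diagonal_zeroed_and_reported(self, tmp_path):
        net, report = read_adjacency_matrix(write_matrix(tmp_path, "1,1\n1,0\n"))
        assert net.m == 1
        assert report.nonzero_diagonal == [1]

    def test_labeled_header_row_and_column(self, tmp_path):
        text = ",a,b\na,0,1\nb,1,0\n"
        net, _ = read_adjacency_matrix(write_matrix(tmp_path, text))
        assert net.names == ("a", "b") and net.has_edge(1, 2)

    def test_tab_separated_input(self, tmp_path):
        net, _ = read_adjacency_matrix(write_matrix(tmp_path, "0\t1\n1\t0\n"))
        assert net.m == 1

    @pytest.mark.parametrize(
        "text,match",
        [
            ("0,1\n", "square"),
            ("0,2\n2,0\n", "must be 0, 1 or blank"),
            (",a,a\na,0,1\na,1,0\n", "duplicate"),
        ],
    )
    def test_malformed_inputs_rejected(self, tmp_path, text, match):
        with pytest.raises(DataError, match=match):
            read_adjacency_matrix(write_matrix(tmp_path, text))

    def test_missing_file_is_a_data_error(self, tmp_path):
        with pytest.raises(DataError, match="not found"):
            read_adjacency_matrix(tmp_path / "absent.csv")

    @pytest.mark.parametrize("triangle", ["upper", "lower", "both"])
    def test_union_edges_independent_of_populated_triangle(self, tmp_path, triangle):
        full = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (0, 3)]:
            if triangle in ("upper", "both"):
                full[i, j] = 1
            if triangle in ("lower", "both"):
                full[j, i] = 1
        text = "\n".join(",".join(str(x) for x in row) for row in full) + "\n"
        net, _ = read_adjacency_matrix(write_matrix(tmp_path, text))
        assert sorted(net.edges()) == [(1, 2), (1, 4), (2, 3)]


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["matrix_csv", "edge_list", "graphml"])
    def test_read_write_identity_on_builtin_network(self, tmp_path, fmt, head):
        net, _ = head
        path = tmp_path / f"net.{fmt}"
        write_network(net, path, format=fmt)
        if fmt == "matrix_csv":
            back, _ = read_adjacency_matrix(path)
        elif fmt == "edge_list":
            back = read_edge_list(path)
        else:
            back = read_graphml(path)
        assert back.n == 39
        assert net.same_topology(back)

    def test_edge_list_preserves_isolated_nodes(self, tmp_path):
        net = AnatomicalNetwork.from_edges(["a", "b", "c"], [("a", "b")])
        path = tmp_path / "net.edges"
        write_network(net, path, format="edge_list")
        assert path.read_text().count("\n") == 2  # one edge record + one isolate
        assert net.same_topology(read_edge_list(path))

    def test_graphml_carries_node_metadata(self, tmp_path, head):
        net, _ = head
        path = tmp_path / "net.graphml"
        write_network(net, path, format="graphml")
        back = read_graphml(path)
        rec = back.node(back.id_of("Maxilla left"))
        assert rec.node_class == "skeletal"
        assert rec.laterality == "left"
        assert back.name_of(rec.mirror_id) == "Maxilla right"

    def test_unknown_format_rejected(self, tmp_path, head):
        with pytest.raises(DataError, match="format"):
            write_network(head[0], tmp_path / "x", format="dot")


class TestBuiltinHeadNetwork:
    def test_node_counts_match_the_published_model(self, head):
        net, _ = head
        assert net.n == 39
        classes = [rec.node_class for rec in net.nodes]
        assert classes.count("central_nervous") == 12
        assert classes.count("skeletal") == 27

    def test_degree_sum_is_even_and_twice_edge_count(self, head):
        net, _ = head
        assert net.degrees.sum() % 2 == 0
        assert net.degrees.sum() == 2 * net.m

    def test_symmetry_map_has_14_pairs_11_axis_and_covers_all_nodes(self, head):
        net, sym = head
        assert len(sym.pairs) == 14
        assert len(sym.axis_ids) == 11
        assert sym.covered_ids() == frozenset(range(1, 40))

    def test_mirror_involution_is_a_graph_automorphism(self, head):
        net, sym = head
        mu = sym.mirror
        A = np.asarray(net.adjacency)
        perm = np.array([mu[i] - 1 for i in range(1, net.n + 1)])
        assert (A[np.ix_(perm, perm)] == A).all()

    def test_derived_symmetry_map_matches_packaged_metadata(self, head):
        net, sym = head
        assert derive_symmetry_map(net) == sym


class TestDeriveSymmetryMap:
    def test_suffix_marked_pair_and_axis_node(self):
        net = AnatomicalNetwork.from_edges(
            ["A left", "A right", "B"], [("A left", "B")]
        )
        sym = derive_symmetry_map(net)
        assert sym.pairs == ((1, 2),) and sym.axis_ids == frozenset({3})

    def test_no_side_markers_gives_all_axis(self):
        net = AnatomicalNetwork.from_edges(["B", "C"], [("B", "C")])
        sym = derive_symmetry_map(net)
        assert sym.pairs == () and sym.axis_ids == frozenset({1, 2})

    def test_unmatched_side_marked_node_is_an_error(self):
        net = AnatomicalNetwork.from_edges(["A.left", "B"], [("A.left", "B")])
        with pytest.raises(DataError, match="counterpart"):
            derive_symmetry_map(net)

    def test_prefix_and_suffix_conventions_both_recognized(self):
        net = AnatomicalNetwork.from_edges(
            ["Left brain", "Right brain", "Bone left", "Bone right"],
            [("Left brain", "Bone left")],
        )
        assert derive_symmetry_map(net).pairs == ((1, 2), (3, 4))

    def test_custom_convention(self):
        net = AnatomicalNetwork.from_edges(["xL", "xR"], [("xL", "xR")])
        conv = NamingConvention(
            left_patterns=(r"L$",), right_patterns=(r"R$",)
        )
        assert derive_symmetry_map(net, conv).pairs == ((1, 2),)


class TestSymmetryMapStructure:
    def test_node_in_two_pairs_rejected(self):
        with pytest.raises(DataError, match="more than once"):
            SymmetryMap(((1, 2), (2, 3)), frozenset())

    def test_pair_overlapping_axis_rejected(self):
        with pytest.raises(DataError, match="more than once"):
            SymmetryMap(((1, 2),), frozenset({2}))

    def test_validate_requires_exact_cover(self, head):
        net, _ = head
        with pytest.raises(DataError, match="covers"):
            SymmetryMap((), frozenset({1})).validate(net)

    def test_symmetry_csv_round_trip(self, tmp_path, head):
        net, sym = head
        path = tmp_path / "sym.csv"
        write_symmetry_csv(sym, net, path)
        assert read_symmetry_csv(path, net) == sym


class TestNodeRecordInvariants:
    def test_sided_node_requires_mirror(self):
        with pytest.raises(DataError, match="inconsistent"):
            NodeRecord(1, "x", laterality="left")

    def test_midline_node_rejects_mirror(self):
        with pytest.raises(DataError, match="inconsistent"):
            NodeRecord(1, "x", laterality="midline", mirror_id=2)

    def test_network_rejects_broken_involution(self):
        nodes = [
            NodeRecord(1, "a", laterality="left", mirror_id=2),
            NodeRecord(2, "b", laterality="right", mirror_id=3),
            NodeRecord(3, "c", laterality="left", mirror_id=2),
        ]
        with pytest.raises(DataError, match="involution"):
            AnatomicalNetwork(nodes, np.zeros((3, 3), dtype=int))

    def test_network_rejects_asymmetric_or_loopy_adjacency(self):
        nodes = [NodeRecord(1, "a"), NodeRecord(2, "b")]
        with pytest.raises(DataError, match="symmetric"):
            AnatomicalNetwork(nodes, np.array([[0, 1], [0, 0]]))
        with pytest.raises(DataError, match="diagonal"):
            AnatomicalNetwork(nodes, np.array([[1, 0], [0, 0]]))
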