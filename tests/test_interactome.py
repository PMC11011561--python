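import math
from collections import deque

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmoa.interactome import (
    ConflictError,
    FormatError,
    Interactome,
    extract_disease_subnetwork,
    read_edge_list,
    shortest_path_hops,
    write_edge_list,
)


def build(edges, nodes=()):
    net = Interactome()
    for n in nodes:
        net.add_node(n)
    for u, v, s in edges:
        net.add_edge(u, v, s)
    return net


class TestReadEdgeList:
    def test_tsv_tokens(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("VEGFA\tactivates\tKDR\nKDR\tinhibits\tTJP1\nA\t+1\tB\nB\t-1\tC\n")
        net = read_edge_list(str(p))
        assert ("VEGFA", "KDR", 1) in net.edges
        assert ("KDR", "TJP1", -1) in net.edges
        assert net.sign("A", "B") == 1 and net.sign("B", "C") == -1

    def test_sif_dialect_multiple_targets(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A activates B C\nB inhibits D\n")
        net = read_edge_list(str(p), dialect="sif")
        assert net.edges == {("A", "B", 1), ("A", "C", 1), ("B", "D", -1)}

    def test_unknown_token_names_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tactivates\tB\nA\t?\tC\n")
        with pytest.raises(FormatError, match=r":2"):
            read_edge_list(str(p))

    def test_conflicting_signs_error(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tactivates\tB\nA\tinhibits\tB\n")
        with pytest.raises(ConflictError):
            read_edge_list(str(p))

    def test_duplicate_identical_records_deduplicated(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tactivates\tB\nA\tactivates\tB\n")
        net = read_edge_list(str(p))
        assert net.n_edges == 1

    def test_isolated_node_header(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("#node LONELY\nA\tactivates\tB\n")
        net = read_edge_list(str(p))
        assert "LONELY" in net.nodes

    def test_roundtrip_preserves_nodes_and_edges(self, tmp_path):
        net = build(
            [("A", "B", 1), ("B", "C", -1), ("C", "A", 1)], nodes=["ISOLATED"]
        )
        for dialect in ("tsv", "sif"):
            p = tmp_path / f"rt.{dialect}"
            write_edge_list(net, str(p), dialect=dialect)
            back = read_edge_list(str(p), dialect=dialect)
            assert back == net


class TestInvariants:
    def test_self_loop_rejected(self):
        net = Interactome()
        with pytest.raises(ValueError, match="self-loop"):
            net.add_edge("A", "A", 1)

    def test_bad_sign_rejected(self):
        net = Interactome()
        with pytest.raises(ValueError):
            net.add_edge("A", "B", 0)


class TestSubnetwork:
    def test_one_hop_closure(self):
        net = build([("A", "B", 1), ("B", "C", 1)])
        sub, ann = extract_disease_subnetwork(net, {"A"})
        assert sub.nodes == {"A", "B"}
        assert sub.edges == {("A", "B", 1)}
        assert ann.set_index("protein")["is_effector"].to_dict() == {
            "A": True,
            "B": False,
        }

    def test_all_nodes_identity(self):
        net = build([("A", "B", 1), ("B", "C", -1)])
        sub, _ = extract_disease_subnetwork(net, net.nodes)
        assert sub == net

    def test_star_leaf_effector(self):
        net = build([("h", f"l{i}", 1) for i in range(1, 6)])
        sub, _ = extract_disease_subnetwork(net, {"l1"})
        assert sub.nodes == {"l1", "h"}

    def test_missing_effector_reported(self):
        net = build([("A", "B", 1)])
        with pytest.raises(KeyError, match="NOPE"):
            extract_disease_subnetwork(net, {"A", "NOPE"})

    def test_empty_effectors_error(self):
        net = build([("A", "B", 1)])
        with pytest.raises(ValueError):
            extract_disease_subnetwork(net, set())

    def test_every_noneffector_touches_an_effector(self):
        # property on a random-ish graph
        edges = [("A", "B", 1), ("B", "C", 1), ("C", "D", -1), ("D", "E", 1), ("B", "E", 1)]
        net = build(edges)
        sub, ann = extract_disease_subnetwork(net, {"C"})
        effectors = {"C"}
        for protein in sub.nodes - effectors:
            assert any(
                (protein in (u, v)) and (other in effectors)
                for u, v, _ in sub.edges
                for other in (u, v)
            )


def _bfs_oracle(adj, a, b):
    """Hand-rolled BFS hop count, independent of networkx."""
    if a == b:
        return 0
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        node, d = frontier.popleft()
        for nxt in adj[node]:
            if nxt == b:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    return math.inf


class TestShortestPathHops:
    def test_identity_and_disconnected(self):
        net = build([("A", "B", 1)], nodes=["Z"])
        assert shortest_path_hops(net, "A", "A") == 0
        assert shortest_path_hops(net, "A", "Z") == math.inf

    def test_two_hop_chain(self):
        net = build([("A", "B", 1), ("B", "C", 1)])
        assert shortest_path_hops(net, "A", "C") == 2

    def test_direction_ignored(self):
        net = build([("B", "A", 1), ("B", "C", 1)])
        assert shortest_path_hops(net, "A", "C") == 2

    def test_unknown_protein(self):
        net = build([("A", "B", 1)])
        with pytest.raises(KeyError):
            shortest_path_hops(net, "A", "Q")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 7), st.integers(0, 7)), min_size=1, max_size=15))
    def test_matches_bfs_oracle_symmetric_triangle(self, pairs):
        net = Interactome()
        for i in range(8):
            net.add_node(f"n{i}")
        for u, v in pairs:
            if u != v:
                net.add_edge(f"n{u}", f"n{v}", 1)
        adj = {n: set() for n in net.nodes}
        for u, v, _ in net.edges:
            adj[u].add(v)
            adj[v].add(u)
        names = sorted(net.nodes)
        for a in names:
            for b in names:
                d = shortest_path_hops(net, a, b)
                assert d == _bfs_oracle(adj, a, b)
                assert d == shortest_path_hops(net, b, a)
        # triangle inequality on finite distances
        for a in names:
            for b in names:
                for c in names:
                    dab = shortest_path_hops(net, a, b)
                    dbc = shortest_path_hops(net, b, c)
                    dac = shortest_path_hops(net, a, c)
                    if math.isfinite(dab) and math.isfinite(dbc):
                        assert dac <= dab + dbc
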