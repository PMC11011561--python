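import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmoa.enrichment import (
    ProteinSet,
    ProteinSetCollection,
    enrichment_network,
    graph_hop_metric,
    hausdorff_distance,
    hypergeometric_p,
    read_gmt,
    run_enrichment,
    select_foreground,
    write_gmt,
)
from netmoa.interactome import Interactome


def enumeration_oracle(k, n, K, N):
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    population = list(range(N))
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestSelectForeground:
    def test_threshold_strict(self):
        prof = {"A": 0.9, "B": -0.85, "C": 0.3, "D": 0.8}
        assert select_foreground(prof, 0.8) == {"A", "B"}  # 0.8 itself excluded

    def test_all_zero(self):
        assert select_foreground({"A": 0.0, "B": 0.0}) == set()


class TestHypergeometricP:
    def test_exact_small_cases(self):
        assert hypergeometric_p(5, 5, 5, 10) == pytest.approx(1 / 252)
        assert hypergeometric_p(0, 3, 4, 10) == 1.0
        assert hypergeometric_p(1, 2, 2, 4) == pytest.approx(5 / 6)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeometric_p(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_p(1, 2, 11, 10)

    def test_matches_enumeration_oracle(self):
        for N in range(2, 13, 2):
            for K in range(1, N + 1, 3):
                for n in range(1, N + 1, 3):
                    for k in range(0, min(n, K) + 1):
                        assert hypergeometric_p(k, n, K, N) == pytest.approx(
                            enumeration_oracle(k, n, K, N), abs=1e-12
                        )


def bh_reference(pvalues):
    """Hand-rolled Benjamini–Hochberg step-up q-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvalues[i] * m / rank)
        q[i] = prev
    return q


class TestRunEnrichment:
    def collection(self):
        background = frozenset(f"P{i}" for i in range(100))
        sets = {
            "tiny": ProteinSet("tiny", "too small", frozenset(f"P{i}" for i in range(5))),
            "hit": ProteinSet("hit", "the signal", frozenset(f"P{i}" for i in range(10))),
            "other": ProteinSet(
                "other", "background-ish", frozenset(f"P{i}" for i in range(40, 90))
            ),
        }
        return ProteinSetCollection(sets=sets, background=background)

    def test_size_filter_applied_before_testing(self):
        results = run_enrichment({"P1", "P2"}, self.collection(), min_size=10, max_size=200)
        assert "tiny" not in {r.set_id for r in results}

    def test_single_full_set_closed_form(self):
        coll = ProteinSetCollection(
            sets={"s": ProteinSet("s", "s", frozenset(f"P{i}" for i in range(10)))},
            background=frozenset(f"P{i}" for i in range(100)),
        )
        foreground = {f"P{i}" for i in range(10)}
        [res] = run_enrichment(foreground, coll)
        expected = 1 / math.comb(100, 10)
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.q_value == pytest.approx(expected, rel=1e-9)
        assert res.significant

    def test_insignificant_sets_stay_in_table(self):
        results = run_enrichment(
            {"P0", "P41", "P50"}, self.collection(), q_threshold=0.001
        )
        ids = {r.set_id for r in results}
        assert "other" in ids
        assert not all(r.significant for r in results)

    def test_foreground_must_be_in_background(self):
        with pytest.raises(ValueError):
            run_enrichment({"NOT_THERE"}, self.collection())

    def test_empty_foreground_warns(self):
        with pytest.warns(UserWarning):
            assert run_enrichment(set(), self.collection()) == []

    def test_bh_matches_reference_and_order_invariance(self):
        rng = np.random.default_rng(0)
        pvals = list(rng.uniform(0, 1, 20))
        from statsmodels.stats.multitest import multipletests

        _, q_lib, _, _ = multipletests(pvals, method="fdr_bh")
        assert list(q_lib) == pytest.approx(bh_reference(pvals))
        perm = rng.permutation(20)
        _, q_perm, _, _ = multipletests([pvals[i] for i in perm], method="fdr_bh")
        for i, j in enumerate(perm):
            assert q_perm[i] == pytest.approx(q_lib[j])


def chain_net(names):
    net = Interactome()
    for a, b in zip(names, names[1:]):
        net.add_edge(a, b, 1)
    return net


class TestHausdorff:
    def test_identity(self):
        d = lambda a, b: 0.0 if a == b else 1.0
        assert hausdorff_distance({"a", "b"}, {"a", "b"}, d) == 0.0

    def test_singletons(self):
        assert hausdorff_distance({"a"}, {"b"}, lambda a, b: 2.0) == 2.0

    def test_path_graph_case(self):
        net = chain_net(["a", "b", "c"])
        d = graph_hop_metric(net)
        assert hausdorff_distance({"a", "b"}, {"b", "c"}, d) == 1.0

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            hausdorff_distance(set(), {"a"}, lambda a, b: 1.0)

    def test_infinite_for_disconnected(self):
        net = Interactome()
        net.add_edge("a", "b", 1)
        net.add_edge("x", "y", 1)
        d = graph_hop_metric(net)
        assert hausdorff_distance({"a"}, {"x"}, d) == math.inf

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_brute_force_symmetry_triangle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        net = Interactome()
        names = [f"n{i}" for i in range(n)]
        for name in names:
            net.add_node(name)
        for _ in range(2 * n):
            u, v = rng.choice(n, 2, replace=False)
            net.add_edge(names[u], names[v], 1)
        d = graph_hop_metric(net)
        sets = []
        for _ in range(3):
            size = int(rng.integers(1, n))
            sets.append(set(rng.choice(names, size, replace=False)))
        X, Y, Z = sets
        dxy = hausdorff_distance(X, Y, d)
        # brute-force oracle over all pairs
        fwd = max(min(d(x, y) for y in Y) for x in X)
        bwd = max(min(d(x, y) for x in X) for y in Y)
        assert dxy == max(fwd, bwd)
        # symmetry
        assert dxy == hausdorff_distance(Y, X, d)
        # triangle inequality (hop metric is a metric on connected parts)
        dxz = hausdorff_distance(X, Z, d)
        dzy = hausdorff_distance(Z, Y, d)
        if math.isfinite(dxz) and math.isfinite(dzy):
            assert dxy <= dxz + dzy

    def test_adding_near_points_never_increases(self):
        net = chain_net(["a", "b", "c", "d"])
        d = graph_hop_metric(net)
        X = {"a"}
        base = hausdorff_distance(X, {"c"}, d)
        grown = hausdorff_distance(X, {"c", "a"}, d)  # add a point on X itself
        assert grown <= base


class TestEnrichmentNetwork:
    def _results(self, ids):
        from netmoa.enrichment import EnrichmentResult

        return [
            EnrichmentResult(i, i, 3, 5, 10, 100, 0.001, 0.001, True) for i in ids
        ]

    def test_threshold_and_identity(self):
        net = chain_net(["a", "b", "c", "d", "e", "f"])
        coll = ProteinSetCollection(
            sets={
                "s1": ProteinSet("s1", "s1", frozenset({"a", "b"})),
                "s2": ProteinSet("s2", "s2", frozenset({"a", "b"})),
                "s3": ProteinSet("s3", "s3", frozenset({"e", "f"})),
            },
            background=frozenset("abcdef"),
        )
        edges = enrichment_network(
            self._results(["s1", "s2", "s3"]), net, coll, max_distance=1.2
        )
        pairs = {(a, b): d for a, b, d in edges}
        assert pairs[("s1", "s2")] == 0.0  # identical member sets
        assert ("s1", "s3") not in pairs  # distance 3 > 1.2

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(4)
        names = [f"n{i}" for i in range(8)]
        net = Interactome()
        for name in names:
            net.add_node(name)
        for _ in range(12):
            u, v = rng.choice(8, 2, replace=False)
            net.add_edge(names[u], names[v], 1)
        sets = {}
        for i in range(3):
            members = frozenset(rng.choice(names, 3, replace=False))
            sets[f"s{i}"] = ProteinSet(f"s{i}", f"s{i}", members)
        coll = ProteinSetCollection(sets=sets, background=frozenset(names))
        edges = enrichment_network(
            self._results(list(sets)), net, coll, max_distance=math.inf
        )
        d = graph_hop_metric(net)
        for a, b, dist in edges:
            assert dist == hausdorff_distance(
                set(sets[a].members), set(sets[b].members), d
            )
        assert len(edges) == 3  # all pairs present at infinite cutoff


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        coll = ProteinSetCollection(
            sets={
                "GO1": ProteinSet("GO1", "first", frozenset({"A", "B", "C"})),
                "GO2": ProteinSet("GO2", "second", frozenset({"B", "D"})),
            },
            background=frozenset("ABCDE"),
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, str(path))
        back = read_gmt(str(path), background="ABCDE")
        assert back.sets.keys() == coll.sets.keys()
        for k in coll.sets:
            assert back.sets[k].members == coll.sets[k].members

    def test_malformed_record(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_id\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(str(path), background=set())
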