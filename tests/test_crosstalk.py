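"""Union construction, betweenness centrality and the ΔBC statistic."""

from itertools import combinations

import numpy as np
import pytest

from deltabc.crosstalk import (
    CentralityTable,
    betweenness,
    delta_bc,
    induced_union,
    rank_targets,
    union_network,
)
from deltabc.errors import ConsistencyError
from deltabc.network import ProteinNetwork
from deltabc.sampling import SeedList, shortest_path_sample

from _oracles import bfs_distances, brute_betweenness, random_network, to_adj


def net_from(label, edges, nodes=()):
    return ProteinNetwork.from_edges(label, edges, nodes=nodes)


class TestUnion:
    def test_disjoint_networks_add_up(self):
        a = net_from("a", [("x", "y"), ("y", "z")])
        b = net_from("b", [("p", "q")])
        u = union_network(a, b)
        assert u.n_nodes == 5 and u.n_edges == 3 and u.label == "union"

    def test_union_with_self_is_identity(self):
        a = net_from("a", [("x", "y"), ("y", "z"), ("z", "x")])
        u = union_network(a, a)
        assert u.nodes == a.nodes and u.edge_set() == a.edge_set()

    def test_hand_union(self):
        a = net_from("a", [("x", "y"), ("y", "z")])
        b = net_from("b", [("y", "w")])
        u = union_network(a, b)
        assert u.nodes == {"x", "y", "z", "w"}
        assert u.edge_set() == {("x", "y"), ("y", "z"), ("w", "y")}

    def test_induced_union_recovers_background_edges(self):
        bg = net_from("bg", [("x", "y"), ("y", "z"), ("x", "z"), ("z", "w")])
        a = bg.induced({"x", "y"}, "a")
        b = bg.induced({"z", "w"}, "b")
        u = induced_union(bg, a, b)
        # plain union misses x-z; the induced union restores it
        assert ("x", "z") in u.edge_set()
        assert union_network(a, b).edge_set() == {("x", "y"), ("w", "z")}

    def test_induced_union_rejects_stray_nodes(self):
        bg = net_from("bg", [("x", "y")])
        with pytest.raises(ConsistencyError):
            induced_union(bg, net_from("a", [("x", "q")]), bg.induced({"y"}, "b"))


class TestBetweenness:
    def test_path_graph_center(self):
        tab = betweenness(net_from("p3", [("a", "b"), ("b", "c")]))
        assert tab.bc == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_counts_leaf_pairs(self):
        star = net_from("star", [("c", x) for x in "abde"])
        tab = betweenness(star)
        assert tab.bc["c"] == 6.0  # C(4,2)
        assert all(tab.bc[x] == 0.0 for x in "abde")

    def test_cycles_split_credit(self):
        five = net_from("c5", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")])
        assert all(v == pytest.approx(1.0) for v in betweenness(five).bc.values())
        four = net_from("c4", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert all(v == pytest.approx(0.5) for v in betweenness(four).bc.values())

    def test_tiny_networks_all_zero(self):
        assert betweenness(net_from("e", [("a", "b")])).bc == {"a": 0.0, "b": 0.0}

    def test_normalized_scale(self):
        star = net_from("star", [("c", x) for x in "abde"])
        tab = betweenness(star, normalized=True)
        assert tab.normalized
        assert tab.bc["c"] == pytest.approx(1.0)  # 6 / ((5-1)(5-2)/2)

    @pytest.mark.parametrize("instance", range(30))
    def test_matches_geodesic_enumeration_oracle(self, instance):
        rng = np.random.default_rng(2000 + instance)
        n = int(rng.integers(4, 13))
        net = random_network(rng, n, float(rng.uniform(0.15, 0.6)))
        impl = betweenness(net).bc
        oracle = brute_betweenness(to_adj(net))
        assert impl.keys() == oracle.keys()
        for v in oracle:
            assert impl[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_total_bc_equals_sum_of_interior_path_lengths(self):
        """Σ_v BC(v) = Σ_{s<t} (d(s,t) − 1) over reachable pairs: every
        geodesic has exactly d−1 interior nodes, unreachable pairs none."""
        rng = np.random.default_rng(3)
        net = random_network(rng, 10, 0.4)
        adj = to_adj(net)
        nodes = sorted(adj)
        dist = {s: bfs_distances(adj, s) for s in nodes}
        expected = sum(
            dist[s][t] - 1
            for s, t in combinations(nodes, 2)
            if t in dist[s]
        )
        assert sum(betweenness(net).bc.values()) == pytest.approx(expected)


def table(label, bc, normalized=False):
    return CentralityTable(label, dict(bc), normalized)


class TestDeltaBC:
    def test_subtraction_formula(self):
        recs = delta_bc(
            table("union", {"v": 10.0}),
            table("a", {"v": 3.0}),
            table("m", {"v": 2.0}),
        )
        assert recs[0].delta_bc == 5.0 and recs[0].rank == 1

    def test_absent_node_contributes_zero(self):
        recs = delta_bc(
            table("union", {"v": 7.0}),
            table("a", {"v": 7.0}),
            table("m", {}),
        )
        (r,) = recs
        assert r.delta_bc == 0.0
        assert r.bc_mito is None and not r.in_mito and r.in_auto

    def test_self_union_yields_minus_bc(self):
        rng = np.random.default_rng(4)
        a = random_network(rng, 9, 0.3, label="a")
        u = union_network(a, a)
        tab_a = betweenness(a)
        recs = delta_bc(betweenness(u), tab_a, tab_a)
        for r in recs:
            assert r.delta_bc == -tab_a.bc[r.node]

    def test_disjoint_subnetworks_yield_all_zeros(self):
        rng = np.random.default_rng(5)
        a = random_network(rng, 8, 0.35, label="a")
        b_edges = [(f"M{x}", f"M{y}") for x, y in
                   (e for e in random_network(rng, 8, 0.35).edge_set())]
        b = ProteinNetwork.from_edges("b", b_edges)
        u = union_network(a, b)
        recs = delta_bc(betweenness(u), betweenness(a), betweenness(b))
        assert all(r.delta_bc == 0.0 for r in recs)

    def test_normalized_tables_rejected(self):
        with pytest.raises(ConsistencyError):
            delta_bc(
                table("union", {"v": 1.0}, normalized=True),
                table("a", {"v": 0.0}),
                table("m", {"v": 0.0}),
            )

    def test_subnetwork_node_missing_from_union_is_fatal(self):
        with pytest.raises(ConsistencyError):
            delta_bc(
                table("union", {"v": 1.0}),
                table("a", {"v": 0.0, "ghost": 1.0}),
                table("m", {}),
            )


class TestRankTargets:
    def _records(self, deltas):
        return delta_bc(
            table("union", deltas),
            table("a", {k: 0.0 for k in deltas}),
            table("m", {k: 0.0 for k in deltas}),
        )

    def test_lexicographic_tie_break(self):
        recs = self._records({"C": 1.0, "B": 5.0, "A": 5.0})
        top = rank_targets(recs, top_k=2)
        assert [(r.node, r.rank) for r in top] == [("A", 1), ("B", 2)]

    def test_single_record(self):
        (r,) = rank_targets(self._records({"only": 2.0}), top_k=5)
        assert r.rank == 1

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(6)
        deltas = {f"n{i:02d}": float(rng.integers(0, 8)) for i in range(20)}
        ranked = rank_targets(self._records(deltas), top_k=20)
        reference = sorted(deltas.items(), key=lambda kv: (-kv[1], kv[0]))
        assert [r.node for r in ranked] == [k for k, _ in reference]
        assert [r.rank for r in ranked] == list(range(1, 21))

    def test_top_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rank_targets(self._records({"a": 1.0}), top_k=0)

    def test_full_table_written(self, tmp_path):
        path = tmp_path / "ranked.tsv"
        rank_targets(self._records({"A": 1.0, "B": 2.0}), top_k=1, path=path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3  # header + both records, not just top_k
        assert lines[1].startswith("B\t")


class TestBridgeDominance:
    def test_bridge_between_cycle_communities_maximizes_delta_bc(self):
        """A node v joining two communities, sampled into both process
        sub-networks as a minor alternative route (low within-process BC),
        dominates ΔBC in the union, where it brokers every cross-process
        pair.  Communities are 4-cycles so the intra-community seed
        geodesics pass through v; clique communities cannot exhibit this
        (adjacent seeds have single-edge geodesics that sample nothing)."""
        edges = []
        for c in "ab":
            cyc = [f"{c}{i}" for i in (1, 2, 3, 4)]
            edges += list(zip(cyc, cyc[1:] + cyc[:1]))
        edges += [("a1", "v"), ("a3", "v"), ("b1", "v"), ("b3", "v")]
        bg = ProteinNetwork.from_edges("bg", edges)
        sub1, _ = shortest_path_sample(bg, SeedList("one", ("a1", "a3")))
        sub2, _ = shortest_path_sample(bg, SeedList("two", ("b1", "b3")))
        assert "v" in sub1.nodes and "v" in sub2.nodes
        u = induced_union(bg, sub1, sub2)
        recs = delta_bc(betweenness(u), betweenness(sub1), betweenness(sub2))
        assert betweenness(sub1).bc["v"] == pytest.approx(1 / 3)
        assert recs[0].node == "v"
        assert recs[0].delta_bc > recs[1].delta_bc
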