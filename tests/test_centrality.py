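"""Centrality measures against an independent shortest-path oracle, and the
above-average selection rule."""

from collections import deque

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netrepos as nr
from netrepos.centrality import (
    betweenness_centrality,
    build_membership_matrix,
    closeness_centrality,
    degree_centrality,
    select_above_average,
)
from netrepos.subnetwork import Subnetwork


def subnet(*pairs, extra_nodes=()):
    nodes = {n: "signature" for e in pairs for n in e}
    nodes.update({n: "signature" for n in extra_nodes})
    edges = frozenset(tuple(sorted(e)) for e in pairs)
    return Subnetwork(entity_id="e", source="text", nodes=nodes, edges=edges)


# --- independent oracle: BFS distances and shortest-path counts ---------

def _bfs_sigma(adj, s):
    dist = {s: 0}
    sigma = {s: 1}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def oracle_betweenness(nodes, edges):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist, sigma = {}, {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_sigma(adj, s)
    bc = {n: 0.0 for n in nodes}
    nodes = sorted(nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    return bc


def oracle_closeness(nodes, edges):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for v in nodes:
        dist, _ = _bfs_sigma(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


class TestWorkedExamples:
    def test_star_degrees(self):
        s = subnet(("c", "x"), ("c", "y"), ("c", "z"))
        scores = degree_centrality(s).scores
        assert scores == {"c": 3.0, "x": 1.0, "y": 1.0, "z": 1.0}

    def test_isolated_node_zero_everywhere(self):
        s = subnet(("a", "b"), extra_nodes=("lone",))
        assert degree_centrality(s).scores["lone"] == 0.0
        assert betweenness_centrality(s).scores["lone"] == 0.0
        assert closeness_centrality(s).scores["lone"] == 0.0

    def test_triangle_regular(self):
        s = subnet(("a", "b"), ("b", "c"), ("a", "c"))
        assert set(degree_centrality(s).scores.values()) == {2.0}
        assert set(betweenness_centrality(s).scores.values()) == {0.0}

    def test_path_betweenness(self):
        s = subnet(("a", "b"), ("b", "c"))
        assert betweenness_centrality(s).scores == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_path_closeness(self):
        s = subnet(("a", "b"), ("b", "c"))
        scores = closeness_centrality(s).scores
        assert scores["b"] == pytest.approx(1.0)
        assert scores["a"] == pytest.approx(2 / 3)

    def test_complete_graph_closeness_one(self):
        nodes = "abcd"
        s = subnet(*[(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1:]])
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(s).scores.values())


@pytest.fixture(scope="module")
def atlas_graphs():
    graphs = [
        g for g in nx.graph_atlas_g()
        if 2 <= len(g) <= 6 and nx.is_connected(g)
    ]
    assert len(graphs) > 100  # 142 connected graphs on 2..6 nodes
    return graphs


class TestOracleEquivalence:
    """Exhaustive check on every connected graph with at most 6 nodes."""

    def test_betweenness_matches_oracle(self, atlas_graphs):
        for g in atlas_graphs:
            s = subnet(*[(str(a), str(b)) for a, b in g.edges()])
            got = betweenness_centrality(s).scores
            want = oracle_betweenness(set(s.nodes), s.edges)
            for v in s.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9), (g, v)

    def test_closeness_matches_oracle(self, atlas_graphs):
        for g in atlas_graphs:
            s = subnet(*[(str(a), str(b)) for a, b in g.edges()])
            got = closeness_centrality(s).scores
            want = oracle_closeness(set(s.nodes), s.edges)
            for v in s.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9), (g, v)

    def test_disconnected_graph_oracles(self):
        # two components plus an isolated node: component-wise conventions
        s = subnet(("a", "b"), ("b", "c"), ("x", "y"), extra_nodes=("lone",))
        got_b = betweenness_centrality(s).scores
        got_c = closeness_centrality(s).scores
        want_b = oracle_betweenness(set(s.nodes), s.edges)
        want_c = oracle_closeness(set(s.nodes), s.edges)
        for v in s.nodes:
            assert got_b[v] == pytest.approx(want_b[v], abs=1e-9)
            assert got_c[v] == pytest.approx(want_c[v], abs=1e-9)


class TestSelectAboveAverage:
    def test_star_selects_center(self):
        s = subnet(("c", "x"), ("c", "y"), ("c", "z"))
        assert select_above_average(degree_centrality(s)) == {"c"}

    def test_all_equal_selects_nothing(self):
        s = subnet(("a", "b"), ("b", "c"), ("a", "c"))
        assert select_above_average(degree_centrality(s)) == frozenset()

    def test_single_node_selects_nothing(self):
        s = subnet(extra_nodes=("a",))
        assert select_above_average(degree_centrality(s)) == frozenset()

    def test_two_degree_values_nonempty_proper_subset(self):
        s = subnet(("a", "b"), ("b", "c"))
        sel = select_above_average(degree_centrality(s))
        assert sel and sel < set(s.nodes)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=30))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_leave_one_out_reading_coincides(self, scores):
        """x > mean-of-others selects exactly the same set as x > overall mean.

        Exact rational arithmetic: the equivalence is algebraic and must not
        depend on float rounding of the two differently computed means.
        """
        from fractions import Fraction

        x = [Fraction(s) for s in scores]
        n, total = len(x), sum(x)
        overall = {i for i in range(n) if x[i] > total / n}
        loo = {i for i in range(n) if x[i] > (total - x[i]) / (n - 1)}
        assert overall == loo

    def test_scale_invariance(self):
        s = subnet(("a", "b"), ("b", "c"), ("c", "d"), ("b", "d"))
        base = select_above_average(betweenness_centrality(s))
        v = betweenness_centrality(s)
        v_scaled = nr.CentralityVector(
            entity_id=v.entity_id, measure=v.measure,
            scores={k: 7.5 * val for k, val in v.scores.items()},
        )
        assert select_above_average(v_scaled) == base


class TestBuildMembershipMatrix:
    def test_single_entity_row(self):
        uni = nr.GeneUniverse(genes=("g1", "g2", "g3"))
        m = build_membership_matrix({"e1": frozenset({"g1", "g3"})}, uni)
        assert m.values.tolist() == [[True, False, True]]

    def test_empty_selection_zero_row(self):
        uni = nr.GeneUniverse(genes=("g1", "g2", "g3"))
        m = build_membership_matrix({"e1": frozenset()}, uni)
        assert not m.values.any()

    def test_unknown_gene_rejected(self):
        uni = nr.GeneUniverse(genes=("g1",))
        with pytest.raises(nr.ValidationError):
            build_membership_matrix({"e1": frozenset({"bad"})}, uni)

    def test_row_sums_equal_selection_sizes(self):
        rng = np.random.default_rng(6)
        uni = nr.GeneUniverse(genes=tuple(f"g{i:02d}" for i in range(30)))
        selections = {
            f"e{j}": frozenset(
                np.array(uni.genes)[rng.choice(30, rng.integers(0, 30), replace=False)]
            )
            for j in range(5)
        }
        m = build_membership_matrix(selections, uni)
        for j, e in enumerate(m.entity_ids):
            assert m.values[j].sum() == len(selections[e])
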