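"""PE-measure, CD-distance family and below-average edge filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pewcc import ppi_graph
from pewcc.reliability import (
    ReliabilityMatrix,
    adjstcd,
    adjstcd_iterate,
    cd_distance,
    filter_unreliable,
    node_average,
    pe_initialize,
    pe_iterate,
    pe_score,
)

from conftest import random_graph


def naive_pe_iterate(matrix, network):
    """Independent double-loop reference for one synchronous PE update."""
    new = {}
    for u, v in network.edges():
        prod = 1.0
        for l in network.nodes:
            if network.has_edge(u, l) and network.has_edge(v, l):
                prod *= 1.0 - matrix.value(u, l) * matrix.value(v, l)
        new[frozenset((u, v))] = 1.0 - prod
    return ReliabilityMatrix(entries=new, iteration=matrix.iteration + 1)


def naive_adjstcd_step(network, w):
    """Direct summation of the iterated-AdjstCD update from weights ``w``."""
    n = network.number_of_nodes()
    w_avg = sum(
        w.get(frozenset((x, y)), 0.0)
        for x in network.nodes
        for y in network.neighbors(x)
    ) / n
    new = {}
    for u, v in network.edges():
        num = sum(
            w.get(frozenset((x, u)), 0.0) + w.get(frozenset((x, v)), 0.0)
            for x in set(network.neighbors(u)) & set(network.neighbors(v))
        )
        s_u = sum(w.get(frozenset((x, u)), 0.0) for x in network.neighbors(u))
        s_v = sum(w.get(frozenset((x, v)), 0.0) for x in network.neighbors(v))
        denom = max(s_u, w_avg) + max(s_v, w_avg)
        new[frozenset((u, v))] = num / denom if denom else 0.0
    return new


class TestPEWorkedExample:
    def test_initialization_is_half_everywhere(self, fig2):
        m = pe_initialize(fig2)
        assert len(m) == 6 and m.iteration == 0
        assert all(v == 0.5 for _, v in m.items())

    def test_first_iteration_values(self, fig2):
        m = pe_iterate(pe_initialize(fig2), fig2)
        assert m.value("1", "2") == pytest.approx(7 / 16)
        for e in [("1", "3"), ("2", "3"), ("2", "4"), ("1", "4")]:
            assert m.value(*e) == pytest.approx(1 / 4)
        assert m.value("3", "5") == 0.0

    def test_triangle_single_step(self):
        tri = ppi_graph.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        m = pe_iterate(pe_initialize(tri), tri)
        assert all(v == pytest.approx(0.25) for _, v in m.items())

    def test_pe_score_composition(self, fig2):
        manual = pe_iterate(pe_initialize(fig2), fig2)
        auto = pe_score(fig2, k=1)
        assert manual.entries == auto.entries

    def test_structural_zero_survives_iterations(self, fig2):
        assert pe_score(fig2, k=2).value("3", "5") == 0.0

    def test_k_below_one_rejected(self, fig2):
        with pytest.raises(ValueError):
            pe_score(fig2, k=0)

    def test_edgeless_network_empty_matrix(self):
        g = ppi_graph.from_edges([], nodes=["x", "y"])
        assert len(pe_initialize(g)) == 0


class TestPEOracleAndProperties:
    @pytest.mark.parametrize("trial", range(100))
    def test_matches_naive_double_loop(self, trial):
        g = random_graph(5 + trial % 36, 0.2, seed=trial)
        m = pe_initialize(g)
        for _ in range(2):
            fast = pe_iterate(m, g)
            slow = naive_pe_iterate(m, g)
            for e, v in fast.items():
                assert v == pytest.approx(slow.entries[e], abs=1e-12)
            m = fast

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_values_in_unit_interval_and_symmetric(self, k):
        g = random_graph(30, 0.25, seed=k)
        m = pe_score(g, k=k)
        for e, v in m.items():
            assert 0.0 <= v <= 1.0
            u, w = tuple(e)
            assert m.value(u, w) == m.value(w, u)

    def test_triangle_free_edges_stay_zero(self):
        # a path graph has no triangles at all
        path = ppi_graph.from_edges([(str(i), str(i + 1)) for i in range(10)])
        for k in (1, 3):
            assert all(v == 0.0 for _, v in pe_score(path, k=k).items())


class TestNodeAverageAndFilter:
    def test_arithmetic_mean(self):
        g = ppi_graph.from_edges([("i", "a"), ("i", "b")])
        m = ReliabilityMatrix({frozenset(("i", "a")): 0.2, frozenset(("i", "b")): 0.4})
        assert node_average(m, g)["i"] == pytest.approx(0.3)

    def test_fig2_node3_average(self, fig2):
        m = pe_score(fig2, k=1)
        assert node_average(m, fig2)["3"] == pytest.approx(1 / 6)

    def test_uniform_weights_average_to_weight(self):
        g = random_graph(12, 0.4, seed=3)
        m = ReliabilityMatrix({frozenset(e): 0.7 for e in g.edges()})
        for v in node_average(m, g).values():
            assert v == pytest.approx(0.7)

    def test_isolated_node_has_no_entry(self):
        g = ppi_graph.from_edges([("a", "b")], nodes=["z"])
        assert "z" not in node_average(pe_initialize(g), g)

    def test_fig2_filter_removes_untriangled_edge(self, fig2):
        m = pe_score(fig2, k=1)
        filtered = filter_unreliable(fig2, m)
        assert not filtered.has_edge("3", "5")
        assert filtered.has_edge("1", "2")
        assert set(filtered.nodes) == set(fig2.nodes)

    def test_uniform_weights_remove_nothing(self):
        g = random_graph(15, 0.3, seed=9)
        m = ReliabilityMatrix({frozenset(e): 0.5 for e in g.edges()})
        assert filter_unreliable(g, m).number_of_edges() == g.number_of_edges()

    def test_star_zero_weight_edge_removed(self):
        g = ppi_graph.from_edges([("c", "a"), ("c", "b"), ("c", "d")])
        m = ReliabilityMatrix(
            {
                frozenset(("c", "a")): 0.0,
                frozenset(("c", "b")): 0.6,
                frozenset(("c", "d")): 0.6,
            }
        )
        f = filter_unreliable(g, m)
        assert not f.has_edge("c", "a")
        assert f.has_edge("c", "b") and f.has_edge("c", "d")

    def test_max_incident_weight_at_both_endpoints_survives(self):
        g = random_graph(20, 0.3, seed=21)
        m = pe_score(g, k=2)
        f = filter_unreliable(g, m)
        for u, v in g.edges():
            p = m.value(u, v)
            max_u = max(m.value(u, x) for x in g.neighbors(u))
            max_v = max(m.value(v, x) for x in g.neighbors(v))
            if p == max_u and p == max_v:
                assert f.has_edge(u, v)


class TestCDDistanceFamily:
    def test_identical_neighbor_sets(self):
        # u and v both adjacent to exactly {a, b, c}
        g = ppi_graph.from_edges(
            [("u", x) for x in "abc"] + [("v", x) for x in "abc"]
        )
        assert cd_distance(g, "u", "v") == pytest.approx(0.0)

    def test_disjoint_neighbor_sets(self):
        g = ppi_graph.from_edges([("u", "a"), ("v", "b")])
        assert cd_distance(g, "u", "v") == pytest.approx(1.0)

    def test_partial_overlap(self):
        g = ppi_graph.from_edges(
            [("u", x) for x in ("s1", "s2", "a")]
            + [("v", x) for x in ("s1", "s2", "b", "c", "d")]
        )
        assert cd_distance(g, "u", "v") == pytest.approx(0.5)

    def test_both_isolated_is_domain_error(self):
        g = ppi_graph.from_edges([("a", "b")], nodes=["u", "v"])
        with pytest.raises(ValueError):
            cd_distance(g, "u", "v")

    def test_adjstcd_disjoint_is_zero(self):
        g = ppi_graph.from_edges([("u", "a"), ("v", "b")])
        assert adjstcd(g, "u", "v") == 0.0

    def test_adjstcd_regular_graph(self):
        # 4-cycle: every degree equals the mean degree 2
        g = ppi_graph.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert adjstcd(g, "a", "c") == pytest.approx(2 * 2 / (2 + 2))

    def test_adjstcd_fig2_low_degree_floor(self, fig2):
        assert adjstcd(fig2, "1", "2") == pytest.approx(2 / 3)


class TestAdjstCDIteration:
    def test_first_iteration_equals_adjstcd(self, fig2):
        m = adjstcd_iterate(fig2, k=1)
        for u, v in fig2.edges():
            assert m.value(u, v) == pytest.approx(adjstcd(fig2, u, v))

    def test_no_common_neighbors_zero_at_any_k(self, fig2):
        for k in (1, 2, 4):
            assert adjstcd_iterate(fig2, k=k).value("3", "5") == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_k2_matches_direct_summation_oracle(self, seed):
        g = random_graph(6 + 4 * seed, 0.45, seed=seed)
        w = {frozenset(e): 1.0 for e in g.edges()}
        for _ in range(2):
            w = naive_adjstcd_step(g, w)
        m = adjstcd_iterate(g, k=2)
        for e, v in m.items():
            assert v == pytest.approx(w[e], abs=1e-12)

    def test_k_below_one_rejected(self, fig2):
        with pytest.raises(ValueError):
            adjstcd_iterate(fig2, k=0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.sets(
        st.tuples(st.integers(0, 14), st.integers(0, 14)).filter(lambda t: t[0] < t[1]),
        min_size=1,
        max_size=40,
    ),
    st.integers(1, 3),
)
def test_pe_unit_interval_and_symmetry_property(edge_ints, k):
    """PE values stay probabilities and symmetric on arbitrary graphs and k."""
    g = ppi_graph.from_edges([(str(a), str(b)) for a, b in edge_ints])
    m = pe_score(g, k=k)
    for e, v in m.items():
        assert 0.0 <= v <= 1.0
        u, w = tuple(e)
        assert m.value(u, w) == m.value(w, u)
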