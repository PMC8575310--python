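"""Graph container, I/O, generators, and degree statistics."""

import io
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

import degreedrift as dd
from degreedrift.graph_core import GraphError, degree_stats


class TestGraphInvariants:
    def test_simple_graph_rejects_self_loops_and_duplicates(self):
        with pytest.raises(GraphError, match="self-loop"):
            dd.Graph.from_edges(3, [(0, 1), (2, 2)])
        with pytest.raises(GraphError, match="duplicate"):
            dd.Graph.from_edges(3, [(0, 1), (1, 0)])

    def test_degree_sum_is_twice_edge_count(self):
        g = dd.Graph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        assert g.degrees.sum() == 2 * g.n_edges
        assert g.degree(0) == 3 and g.degree(3) == 2

    def test_neighbors_match_edges(self):
        g = dd.Graph.from_edges(3, [(0, 1), (1, 2)])
        assert sorted(g.neighbors(1)) == [0, 2]
        assert g.connected
        assert not dd.Graph.from_edges(4, [(0, 1), (2, 3)]).connected


class TestEdgeListIO:
    def test_read_path_graph(self):
        g = dd.read_edge_list("0 1\n1 2")
        assert g.n_nodes == 3 and g.edges == ((0, 1), (1, 2))

    def test_read_rejects_self_loop_with_line_number(self):
        with pytest.raises(GraphError, match="line 1"):
            dd.read_edge_list("3 3")

    def test_read_rejects_empty_input(self):
        with pytest.raises(GraphError, match="empty"):
            dd.read_edge_list("# only a comment\n")

    def test_duplicate_edges_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            g = dd.read_edge_list("0 1\n1 0\n1 2")
        assert g.n_edges == 2

    def test_write_is_canonical(self):
        g = dd.Graph.from_edges(3, [(1, 2), (0, 1)])
        buf = io.StringIO()
        dd.write_edge_list(g, buf)
        assert buf.getvalue().splitlines()[1:] == ["0 1", "1 2"]

    def test_write_star_with_core_zero(self):
        buf = io.StringIO()
        dd.write_edge_list(dd.make_star(3), buf)
        assert buf.getvalue().splitlines()[1:] == ["0 1", "0 2", "0 3"]

    def test_worked_example_round_trips(self, example12):
        buf = io.StringIO()
        dd.write_edge_list(example12.graph, buf)
        back = dd.read_edge_list(io.StringIO(buf.getvalue()))
        assert back.edges == example12.graph.edges
        assert sorted(back.degrees) == sorted(example12.graph.degrees)

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_identity_for_generated_graphs(self, seed):
        g = dd.make_small_world(20, 4, 0.3, seed)
        buf = io.StringIO()
        dd.write_edge_list(g, buf)
        assert dd.read_edge_list(io.StringIO(buf.getvalue())).edges == g.edges


class TestGenerators:
    def test_star_shape(self):
        g = dd.make_star(8)
        assert g.n_nodes == 9 and g.degree(0) == 8
        assert g.avg_degree == Fraction(16, 9)
        assert all(g.degree(i) == 1 for i in range(1, 9))

    def test_star_degenerate_and_avg_degree(self):
        assert dd.make_star(1).n_edges == 1
        assert dd.make_star(5).avg_degree == Fraction(5, 3)
        with pytest.raises(GraphError):
            dd.make_star(0)

    def test_complete_graph(self):
        g = dd.make_complete(4)
        assert g.n_edges == 6 and set(g.degrees) == {3}
        assert dd.make_complete(2).n_edges == 1
        assert degree_stats(dd.make_complete(7)).fluctuation == 0
        with pytest.raises(GraphError):
            dd.make_complete(1)

    def test_ring_lattice(self):
        assert dd.make_ring_lattice(6, 2).edges == tuple(
            sorted({(i, (i + 1) % 6) if i < (i + 1) % 6 else ((i + 1) % 6, i) for i in range(6)})
        )
        g = dd.make_ring_lattice(10, 4)
        assert g.n_edges == 20 and set(g.degrees) == {4}
        assert degree_stats(g).fluctuation == 0
        with pytest.raises(GraphError):
            dd.make_ring_lattice(10, 3)
        with pytest.raises(GraphError):
            dd.make_ring_lattice(4, 4)

    def test_small_world_q0_is_the_lattice(self):
        assert dd.make_small_world(12, 4, 0.0, seed=5).edges == dd.make_ring_lattice(12, 4).edges
        assert degree_stats(dd.make_small_world(12, 4, 0.0, seed=5)).fluctuation == 0

    def test_small_world_conserves_edge_count(self):
        for seed in range(100):
            g = dd.make_small_world(1000, 6, 1.0, seed)
            assert g.n_edges == 3000
        assert float(degree_stats(g).fluctuation) > 0

    @pytest.mark.parametrize("q", [0.0, 0.1, 0.5, 1.0])
    def test_small_world_edge_count_for_all_q(self, q):
        g = dd.make_small_world(60, 4, q, seed=3)
        assert g.n_edges == 120

    def test_small_world_rejects_bad_parameters(self):
        with pytest.raises(GraphError):
            dd.make_small_world(10, 4, 1.5, seed=0)
        with pytest.raises(GraphError):
            dd.make_small_world(10, 3, 0.1, seed=0)

    @pytest.mark.parametrize("seed", range(100))
    def test_generator_outputs_are_simple_and_connected(self, seed):
        for g in (
            dd.make_small_world(50, 4, 0.3, seed),
            dd.make_scale_free(64, 2.8, k_min=2, seed=seed),
        ):
            assert g.connected
            assert all(i < j for i, j in g.edges)  # canonical, no self-loops
            assert len(set(g.edges)) == g.n_edges
            assert g.degrees.sum() == 2 * g.n_edges

    def test_scale_free_respects_minimum_degree(self):
        for seed in range(20):
            g = dd.make_scale_free(128, 3.5, k_min=3, seed=seed)
            assert g.degrees.min() >= 3

    def test_scale_free_rejects_bad_exponent(self):
        with pytest.raises(GraphError):
            dd.make_scale_free(64, 1.9, seed=0)
        with pytest.raises(GraphError):
            dd.make_scale_free(64, 3.0, k_min=0, seed=0)

    def test_heavier_tail_gives_larger_fluctuation(self):
        """At equal N, gamma=2.5 networks fluctuate more than gamma=4 ones."""
        d25 = np.mean(
            [
                float(degree_stats(dd.make_scale_free(256, 2.5, seed=s)).fluctuation)
                for s in range(15)
            ]
        )
        d40 = np.mean(
            [
                float(degree_stats(dd.make_scale_free(256, 4.0, seed=s)).fluctuation)
                for s in range(15)
            ]
        )
        assert d25 > d40 > 0

    def test_scale_free_fluctuation_matches_sampled_distribution(self):
        """The generator preserves its drawn degree sequence, so the mean
        empirical fluctuation tracks the exact moments of the discrete
        power-law it samples from (computed independently by summation)."""
        gamma, k_min, n = 4.0, 3, 1024
        ks = np.arange(k_min, n, dtype=float)
        w = ks**-gamma
        w /= w.sum()
        m1, m2 = (w * ks).sum(), (w * ks**2).sum()
        target = m2 / m1**2 - 1
        vals = [
            float(degree_stats(dd.make_scale_free(n, gamma, k_min=k_min, seed=s)).fluctuation)
            for s in range(40)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 3 * se


class TestDegreeStats:
    def test_complete_graph_is_regular(self):
        s = degree_stats(dd.make_complete(4))
        assert s.distribution == {3: Fraction(1)}
        assert s.fluctuation == 0

    def test_star_moments_by_hand(self):
        s = degree_stats(dd.make_star(8))
        assert s.distribution == {1: Fraction(8, 9), 8: Fraction(1, 9)}
        assert s.mean == Fraction(16, 9)
        assert s.second_moment == Fraction(8)
        assert s.fluctuation == Fraction(49, 32)

    def test_worked_example_average_degree(self, example12):
        assert degree_stats(example12.graph).mean == 3

    @given(st.integers(0, 2**31 - 1))
    def test_distribution_sums_to_one_and_fluctuation_nonnegative(self, seed):
        g = dd.make_scale_free(48, 3.0, k_min=2, seed=seed)
        s = degree_stats(g)
        assert sum(s.distribution.values()) == 1
        assert s.fluctuation >= 0


class TestTheoreticalFluctuation:
    def test_gamma_four_value(self):
        assert dd.theoretical_fluctuation(4.0) == pytest.approx(1 / 3, abs=1e-12)

    def test_large_gamma_limit_vanishes(self):
        assert dd.theoretical_fluctuation(200.0) < 1e-3

    def test_strictly_decreasing_above_three(self):
        grid = np.linspace(3.05, 12.0, 60)
        vals = [dd.theoretical_fluctuation(g) for g in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_heavy_regime_increases_with_cutoff(self):
        lo = dd.theoretical_fluctuation(2.5, kmax_over_kmean=10)
        hi = dd.theoretical_fluctuation(2.5, kmax_over_kmean=100)
        assert 0 < lo < hi

    def test_singular_inputs_rejected(self):
        for bad in (2.0, 3.0, 1.5):
            with pytest.raises(GraphError):
                dd.theoretical_fluctuation(bad)
        with pytest.raises(GraphError):
            dd.theoretical_fluctuation(2.5)  # missing cutoff ratio


class TestWorkedExample:
    def test_printed_structure(self, example12):
        g = example12.graph
        node = example12.node
        assert g.n_nodes == 12 and g.n_edges == 18
        assert g.avg_degree == 3
        assert g.degree(node(11)) == 6
        assert sorted(example12.label(j) for j in g.neighbors(node(11))) == [1, 2, 4, 6, 7, 10]
        assert g.degree(node(2)) == 2
        assert g.degree(node(6)) == 2
        assert g.degree(node(10)) == 5
        assert g.connected

    def test_mutant_set(self, example12):
        assert {example12.label(m) for m in example12.mutants} == {2, 6, 10}
        assert example12.mutants < set(example12.graph.neighbors(example12.node(11)))
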