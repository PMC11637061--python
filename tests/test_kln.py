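"""The KLN scoring chain: path change factor, distributions, KL model,
damage influence, and the full ranking."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from klnrank import (
    SELF,
    UNREACHABLE,
    DegenerateDistributionError,
    GraphDomainError,
    damage_influence,
    fitting_distribution,
    kl_divergence,
    kln_score,
    node_divergence,
    path_change_factor,
    post_removal_profile,
    random_graph,
    rank_all,
    real_distribution,
)

from _reference import ref_kln_scores


class TestPathChangeFactor:
    @pytest.mark.parametrize(
        "l,expected", [(1, 1.0), (2, 0.5), (4, 0.25), (UNREACHABLE, 0.5), (SELF, 1.0)]
    )
    def test_values(self, l, expected):
        assert path_change_factor(l) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0, -3, 1.5, "far"])
    def test_rejects_non_positive_or_non_integer(self, bad):
        with pytest.raises(GraphDomainError):
            path_change_factor(bad)


class TestRealDistribution:
    def test_fixture_node_1_matches_printed_vector(self, toy):
        p = real_distribution(toy, 1)
        assert p.neighbors == (2, 6, 7, 8)
        assert np.allclose(p.probs, (0.384, 0.231, 0.154, 0.231), atol=1e-3)

    def test_single_neighbor_is_certain(self):
        g = nx.path_graph(2)
        assert real_distribution(g, 0).probs == pytest.approx([1.0])

    def test_equal_degrees_give_uniform(self):
        g = nx.cycle_graph(4)
        assert np.allclose(real_distribution(g, 0).probs, 0.5)

    def test_isolated_center_rejected(self):
        g = nx.empty_graph(2)
        with pytest.raises(GraphDomainError):
            real_distribution(g, 0)


class TestPostRemovalProfile:
    def test_fixture_center_1(self, toy):
        prof = post_removal_profile(toy, 1)
        assert prof.neighbors == (2, 6, 7, 8)
        assert prof.post_degree == {2: 4, 6: 2, 7: 1, 8: 2}
        assert prof.post_distance[(7, 2)] == 4
        assert prof.post_distance[(7, 6)] == 3
        assert prof.post_distance[(7, 8)] == 2
        assert prof.kshell == {2: 3, 6: 2, 7: 2, 8: 2}
        # symmetry and the d'(j) = d(j) - 1 identity for neighbors
        for (n, j), l in prof.post_distance.items():
            assert prof.post_distance[(j, n)] == l
        assert all(
            prof.post_degree[j] == prof.pre_degree[j] - 1 for j in prof.neighbors
        )

    def test_star_center_neighbors_all_disconnected(self):
        g = nx.star_graph(3)
        prof = post_removal_profile(g, 0)
        assert all(l is UNREACHABLE for l in prof.post_distance.values())
        assert set(prof.post_degree.values()) == {0}

    def test_triangle_remaining_pair_adjacent(self):
        prof = post_removal_profile(nx.cycle_graph(3), 0)
        assert prof.post_distance[(1, 2)] == 1

    def test_unknown_center(self, toy):
        with pytest.raises(GraphDomainError):
            post_removal_profile(toy, 99)


class TestFittingDistribution:
    def test_fixture_rows_match_printed_matrix(self, toy):
        q = fitting_distribution(post_removal_profile(toy, 1))
        assert np.allclose(q.row(7), (0.359, 0.207, 0.180, 0.254), atol=1e-3)
        assert np.allclose(q.row(2), (0.533, 0.267, 0.067, 0.133), atol=1e-3)
        assert np.allclose(q.row(6), (0.517, 0.259, 0.075, 0.149), atol=1e-3)
        assert np.allclose(q.row(8), (0.341, 0.197, 0.121, 0.341), atol=1e-3)

    def test_rows_are_distributions(self, toy):
        for center in (1, 2, 6, 10):
            q = fitting_distribution(post_removal_profile(toy, center))
            assert np.allclose(q.rows.sum(axis=1), 1.0, atol=1e-12)
            assert (q.rows >= 0).all()

    def test_symmetric_remainder_gives_equal_rows(self):
        # removing one end of a 4-cycle leaves a path; the two far ends
        # of the path are interchangeable
        g = nx.cycle_graph(4)
        q = fitting_distribution(post_removal_profile(g, 0))
        # neighbors of 0 are 1 and 3, symmetric through node 2
        assert np.allclose(q.row(1), q.row(3)[::-1])

    def test_zero_floor_on_star_is_degenerate(self):
        prof = post_removal_profile(nx.star_graph(3), 0)
        with pytest.raises(DegenerateDistributionError):
            fitting_distribution(prof, floor=0.0)


class TestKlDivergence:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.4, 0.35, 0.25])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_printed_kl_terms_base_10(self, toy):
        p = real_distribution(toy, 1)
        q = fitting_distribution(post_removal_profile(toy, 1))
        assert kl_divergence(p, q.row(6)) == pytest.approx(0.031, abs=1e-3)
        assert kl_divergence(p, q.row(7)) == pytest.approx(0.002, abs=1e-3)
        assert kl_divergence(p, q.row(2)) == pytest.approx(0.042, abs=1e-3)
        assert kl_divergence(p, q.row(8)) == pytest.approx(0.013, abs=1e-3)

    def test_zero_p_entries_contribute_nothing(self):
        assert kl_divergence([0.5, 0.5, 0.0], [0.25, 0.25, 0.5], log_base=2) == (
            pytest.approx(1.0)
        )

    def test_length_mismatch(self):
        with pytest.raises(GraphDomainError):
            kl_divergence([0.5, 0.5], [1.0])

    @given(
        weights=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
        seed=st.integers(0, 10_000),
    )
    def test_gibbs_nonnegativity(self, weights, seed):
        rng = np.random.default_rng(seed)
        p = np.array(weights) / np.sum(weights)
        q = rng.dirichlet(np.ones(len(p)))
        assert kl_divergence(p, q) >= -1e-12


class TestNodeScores:
    def test_fixture_divergence_and_damage(self, toy):
        assert node_divergence(toy, 1) == pytest.approx(0.218, abs=1e-3)
        assert damage_influence(toy, 1) == pytest.approx(4.218, abs=1e-3)

    def test_star_center_divergence_finite(self):
        d = node_divergence(nx.star_graph(4), 0)
        assert math.isfinite(d) and d >= 0

    def test_isolated_node_damage_zero(self):
        g = nx.path_graph(2)
        g.add_node("iso")
        assert damage_influence(g, "iso") == 0.0
        assert kln_score(g, "iso") == 0.0

    def test_degree_one_node_damage_is_one(self):
        # a leaf's single-entry P and q rows coincide, so KL = 0, DE = 1
        g = nx.path_graph(3)
        assert damage_influence(g, 0) == pytest.approx(1.0)

    def test_kln_from_given_damage_values(self):
        g = nx.star_graph(4)  # center 0, neighbors 1..4 stand in for 2,6,7,8
        de = {0: 4.218, 1: 5.088, 2: 3.132, 3: 2.028, 4: 2.711}
        assert kln_score(g, 0, de=de) == pytest.approx(
            4.218 + math.sqrt(12.959), abs=1e-9
        )

    def test_star_center_closed_form(self):
        k = 5
        g = nx.star_graph(k)
        table = rank_all(g)
        # every leaf has DE = 1 exactly
        assert all(table.de[j] == pytest.approx(1.0) for j in range(1, k + 1))
        assert table.kln[0] == pytest.approx(table.de[0] + math.sqrt(k))


class TestRankAll:
    def test_edgeless_graph_all_zero_identifier_order(self):
        g = nx.empty_graph(4)
        table = rank_all(g)
        assert set(table.kln.values()) == {0.0}
        assert table.ranking == (0, 1, 2, 3)

    def test_cycle_is_score_uniform(self):
        table = rank_all(nx.cycle_graph(6))
        assert np.ptp(list(table.kln.values())) < 1e-12

    def test_automorphic_fixture_nodes_4_and_5_tie(self, toy):
        table = rank_all(toy)
        assert table.kln[4] == pytest.approx(table.kln[5], abs=1e-12)

    def test_invariants_de_and_kln_lower_bounds(self, toy):
        table = rank_all(toy)
        for v in toy.nodes():
            assert table.de[v] >= toy.degree(v)
            assert table.kln[v] >= table.de[v]
        assert sorted(table.ranking) == sorted(toy.nodes())

    @given(seed=st.integers(0, 300))
    def test_matches_brute_force_reference(self, seed):
        g = random_graph("ER", seed=seed, n=(seed % 15) + 4, p=0.3)
        mine = rank_all(g).kln
        ref = ref_kln_scores(g)
        assert all(mine[v] == pytest.approx(ref[v], abs=1e-9) for v in g.nodes())

    @given(seed=st.integers(0, 150))
    def test_isomorphism_invariance(self, seed):
        g = random_graph("ER", seed=seed, n=12, p=0.3)
        perm = {v: f"z{(v * 5 + 1) % 12:02d}" for v in g.nodes()}
        h = nx.relabel_nodes(g, perm)
        kg, kh = rank_all(g).kln, rank_all(h).kln
        assert all(kg[v] == pytest.approx(kh[perm[v]], abs=1e-9) for v in g.nodes())

    def test_edge_order_invariance(self, toy):
        reversed_g = nx.Graph()
        reversed_g.add_edges_from(reversed([e for e in toy.edges()]))
        a, b = rank_all(toy), rank_all(reversed_g)
        assert all(a.kln[v] == pytest.approx(b.kln[v], abs=1e-12) for v in toy)
        assert a.ranking == b.ranking

    def test_bfs_cutoff_treats_far_pairs_as_disconnected(self):
        # removing one end of a long path: with a 1-hop cutoff every
        # surviving pair beyond distance 1 must fall back to lambda = 1/2
        g = nx.cycle_graph(8)
        full = rank_all(g)
        capped = rank_all(g, bfs_cutoff=1)
        assert any(
            capped.kln[v] != pytest.approx(full.kln[v], abs=1e-12) for v in g
        )
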