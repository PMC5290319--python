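import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloseed import build_conflict_graph, incompatible, pattern_likelihood, presence_table, reliability_score
from phyloseed.bayes import PresenceTable
from phyloseed.patterns import bits_to_mask, log_likelihood_matrix, reliability_scores

from conftest import make_matrix


def table_from_p(p):
    p = np.asarray(p, dtype=float)
    return PresenceTable(
        p=p,
        q=1.0 - p,
        samples=[f"S{j}" for j in range(p.shape[1])],
        variants=[f"v{i}" for i in range(p.shape[0])],
    )


class TestIncompatible:
    def test_crossing_pair(self):
        assert incompatible([1, 1, 0], [0, 1, 1]) is True

    def test_nested(self):
        assert incompatible([1, 1, 0], [1, 1, 1]) is False

    def test_disjoint(self):
        assert incompatible([1, 0], [0, 1]) is False

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            incompatible([1, 0], [1, 0, 1])

    @given(st.integers(0, 255), st.integers(0, 255))
    def test_symmetry_and_trivial_degrees(self, u, v):
        assert incompatible(u, v, 8) == incompatible(v, u, 8)
        assert not incompatible(u, u, 8)
        assert not incompatible(u, 0, 8)
        assert not incompatible(u, 255, 8)


class TestLikelihood:
    def test_two_sample_arithmetic(self):
        table = table_from_p([[0.9, 0.3]])
        # pattern {S1}: p1 * q2 = 0.9 * 0.7
        assert pattern_likelihood(0, [1, 0], table) == pytest.approx(0.63)

    def test_degenerate_certainty(self):
        table = table_from_p([[1.0, 1.0, 0.0]])
        assert pattern_likelihood(0, [1, 1, 0], table) == pytest.approx(1.0)
        for bits in itertools.product([0, 1], repeat=3):
            if list(bits) != [1, 1, 0]:
                assert pattern_likelihood(0, list(bits), table) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [2, 4, 7, 10])
    def test_normalization_over_all_patterns(self, n, rng):
        p = rng.uniform(0, 1, size=(5, n))
        table = table_from_p(p)
        masks = np.arange(2**n, dtype=np.int64)
        loglik = log_likelihood_matrix(table, masks)
        sums = np.exp(loglik).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_loglik_matrix_matches_scalar(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 5))
        table = table_from_p(p)
        masks = np.arange(2**5, dtype=np.int64)
        loglik = log_likelihood_matrix(table, masks)
        for i in (0, 3):
            for mask in (0, 7, 21, 31):
                assert np.exp(loglik[i, mask]) == pytest.approx(pattern_likelihood(i, int(mask), table), rel=1e-9)


class TestReliability:
    def test_hand_computed(self):
        # m=2 with L = 0.9 and 0.5: omega = -0.5 * ln(0.1 * 0.5)
        table = table_from_p([[0.9, 1.0], [0.5, 1.0]])
        omega = reliability_score([1, 1], table)
        assert omega == pytest.approx(-0.5 * np.log(0.1 * 0.5), rel=1e-9)
        assert omega == pytest.approx(1.4979, abs=1e-4)

    def test_zero_support(self):
        table = table_from_p([[1.0, 0.0], [1.0, 0.0]])
        assert reliability_score([0, 1], table) == pytest.approx(0.0)

    def test_normalization_by_m(self):
        base = [[0.9, 1.0], [0.5, 1.0]]
        with_zero = base + [[0.0, 1.0]]  # L(v) = 0 for the added variant
        w2 = reliability_score([1, 1], table_from_p(base))
        w3 = reliability_score([1, 1], table_from_p(with_zero))
        assert w3 == pytest.approx(w2 * 2 / 3, rel=1e-9)

    def test_likelihood_cap_keeps_score_finite(self):
        table = table_from_p([[1.0, 1.0]])
        assert np.isfinite(reliability_score([1, 1], table))

    def test_dominates_best_single_variant(self, rng):
        p = rng.uniform(0, 1, size=(6, 4))
        table = table_from_p(p)
        masks = np.arange(16, dtype=np.int64)
        omega = reliability_scores(table, masks)
        like = np.exp(log_likelihood_matrix(table, masks))
        m = p.shape[0]
        lower = (-np.log1p(-np.minimum(like, 1 - 1e-12)) / m).max(axis=0)
        assert (omega >= lower - 1e-12).all()


class TestConflictGraph:
    def test_uniform_three_samples(self):
        table = table_from_p(np.full((3, 3), 0.5))
        graph = build_conflict_graph(table)
        assert graph.n_nodes == 8
        edge_masks = {
            frozenset((int(graph.masks[i]), int(graph.masks[j])))
            for i, j in zip(*graph.edges)
        }
        # only the three crossing pairs of two-sample patterns conflict
        expected = {
            frozenset((0b011, 0b110)),
            frozenset((0b011, 0b101)),
            frozenset((0b110, 0b101)),
        }
        assert edge_masks == expected

    def test_exhaustive_pair_check(self, rng):
        n = 4
        table = table_from_p(rng.uniform(0, 1, size=(3, n)))
        graph = build_conflict_graph(table)
        edge_set = {(int(i), int(j)) for i, j in zip(*graph.edges)}
        for i in range(graph.n_nodes):
            for j in range(i + 1, graph.n_nodes):
                expected = incompatible(int(graph.masks[i]), int(graph.masks[j]), n)
                assert ((i, j) in edge_set) == expected

    def test_empty_and_full_have_degree_zero(self, rng):
        table = table_from_p(rng.uniform(0, 1, size=(4, 5)))
        graph = build_conflict_graph(table)
        for mask in (0, 31):
            assert graph.degree(graph.index_of(mask)) == 0

    def test_noiseless_laminar_conflicts_are_cheap(self, config, rng, laminar_matrix):
        table = presence_table(laminar_matrix, config)
        graph = build_conflict_graph(table)
        # on clean data every edge has a near-zero-weight endpoint, so
        # resolving all conflicts costs (almost) nothing
        for i, j in zip(*graph.edges):
            assert min(graph.weights[int(i)], graph.weights[int(j)]) < 1e-4
        true_masks = {0b1111, 0b0011, 0b1100, 0b0001, 0b0100}
        for mask in true_masks:
            assert graph.weights[graph.index_of(mask)] > 0.1
        from phyloseed import solve_min_vertex_cover

        solution = solve_min_vertex_cover(graph, zero_weight_tol=1e-10)
        assert solution.objective < 1e-3
        assert true_masks <= solution.kept

    def test_enumeration_limit(self, rng):
        table = table_from_p(rng.uniform(0, 1, size=(2, 16)))
        with pytest.raises(ValueError, match="restricted"):
            build_conflict_graph(table, max_enumeration_samples=14, restricted=False)
        graph = build_conflict_graph(table, max_enumeration_samples=14)
        assert graph.restricted
        assert graph.n_nodes < 2**16
        assert 0 in graph.masks and (2**16 - 1) in graph.masks

    def test_edge_list_export(self, tmp_path, rng):
        table = table_from_p(rng.uniform(0, 1, size=(3, 3)))
        graph = build_conflict_graph(table)
        out = tmp_path / "edges.tsv"
        graph.write_edge_list(out)
        lines = out.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["pattern", "weight_nats", "neighbors"]
        assert len(lines) == 9


def test_bits_mask_round_trip(rng):
    from phyloseed.patterns import mask_to_bits

    for _ in range(20):
        mask = int(rng.integers(0, 2**10))
        assert bits_to_mask(mask_to_bits(mask, 10)) == mask
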