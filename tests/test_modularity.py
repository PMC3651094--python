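"""Spectral modularity: implicit operator, power iteration, division queue."""

import numpy as np
import pytest

from voxconn import modularity
from voxconn.graph import BinaryGraph
from voxconn.synth import gen_graph
from conftest import all_set_partitions, brute_force_Q, random_graph


def dense_B(g: BinaryGraph) -> np.ndarray:
    a = g.to_dense()
    k = a.sum(axis=1)
    return a - np.outer(k, k) / k.sum()


class _DiagonalOperator:
    """Stand-in operator with a prescribed spectrum."""

    def __init__(self, spectrum):
        self.d = np.asarray(spectrum, dtype=np.float64)
        self.n = self.d.size

    def matvec(self, x):
        return self.d * x


class TestOperator:
    def test_ones_vector_in_null_space(self):
        g = random_graph(12, 0.3, seed=0)
        op = modularity.ModularityOperator(g)
        np.testing.assert_allclose(op.matvec(np.ones(12)), 0.0, atol=1e-9)

    def test_matches_dense_B(self, rng):
        g = random_graph(6, 0.5, seed=1)
        op = modularity.ModularityOperator(g)
        b = dense_B(g)
        for _ in range(5):
            x = rng.normal(size=6)
            np.testing.assert_allclose(op.matvec(x), b @ x, atol=1e-10)

    def test_restricted_rows_sum_to_zero(self):
        g = random_graph(10, 0.4, seed=2)
        sub = np.array([0, 2, 3, 7, 9])
        op = modularity.ModularityOperator(g, restrict=sub)
        np.testing.assert_allclose(op.matvec(np.ones(5)), 0.0, atol=1e-9)

    def test_restricted_matches_generalized_dense(self, rng):
        g = random_graph(9, 0.4, seed=3)
        sub = np.array([1, 2, 4, 6, 8])
        b = dense_B(g)[np.ix_(sub, sub)]
        b -= np.diag(b.sum(axis=1))
        op = modularity.ModularityOperator(g, restrict=sub)
        x = rng.normal(size=5)
        np.testing.assert_allclose(op.matvec(x), b @ x, atol=1e-10)

    def test_length_mismatch(self):
        op = modularity.ModularityOperator(random_graph(5, 0.6, seed=4))
        with pytest.raises(ValueError):
            op.matvec(np.ones(4))


class TestPowerMethod:
    def test_returns_most_positive_not_dominant(self):
        # dominant magnitude is -5; the shift pass must recover 3
        res = modularity.power_method(_DiagonalOperator([3.0, 1.0, -5.0]), seed=7)
        assert res.converged
        assert res.beta == pytest.approx(3.0, abs=1e-6)

    def test_degenerate_top_eigenvalue(self):
        res = modularity.power_method(_DiagonalOperator([2.0, 2.0, 0.0]), seed=1)
        assert res.converged
        assert res.beta == pytest.approx(2.0, abs=1e-6)

    def test_two_cliques_eigenpair_vs_dense_solver(self):
        g = gen_graph("two_cliques", n=3)
        res = modularity.power_method(modularity.ModularityOperator(g), seed=3)
        evals = np.linalg.eigvalsh(dense_B(g))
        assert res.beta == pytest.approx(evals[-1], abs=1e-6)
        assert res.beta > 0
        signs = np.sign(res.x)
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    def test_unconverged_flag(self):
        res = modularity.power_method(_DiagonalOperator([1.0, -1.0, 0.5]),
                                      max_iter=5, seed=0)
        assert not res.converged


class TestQ:
    def test_single_module_is_zero(self):
        g = random_graph(8, 0.4, seed=5)
        assert modularity.modularity_Q(g, np.zeros(8)) == pytest.approx(0.0)

    def test_two_cliques_truth(self):
        g = gen_graph("two_cliques", n=3)
        labels = [0, 0, 0, 1, 1, 1]
        assert modularity.modularity_Q(g, labels) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(8, 0.45, seed + 100)
        if g.M == 0:
            pytest.skip("empty graph drawn")
        labels = rng.integers(0, 3, size=8)
        assert modularity.modularity_Q(g, labels) == pytest.approx(
            brute_force_Q(g, labels), abs=1e-12)


class TestSpectralDivide:
    def test_two_cliques_exact_partition(self):
        g = gen_graph("two_cliques", n=3)
        part = modularity.spectral_divide(g, seed=0)
        assert part.module_count == 2
        assert part.Q == pytest.approx(0.5)
        assert len(set(part.labels[:3])) == 1 and part.labels[0] != part.labels[3]

    def test_complete_graph_stays_whole(self):
        part = modularity.spectral_divide(gen_graph("complete", n=5), seed=0)
        assert part.module_count == 1
        assert part.Q == pytest.approx(0.0)

    def test_planted_partition_recovery(self):
        g = gen_graph("planted_partition", sizes=[10] * 4, p_in=0.9, p_out=0.05,
                      seed=7)
        part = modularity.spectral_divide(g, seed=2)
        planted = np.repeat(np.arange(4), 10)
        # same partition up to relabeling: the label pairing is a bijection
        pairs = set(zip(part.labels.tolist(), planted.tolist()))
        assert part.module_count == 4 and len(pairs) == 4

    @pytest.mark.parametrize("fixture,n", [("two_cliques", 3), ("barbell", 4)])
    def test_attains_exhaustive_optimum(self, fixture, n):
        g = gen_graph(fixture, n=n)
        part = modularity.spectral_divide(g, seed=1)
        best = max(brute_force_Q(g, labels)
                   for labels in all_set_partitions(g.N))
        assert part.Q == pytest.approx(best, abs=1e-12)

    def test_every_split_increases_Q(self):
        g = gen_graph("planted_partition", sizes=[8] * 3, p_in=0.8, p_out=0.1,
                      seed=3)
        part = modularity.spectral_divide(g, seed=4)
        assert part.Q >= 0.0
        # the committed partition cannot be beaten by undoing any merge of
        # two of its modules (each accepted split had positive gain)
        for a in range(part.module_count):
            for b in range(a + 1, part.module_count):
                merged = part.labels.copy()
                merged[merged == b] = a
                assert modularity.modularity_Q(g, merged) < part.Q

    def test_determinism_under_seed(self):
        g = random_graph(40, 0.15, seed=9)
        p1 = modularity.spectral_divide(g, seed=11)
        p2 = modularity.spectral_divide(g, seed=11)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.Q == p2.Q

    @pytest.mark.parametrize("seed", range(10))
    def test_small_random_graphs_Q_nonnegative(self, seed):
        g = random_graph(10, 0.35, seed + 200)
        if g.M == 0:
            pytest.skip("empty graph drawn")
        part = modularity.spectral_divide(g, seed=seed)
        assert part.Q >= -1e-12
        assert part.Q == pytest.approx(brute_force_Q(g, part.labels), abs=1e-12)


class TestZScore:
    def test_null_mean_gives_zero(self):
        assert modularity.modularity_zscore(0.2, [0.1, 0.2, 0.3]) == pytest.approx(0.0)

    def test_hand_computation(self):
        assert modularity.modularity_zscore(0.8, [0.1, 0.2, 0.3]) == pytest.approx(6.0)

    def test_shift_invariance(self):
        nulls = [0.11, 0.15, 0.19, 0.21]
        z1 = modularity.modularity_zscore(0.7, nulls)
        z2 = modularity.modularity_zscore(0.7 + 5, [v + 5 for v in nulls])
        assert z1 == pytest.approx(z2)

    def test_zero_spread_error(self):
        with pytest.raises(ValueError, match="spread"):
            modularity.modularity_zscore(0.5, [0.2, 0.2])
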