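"""Network construction: normalization, blocked correlation, thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from voxconn import construct
from voxconn.io import TimeSeriesSet


class TestNormalize:
    def test_single_column_oracle(self):
        # (1,2,3) centers to (-1,0,1), norm sqrt(2)
        u = construct.normalize_series(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            u.U[:, 0], [-1 / math.sqrt(2), 0, 1 / math.sqrt(2)], atol=1e-12)

    def test_inner_products_are_pearson(self, rng):
        data = rng.normal(size=(30, 8))
        u = construct.normalize_series(data)
        np.testing.assert_allclose(u.U.T @ u.U, np.corrcoef(data.T), atol=1e-9)

    def test_identical_and_negated_columns(self, rng):
        col = rng.normal(size=20)
        u = construct.normalize_series(np.stack([col, col, -col], axis=1))
        r = u.U.T @ u.U
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert r[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_column_invariants(self, rng):
        u = construct.normalize_series(rng.normal(size=(50, 10)))
        assert np.all(np.abs(u.U.sum(axis=0)) < 1e-9 * 50)
        assert np.all(np.abs(np.linalg.norm(u.U, axis=0) - 1) < 1e-9)

    def test_constant_column_is_named_error(self, rng):
        data = rng.normal(size=(10, 3))
        data[:, 1] = 7.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            construct.normalize_series(data)


class TestBlockedCorrelation:
    def test_block_count_n5_bs2(self, rng):
        u = construct.normalize_series(rng.normal(size=(10, 5)))
        blocks = list(construct.blocked_correlation(u, block_size=2))
        assert len(blocks) == 6  # 3 column blocks -> 3*4/2 upper tiles

    def test_single_block_when_bs_ge_n(self, rng):
        u = construct.normalize_series(rng.normal(size=(10, 4)))
        blocks = list(construct.blocked_correlation(u, block_size=4))
        assert len(blocks) == 1
        assert blocks[0].values.shape == (4, 4)

    @pytest.mark.parametrize("block_size", [1, 3, 7, 30])
    def test_assembled_equals_dense_product(self, rng, block_size):
        data = rng.normal(size=(20, 30))
        u = construct.normalize_series(data)
        assembled = construct.assemble_correlation(
            construct.blocked_correlation(u, block_size), 30)
        np.testing.assert_allclose(assembled, np.corrcoef(data.T), atol=1e-9)

    def test_blocks_tile_upper_triangle_once(self, rng):
        u = construct.normalize_series(rng.normal(size=(10, 7)))
        seen = np.zeros((7, 7), dtype=int)
        for b in construct.blocked_correlation(u, block_size=3):
            assert b.col_range[0] >= b.row_range[0]
            seen[b.row_range[0]:b.row_range[1], b.col_range[0]:b.col_range[1]] += 1
        iu = np.triu_indices(7)
        assert np.all(seen[iu] >= 1)


class TestGroupAverage:
    def test_identity_and_cancellation(self, rng):
        r = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(construct.group_average([r]), r)
        np.testing.assert_allclose(construct.group_average([r, -r]),
                                   np.zeros((4, 4)), atol=1e-15)

    def test_elementwise_mean(self, rng):
        mats = [rng.normal(size=(5, 5)) for _ in range(3)]
        np.testing.assert_allclose(construct.group_average(mats),
                                   (mats[0] + mats[1] + mats[2]) / 3)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            construct.group_average([np.eye(2), np.eye(3)])


class TestSparsityBounds:
    def test_closed_form_small_n(self):
        assert construct.sparsity_lower_bound(3) == pytest.approx(math.log(3) / 2)
        with pytest.raises(ValueError):
            construct.sparsity_lower_bound(2)

    def test_monotone_decreasing_in_n(self):
        ns = np.unique(np.geomspace(3, 10 ** 6, 200).astype(int))
        vals = [construct.sparsity_lower_bound(int(n)) for n in ns]
        assert np.all(np.diff(vals) < 0)

    def test_bonferroni_inverts_t_relation(self):
        # independent check: plug r_crit back through the t transform
        import scipy.stats
        n, L, alpha = 200, 120, 0.05
        r = construct.bonferroni_threshold(n, L, alpha)
        df = L - 2
        t = r * math.sqrt(df / (1 - r ** 2))
        p = 2 * scipy.stats.t.sf(t, df)
        assert p == pytest.approx(alpha / (n * (n - 1) / 2), rel=1e-9)

    def test_single_test_high_alpha_limit(self):
        # N=2 -> one test; alpha -> 1 drives the critical r to 0
        assert construct.bonferroni_threshold(2, 50, alpha=1 - 1e-9) < 1e-4

    def test_rcrit_increases_with_n(self):
        vals = [construct.bonferroni_threshold(n, 100) for n in (10, 100, 1000, 10000)]
        assert np.all(np.diff(vals) > 0)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            construct.bonferroni_threshold(10, 50, alpha=0.0)

    def test_montecarlo_null_exceedance(self, rng):
        # 1e5 independent Gaussian pairs of length 50: the fraction with
        # |r| above the critical value should match the nominal level.
        L, n_pairs, alpha = 50, 100_000, 0.05
        a = rng.standard_normal((n_pairs, L))
        b = rng.standard_normal((n_pairs, L))
        a -= a.mean(axis=1, keepdims=True)
        b -= b.mean(axis=1, keepdims=True)
        r = np.sum(a * b, axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        r_crit = construct.bonferroni_threshold(2, L, alpha=alpha)  # single test
        rate = np.mean(np.abs(r) > r_crit)
        se = math.sqrt(alpha * (1 - alpha) / n_pairs)
        assert abs(rate - alpha) < 3 * se


class TestBinarize:
    def test_threshold_counts_edges(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.2
        r[1, 2] = r[2, 1] = 0.5
        g = construct.binarize(r, 0.45)
        assert g.M == 2
        assert g.has_edge(0, 1) and g.has_edge(1, 2) and not g.has_edge(0, 2)

    def test_extreme_thresholds(self, rng):
        data = rng.normal(size=(30, 6))
        r = np.corrcoef(data.T)
        off = r[np.triu_indices(6, 1)]
        assert construct.binarize(r, off.max()).M == 0
        assert construct.binarize(r, off.min() - 1e-9).M == 6 * 5 // 2

    def test_asymmetric_rejected(self):
        r = np.eye(3)
        r[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            construct.binarize(r, 0.1)

    def test_diagonal_ignored(self):
        g = construct.binarize(np.eye(4), 0.5)
        assert g.M == 0

    @given(st.floats(min_value=-1, max_value=1), st.integers(0, 10 ** 6))
    def test_sparsity_nonincreasing_in_threshold(self, thr, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(15, 8))
        r = np.corrcoef(data.T)
        s_lo = construct.sparsity(construct.binarize(r, thr))
        s_hi = construct.sparsity(construct.binarize(r, min(thr + 0.1, 1.0)))
        assert s_hi <= s_lo


class TestSparsity:
    def test_known_values(self):
        from voxconn.synth import gen_graph
        assert construct.sparsity(gen_graph("complete", n=5)) == 1.0
        from voxconn.graph import BinaryGraph
        assert construct.sparsity(BinaryGraph.from_edges(4, [])) == 0.0
        # K3 plus an isolated node: 3 edges of 6 possible
        k3_iso = BinaryGraph.from_edges(4, [(0, 1), (0, 2), (1, 2)])
        assert construct.sparsity(k3_iso) == 0.5
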