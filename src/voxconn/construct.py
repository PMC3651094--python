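"""From time series to thresholded binary networks.

The construction follows the standard functional-connectome recipe:
each node's time course is centered and scaled to unit norm so that the
full Pearson matrix is the single matrix product ``R = U^T U``; the
product is evaluated block-by-block over the upper triangle so peak
dense storage never exceeds one block; per-subject matrices are averaged
element-wise into a group matrix; and the group matrix is binarized by a
correlation threshold ``R_ij > r`` into a simple undirected graph.

Two analytic quantities bound the useful sparsity range of the
thresholded graphs:

* a lower bound ``S1 = ln(N)/(N-1)`` from the requirement that the mean
  degree exceed ``ln N`` (below which small-world estimates degrade);
* a critical correlation ``r_crit`` at which an edge is significant at
  level ``alpha`` after Bonferroni correction over all ``N(N-1)/2``
  pairs, via the exact t-transform of a Pearson coefficient with
  ``L - 2`` degrees of freedom.  The sparsity actually achieved at
  ``r_crit`` (the upper bound ``S2``) depends on the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import scipy.stats

from .graph import BinaryGraph
from .io import TimeSeriesSet

__all__ = [
    "NormalizedSeries",
    "CorrelationBlock",
    "normalize_series",
    "blocked_correlation",
    "assemble_correlation",
    "correlation_matrix",
    "group_average",
    "sparsity_lower_bound",
    "bonferroni_threshold",
    "binarize",
    "sparsity",
]

DEFAULT_BLOCK_SIZE = 2048  # columns per correlation block


@dataclass
class NormalizedSeries:
    """L x N matrix whose columns are centered, unit-norm time courses."""

    U: np.ndarray

    @property
    def N(self) -> int:
        return self.U.shape[1]

    @property
    def L(self) -> int:
        return self.U.shape[0]


@dataclass
class CorrelationBlock:
    """One dense tile of the upper block-triangle of ``R = U^T U``."""

    row_range: tuple
    col_range: tuple
    values: np.ndarray


def normalize_series(ts: TimeSeriesSet | np.ndarray) -> NormalizedSeries:
    """Center each column and scale it to unit Euclidean norm.

    After normalization ``U^T U`` is exactly the pairwise Pearson
    correlation matrix.  A constant (zero-variance) column is a hard
    error — dropping it silently would desynchronize the node indexing
    from the voxel mask.
    """
    data = ts.data if isinstance(ts, TimeSeriesSet) else np.asarray(ts, dtype=np.float64)
    centered = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        raise ValueError(f"constant time series at node(s) {bad[:10].tolist()}")
    return NormalizedSeries(U=centered / norms)


def blocked_correlation(u: NormalizedSeries, block_size: int = DEFAULT_BLOCK_SIZE
                        ) -> Iterator[CorrelationBlock]:
    """Yield the upper block-triangle of ``R = U^T U`` one dense tile at a time.

    With ``b = ceil(N / block_size)`` column blocks, exactly
    ``b(b+1)/2`` tiles are produced (block pairs with
    ``col_block >= row_block``), tiling the upper triangle of R once.
    Only one tile is dense in memory at a time.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    U = u.U
    n = U.shape[1]
    starts = list(range(0, n, block_size))
    for bi, ri in enumerate(starts):
        r_end = min(ri + block_size, n)
        for rj in starts[bi:]:
            c_end = min(rj + block_size, n)
            vals = U[:, ri:r_end].T @ U[:, rj:c_end]
            np.clip(vals, -1.0, 1.0, out=vals)
            yield CorrelationBlock(row_range=(ri, r_end),
                                   col_range=(rj, c_end), values=vals)


def assemble_correlation(blocks, n: int) -> np.ndarray:
    """Mirror a stream of upper-triangle blocks into the full N x N matrix."""
    r = np.empty((n, n), dtype=np.float64)
    for b in blocks:
        i0, i1 = b.row_range
        j0, j1 = b.col_range
        r[i0:i1, j0:j1] = b.values
        if (i0, i1) != (j0, j1):
            r[j0:j1, i0:i1] = b.values.T
    return r


def correlation_matrix(ts: TimeSeriesSet | np.ndarray,
                       block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
    """Full Pearson matrix of a time-series set via the blocked path."""
    u = normalize_series(ts)
    return assemble_correlation(blocked_correlation(u, block_size), u.N)


def group_average(matrices: Sequence[np.ndarray], fisher_z: bool = False) -> np.ndarray:
    """Element-wise mean of same-shape correlation matrices.

    The plain arithmetic mean of r values is the default; ``fisher_z``
    averages arctanh-transformed values instead and transforms back
    (diagonal pinned to 1).
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    shape = np.asarray(matrices[0]).shape
    for m in matrices[1:]:
        if np.asarray(m).shape != shape:
            raise ValueError("correlation matrices differ in shape")
    if not fisher_z:
        out = np.zeros(shape, dtype=np.float64)
        for m in matrices:
            out += np.asarray(m, dtype=np.float64)
        return out / len(matrices)
    acc = np.zeros(shape, dtype=np.float64)
    for m in matrices:
        z = np.arctanh(np.clip(np.asarray(m, dtype=np.float64), -1 + 1e-15, 1 - 1e-15))
        acc += z
    out = np.tanh(acc / len(matrices))
    if shape[0] == shape[1]:
        np.fill_diagonal(out, 1.0)
    return out


def sparsity_lower_bound(n_nodes: int) -> float:
    """Sparsity at which the mean degree equals ``ln N``: ``ln(N)/(N-1)``.

    Below this the mean degree falls under ``ln N`` and small-world
    properties become unreliable to estimate.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    return math.log(n_nodes) / (n_nodes - 1)


def bonferroni_threshold(n_nodes: int, n_timepoints: int, alpha: float = 0.05) -> float:
    """Critical Pearson r at Bonferroni-corrected two-tailed significance.

    The per-test level is ``alpha / (N(N-1)/2)``; the critical t with
    ``df = L - 2`` is inverted through ``t = r sqrt(df / (1 - r^2))`` to
    give ``r_crit = t / sqrt(df + t^2)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_timepoints < 5:
        raise ValueError("need at least 5 time points")
    n_tests = max(n_nodes * (n_nodes - 1) // 2, 1)
    per_test = alpha / n_tests
    df = n_timepoints - 2
    t_crit = scipy.stats.t.isf(per_test / 2.0, df)
    return float(t_crit / math.sqrt(df + t_crit ** 2))


def binarize(r: np.ndarray, r_threshold: float, tol: float = 1e-9) -> BinaryGraph:
    """Threshold a symmetric correlation matrix into a binary graph.

    Edge (i, j), i != j, is present iff ``R_ij > r_threshold`` (strict);
    the diagonal is ignored.  Asymmetry beyond ``tol`` is an error.
    """
    r = np.asarray(r, dtype=np.float64)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=tol, rtol=0):
        raise ValueError("correlation matrix is not symmetric")
    a = np.triu(r > r_threshold, 1)
    ii, jj = np.nonzero(a)
    return BinaryGraph.from_edges(r.shape[0], np.stack([ii, jj], axis=1))


def sparsity(g: BinaryGraph) -> float:
    """Fraction of realized edges: ``2M / (N(N-1))`` = mean degree / (N-1)."""
    if g.N < 2:
        raise ValueError("sparsity needs at least 2 nodes")
    return 2.0 * g.M / (g.N * (g.N - 1))
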