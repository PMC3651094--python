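"""Core binary-graph container.

A :class:`BinaryGraph` is a simple (no self-loops, no multi-edges),
undirected, unweighted graph stored in compressed neighbor-list (CSR)
form.  Both directions of every edge are stored so that neighbor lookup
is a contiguous slice; neighbor lists are kept sorted so membership
tests are a binary search and serialization is canonical.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["BinaryGraph"]


class BinaryGraph:
    """Simple undirected unweighted graph in CSR neighbor-list form.

    Parameters
    ----------
    n_nodes:
        Number of nodes ``N``.  Nodes are the integers ``0..N-1``.
    indptr, indices:
        CSR structure of the (symmetric) adjacency matrix: the neighbors
        of node ``i`` are ``indices[indptr[i]:indptr[i+1]]``, sorted
        ascending.

    Use :meth:`from_edges` or :meth:`from_dense` rather than the raw
    constructor; they validate simplicity and apply symmetric closure.
    """

    __slots__ = ("N", "indptr", "indices", "rewire_saturated")

    def __init__(self, n_nodes: int, indptr: np.ndarray, indices: np.ndarray):
        self.N = int(n_nodes)
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int64)
        #: set by maslov_rewire when the proposal cap was hit
        self.rewire_saturated = False

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_edges(cls, n_nodes: int, edges, *, allow_duplicates: bool = False) -> "BinaryGraph":
        """Build from an iterable of ``(i, j)`` pairs.

        Symmetric closure is applied (each pair yields both directions).
        Self-loops raise; duplicate undirected edges raise unless
        ``allow_duplicates`` (then they collapse silently).
        """
        e = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                       dtype=np.int64)
        if e.size == 0:
            e = e.reshape(0, 2)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be (M, 2)")
        if e.size and (e.min() < 0 or e.max() >= n_nodes):
            raise ValueError("edge endpoint out of range")
        if np.any(e[:, 0] == e[:, 1]):
            bad = e[e[:, 0] == e[:, 1]][0]
            raise ValueError(f"self-loop on node {int(bad[0])} is not allowed")
        lo = np.minimum(e[:, 0], e[:, 1])
        hi = np.maximum(e[:, 0], e[:, 1])
        canon = np.unique(np.stack([lo, hi], axis=1), axis=0)
        if not allow_duplicates and canon.shape[0] != e.shape[0]:
            raise ValueError("duplicate edge(s) in input")
        both = np.concatenate([canon, canon[:, ::-1]], axis=0) if canon.size else canon
        order = np.lexsort((both[:, 1], both[:, 0])) if both.size else np.array([], np.int64)
        both = both[order] if both.size else both.reshape(0, 2)
        counts = np.bincount(both[:, 0], minlength=n_nodes) if both.size else np.zeros(n_nodes, np.int64)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        return cls(n_nodes, indptr, both[:, 1] if both.size else np.array([], np.int64))

    @classmethod
    def from_dense(cls, a: np.ndarray) -> "BinaryGraph":
        """Build from a dense boolean/0-1 adjacency matrix (symmetrized by OR)."""
        a = np.asarray(a) != 0
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = a | a.T
        np.fill_diagonal(a, False)
        ii, jj = np.nonzero(np.triu(a, 1))
        return cls.from_edges(a.shape[0], np.stack([ii, jj], axis=1))

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def M(self) -> int:
        """Edge count."""
        return self.indices.size // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def has_edge(self, i: int, j: int) -> bool:
        nb = self.neighbors(i)
        pos = np.searchsorted(nb, j)
        return pos < nb.size and nb[pos] == j

    def edge_array(self) -> np.ndarray:
        """All edges as an (M, 2) array with ``i < j``, lexicographically sorted."""
        src = np.repeat(np.arange(self.N, dtype=np.int64), self.degrees)
        keep = src < self.indices
        return np.stack([src[keep], self.indices[keep]], axis=1)

    def to_scipy_sparse(self) -> sp.csr_matrix:
        data = np.ones(self.indices.size, dtype=np.float64)
        return sp.csr_matrix((data, self.indices, self.indptr), shape=(self.N, self.N))

    def to_dense(self) -> np.ndarray:
        return self.to_scipy_sparse().toarray()

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryGraph):
            return NotImplemented
        return (self.N == other.N
                and np.array_equal(self.indptr, other.indptr)
                and np.array_equal(self.indices, other.indices))

    def __hash__(self):  # graphs are mutable only in principle; keep unhashable
        raise TypeError("BinaryGraph is not hashable")

    def __repr__(self) -> str:
        return f"BinaryGraph(N={self.N}, M={self.M})"
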