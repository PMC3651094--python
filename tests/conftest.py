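"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (textbook Floyd-Warshall,
exhaustive double sums, full set-partition enumeration) and never call
the code paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from voxconn.graph import BinaryGraph

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------

def naive_fw(g: BinaryGraph) -> np.ndarray:
    """Textbook O(N^3) Floyd-Warshall on a dense float matrix with np.inf."""
    n = g.N
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in g.edge_array():
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d


def brute_force_Q(g: BinaryGraph, labels) -> float:
    """Literal double sum (1/2m) sum_{ij same module} (A_ij - k_i k_j / 2m)."""
    a = g.to_dense()
    k = a.sum(axis=1)
    two_m = k.sum()
    labels = np.asarray(labels)
    q = 0.0
    for i in range(g.N):
        for j in range(g.N):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def triangle_count_brute(g: BinaryGraph, node: int) -> int:
    """Count edges among the neighbors of ``node`` by enumerating pairs."""
    nb = list(g.neighbors(node))
    return sum(1 for x in range(len(nb)) for y in range(x + 1, len(nb))
               if g.has_edge(nb[x], nb[y]))


def all_set_partitions(n: int):
    """Every partition of range(n) as a label array (restricted growth strings)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i, max_used):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_used + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_used, lab))

    yield from rec(1, 0) if n > 0 else iter([np.zeros(0, np.int64)])


def random_graph(n: int, p: float, seed: int) -> BinaryGraph:
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n, 1)
    keep = rng.random(ii.size) < p
    return BinaryGraph.from_edges(n, np.stack([ii[keep], jj[keep]], axis=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
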