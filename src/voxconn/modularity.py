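"""Newman spectral community detection.

Modularity of a partition ``g`` of a binary graph is

    Q = (1/2m) * sum_{ij} (A_ij - k_i k_j / 2m) * delta(g_i, g_j)

with ``m`` the edge count.  The best bisection of a (sub)network is
read off the sign pattern of the eigenvector belonging to the most
positive eigenvalue of the modularity matrix ``B = A - k k^T / 2m``
(for a subset ``g`` the generalized matrix subtracts the diagonal
correction ``d_i = sum_{j in g} B_ij``).  B is never materialized: the
operator applies ``A x - k (k^T x) / 2m`` with sparse products.  The
leading eigenpair comes from shifted power iteration, and a division
queue repeatedly bisects modules while a split keeps a positive leading
eigenvalue and strictly increases Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import BinaryGraph

__all__ = [
    "ModularityOperator",
    "EigenResult",
    "Partition",
    "apply_B",
    "power_method",
    "spectral_divide",
    "modularity_Q",
    "modularity_zscore",
]


class ModularityOperator:
    """Implicit (generalized) modularity matrix of a graph or node subset.

    For the whole graph the operator is ``B = A - k k^T / 2m``.
    Restricted to a subset g it is Newman's generalized matrix
    ``B^(g)_ij = B_ij - delta_ij * d_i`` with
    ``d_i = sum_{j in g} B_ij``, which keeps every row summing to zero
    so the all-ones vector stays in the null space.
    """

    def __init__(self, graph: BinaryGraph, restrict: np.ndarray | None = None):
        self.graph = graph
        self.adj = graph.to_scipy_sparse()
        self.k_full = graph.degrees.astype(np.float64)
        self.two_m = float(self.k_full.sum())
        if self.two_m == 0:
            raise ValueError("graph has no edges; modularity is undefined")
        if restrict is None:
            self.restrict = None
            self.k = self.k_full
            self.sub_adj = self.adj
            self.diag_correction = np.zeros(graph.N)
        else:
            restrict = np.asarray(restrict, dtype=np.int64)
            self.restrict = restrict
            self.k = self.k_full[restrict]
            self.sub_adj = self.adj[restrict][:, restrict].tocsr()
            # d_i = sum_{j in g} (A_ij - k_i k_j / 2m)
            a_row = np.asarray(self.sub_adj.sum(axis=1)).ravel()
            self.diag_correction = a_row - self.k * self.k.sum() / self.two_m

    @property
    def n(self) -> int:
        return self.k.size

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.size != self.n:
            raise ValueError(f"vector length {x.size} != operator size {self.n}")
        y = self.sub_adj @ x - self.k * (self.k @ x) / self.two_m
        if self.restrict is not None:
            y -= self.diag_correction * x
        return y


def apply_B(op: ModularityOperator, x: np.ndarray) -> np.ndarray:
    """Apply the (generalized) modularity operator to a vector."""
    return op.matvec(x)


@dataclass
class EigenResult:
    beta: float
    x: np.ndarray
    iterations: int
    converged: bool


@dataclass
class Partition:
    labels: np.ndarray
    Q: float

    @property
    def module_count(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _iterate(matvec, x: np.ndarray, tol: float, max_iter: int):
    """Power iteration; returns (eigenvalue, unit vector, iters, converged)."""
    beta = 0.0
    for it in range(1, max_iter + 1):
        y = matvec(x)
        beta = float(x @ y)
        resid = float(np.max(np.abs(y - beta * x)))
        if resid <= tol * max(1.0, abs(beta)):
            return beta, x, it, True
        ny = float(np.linalg.norm(y))
        if ny == 0.0:  # x in the null space and nothing dominant: eigenvalue 0
            return 0.0, x, it, True
        x = y / ny
    return beta, x, max_iter, False


def power_method(op, tol: float = 1e-8, max_iter: int = 10000,
                 seed: int = 0) -> EigenResult:
    """Most positive eigenvalue (and eigenvector) of a symmetric operator.

    ``op`` needs only ``.n`` and ``.matvec``.  Strategy: plain power
    iteration converges to the dominant-magnitude eigenvalue; if that
    value is negative, a second pass on the shifted operator
    ``B + |beta_1| I`` (whose spectrum is non-negative and ordered like
    B's) isolates the algebraically largest eigenvalue, which is shifted
    back.  The start vector is seeded uniform noise orthogonalized
    against the all-ones vector (always in B's null space).
    """
    n = op.n
    if n < 1:
        raise ValueError("operator must act on at least one node")
    if n == 1:
        return EigenResult(beta=float(op.matvec(np.ones(1))[0]),
                           x=np.ones(1), iterations=0, converged=True)
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(-1.0, 1.0, n)
    x0 -= x0.mean()
    nrm = np.linalg.norm(x0)
    if nrm == 0.0:
        x0 = np.zeros(n)
        x0[0], x0[1] = 1.0, -1.0
        nrm = np.sqrt(2.0)
    x0 /= nrm

    beta1, x1, it1, conv1 = _iterate(op.matvec, x0.copy(), tol, max_iter)
    if conv1 and beta1 >= 0.0:
        return EigenResult(beta=beta1, x=x1, iterations=it1, converged=True)
    # shift the spectrum up by the dominant magnitude and re-run
    shift = abs(beta1)
    shifted = lambda v: op.matvec(v) + shift * v
    beta2, x2, it2, conv2 = _iterate(shifted, x0.copy(), tol, max_iter)
    return EigenResult(beta=beta2 - shift, x=x2, iterations=it1 + it2,
                       converged=conv2)


def modularity_Q(g: BinaryGraph, labels) -> float:
    """Exact Q of a labeling, both orientations (and the diagonal term) counted.

    Equivalent to the double sum ``(1/2m) sum_{i,j: g_i=g_j}
    (A_ij - k_i k_j/2m)``; evaluated per module as
    ``sum_c [ 2 m_c / 2m - (K_c / 2m)^2 ]`` with m_c the intra-module
    edge count and K_c the module's total degree.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size != g.N:
        raise ValueError("one label per node required")
    two_m = 2.0 * g.M
    if two_m == 0:
        raise ValueError("graph has no edges; modularity is undefined")
    edges = g.edge_array()
    k = g.degrees.astype(np.float64)
    q = 0.0
    for lab in np.unique(labels):
        members = labels == lab
        intra = np.count_nonzero(members[edges[:, 0]] & members[edges[:, 1]])
        ktot = float(k[members].sum())
        q += 2.0 * intra / two_m - (ktot / two_m) ** 2
    return q


def spectral_divide(g: BinaryGraph, tol: float = 1e-8, seed: int = 0,
                    max_iter: int = 10000) -> Partition:
    """Queue-driven recursive spectral bisection.

    Starting from the whole network as one module, repeatedly dequeue a
    module, compute the leading eigenpair of its generalized modularity
    operator, and split it by eigenvector sign when the eigenvalue is
    positive, both sign groups are nonempty, and the exactly evaluated
    modularity gain is positive; the two halves are enqueued.  Entries
    exactly 0 join the positive group.  Deterministic for a fixed seed.
    """
    if g.N < 1:
        raise ValueError("graph must have at least one node")
    labels = np.zeros(g.N, dtype=np.int64)
    if g.M == 0:
        return Partition(labels=labels, Q=0.0)
    queue: list = [np.arange(g.N, dtype=np.int64)]
    final_modules: list = []
    q_current = modularity_Q(g, labels)
    draw = 0
    while queue:
        members = queue.pop(0)
        if members.size < 2:
            final_modules.append(members)
            continue
        op = ModularityOperator(g, restrict=None if members.size == g.N else members)
        res = power_method(op, tol=tol, max_iter=max_iter, seed=seed + draw)
        draw += 1
        if not (res.converged and res.beta > tol):
            final_modules.append(members)
            continue
        pos = res.x >= 0.0  # exact zeros join the positive group
        g1, g2 = members[pos], members[~pos]
        if g1.size == 0 or g2.size == 0:
            final_modules.append(members)
            continue
        # exact gain check before committing the split
        trial = labels.copy()
        new_label = labels.max() + 1
        trial[g2] = new_label
        q_trial = modularity_Q(g, trial)
        if q_trial <= q_current:
            final_modules.append(members)
            continue
        labels = trial
        q_current = q_trial
        queue.append(g1)
        queue.append(g2)
    # compact labels to 0..K-1 in first-appearance order
    out = np.empty(g.N, dtype=np.int64)
    remap: dict = {}
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(int(lab), len(remap))
    return Partition(labels=out, Q=modularity_Q(g, out))


def modularity_zscore(q_real: float, q_null) -> float:
    """(Q_real - mean(Q_null)) / sd(Q_null), with the sample (n-1) sd."""
    q_null = np.asarray(q_null, dtype=np.float64)
    if q_null.size < 2:
        raise ValueError("need at least 2 null values")
    sd = float(q_null.std(ddof=1))
    if sd == 0.0:
        raise ValueError("null distribution has zero spread")
    return (q_real - float(q_null.mean())) / sd
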