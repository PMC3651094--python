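"""Degree-preserving null networks (Maslov–Sneppen rewiring).

A null network keeps every node's degree while randomizing the
topology: repeatedly pick two distinct edges (a, b) and (c, d), propose
the swap to (a, d) and (c, b), and accept only when no self-loop and no
duplicate edge would result.  Rewiring continues until a target number
of successful swaps per edge is reached (or a proposal cap is hit, in
which case the partially rewired graph is returned and flagged).
Ensembles of such nulls provide the reference clustering coefficient,
path length and modularity used by the small-world indices and the
modularity z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import BinaryGraph
from .metrics import apsp_bfs, apsp_blocked_fw, characteristic_path_length, clustering
from .modularity import modularity_Q, spectral_divide

__all__ = ["EnsembleSummary", "maslov_rewire", "ensemble_summary"]

DEFAULT_SWAPS_PER_EDGE = 10.0
DEFAULT_N_NETWORKS = 15
_ATTEMPT_FACTOR = 100  # proposal cap = factor * target successful swaps


@dataclass
class EnsembleSummary:
    """Means and sample sds of Cp/Lp (and optional Q) over rewired nulls."""

    n_networks: int
    Cp_rand: np.ndarray
    Lp_rand: np.ndarray
    Q_rand: np.ndarray | None
    seeds: list
    degenerate_sd: bool = False

    @property
    def Cp_rand_mean(self) -> float:
        return float(self.Cp_rand.mean())

    @property
    def Cp_rand_sd(self) -> float:
        return float(self.Cp_rand.std(ddof=1)) if self.n_networks > 1 else 0.0

    @property
    def Lp_rand_mean(self) -> float:
        return float(self.Lp_rand.mean())

    @property
    def Lp_rand_sd(self) -> float:
        return float(self.Lp_rand.std(ddof=1)) if self.n_networks > 1 else 0.0


def maslov_rewire(g: BinaryGraph, swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
                  seed: int = 0) -> BinaryGraph:
    """Degree-preserving random rewiring of a simple graph.

    Performs ``swaps_per_edge * M`` successful double-edge swaps.  Each
    proposal draws two distinct edges uniformly (the second in a
    uniformly random orientation) and swaps their endpoints; proposals
    creating a self-loop or duplicate edge are rejected, so the degree
    sequence, the edge count, and simplicity are all invariant.  If the
    proposal cap (100x the target) is reached first, the current graph
    is returned with ``rewire_saturated`` set and a warning.
    """
    if g.M < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    edges = g.edge_array().copy()  # (M, 2)
    m = edges.shape[0]
    edge_set = {(int(i), int(j)) for i, j in edges}
    target = int(round(swaps_per_edge * m))
    cap = _ATTEMPT_FACTOR * max(target, 1)
    successes = 0
    attempts = 0
    while successes < target and attempts < cap:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(0, 2):  # random orientation of the second edge
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    out = BinaryGraph.from_edges(g.N, edges)
    if successes < target:
        out.rewire_saturated = True
        warnings.warn(
            f"rewiring saturated: {successes}/{target} swaps after {attempts} proposals",
            RuntimeWarning, stacklevel=2)
    return out


def ensemble_summary(g: BinaryGraph, n: int = DEFAULT_N_NETWORKS, base_seed: int = 0,
                     swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
                     with_q: bool = False, apsp: str = "bfs",
                     block_n: int = 64) -> EnsembleSummary:
    """Cp/Lp (optionally Q) statistics over ``n`` independent rewired nulls.

    Null ``i`` is generated with seed ``base_seed + i`` so each member
    is individually reproducible.  With ``n = 1`` the sample sd is
    undefined and reported as 0 with ``degenerate_sd`` set.
    """
    if n < 1:
        raise ValueError("need at least one null network")
    seeds = [base_seed + i for i in range(n)]
    cps = np.empty(n)
    lps = np.empty(n)
    qs = np.empty(n) if with_q else None
    for i, s in enumerate(seeds):
        null = maslov_rewire(g, swaps_per_edge=swaps_per_edge, seed=s)
        _, cps[i] = clustering(null)
        dm = apsp_bfs(null) if apsp == "bfs" else apsp_blocked_fw(null, block_n)
        lps[i] = characteristic_path_length(dm)
        if with_q:
            qs[i] = spectral_divide(null, seed=s).Q
    return EnsembleSummary(n_networks=n, Cp_rand=cps, Lp_rand=lps, Q_rand=qs,
                           seeds=seeds, degenerate_sd=(n == 1))
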