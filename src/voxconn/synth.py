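"""Synthetic inputs: planted-structure time series and benchmark graphs.

The time-series generator emulates preprocessed multi-subject recordings
with a planted modular correlation structure: nodes fall into blocks,
every within-block pair has target correlation ``within_r`` and every
across-block pair ``between_r``, and samples are drawn from the
corresponding zero-mean Gaussian (positive semi-definiteness of the
block-constant covariance is checked before sampling).  Optional AR(1)
smoothing gives the series the band-limited temporal character of
filtered physiological signals without changing the cross-node
correlation structure; optional white subject noise attenuates all
correlations uniformly, emulating inter-subject variability.

Benchmark graphs (cliques, rings, lattices, ER, planted partitions,
barbells, ...) back the oracle tests of every downstream stage.  Every
generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import BinaryGraph
from .io import TimeSeriesSet, VoxelMask

__all__ = ["PlantedDesign", "gen_modular_timeseries", "gen_subject_set", "gen_graph"]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted modular correlation structure."""

    N: int = 100
    L: int = 2000
    n_modules: int = 4
    within_r: float = 0.9
    between_r: float = 0.0
    subject_noise_sd: float = 0.0
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.between_r <= self.within_r < 1.0):
            raise ValueError("require 0 <= between_r <= within_r < 1")
        if self.N < self.n_modules or self.n_modules < 1:
            raise ValueError("need at least one node per module")
        if self.L < 3:
            raise ValueError("need at least 3 time points")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")

    def module_labels(self) -> np.ndarray:
        """Planted module of each node (modules as equal as possible)."""
        sizes = np.full(self.n_modules, self.N // self.n_modules)
        sizes[: self.N % self.n_modules] += 1
        return np.repeat(np.arange(self.n_modules), sizes)

    def covariance(self) -> np.ndarray:
        labels = self.module_labels()
        same = labels[:, None] == labels[None, :]
        cov = np.where(same, self.within_r, self.between_r)
        np.fill_diagonal(cov, 1.0)
        return cov


def gen_modular_timeseries(design: PlantedDesign, seed: int | None = None,
                           subject_id: str = "sim") -> TimeSeriesSet:
    """Sample an L x N series with the design's block-constant covariance.

    Deterministic under (design, seed); ``seed`` defaults to
    ``design.seed``.  AR(1) smoothing, applied identically to every
    node, preserves the cross-node correlation structure in
    expectation.
    """
    cov = design.covariance()
    # PSD check before sampling
    min_eig = float(np.linalg.eigvalsh(cov).min())
    if min_eig < -1e-10:
        raise ValueError(f"design covariance is not PSD (min eigenvalue {min_eig:.3e})")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(design.N))
    z = rng.standard_normal((design.L, design.N))
    x = z @ chol.T
    if design.ar_coeff > 0.0:
        phi = design.ar_coeff
        for t in range(1, design.L):
            x[t] = phi * x[t - 1] + np.sqrt(1.0 - phi ** 2) * x[t]
    if design.subject_noise_sd > 0.0:
        x = x + design.subject_noise_sd * rng.standard_normal(x.shape)
    return TimeSeriesSet(data=x, subject_id=subject_id)


def gen_subject_set(design: PlantedDesign, n_subjects: int) -> list:
    """Independent per-subject series (seeds ``design.seed + 1 + i``)."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    return [gen_modular_timeseries(design, seed=design.seed + 1 + i,
                                   subject_id=f"sub-{i:03d}")
            for i in range(n_subjects)]


def timeseries_to_volume(ts: TimeSeriesSet, dims: tuple | None = None):
    """Pack a generic series into a 4-D volume plus mask (for I/O round trips).

    Nodes are laid out along the raster scan of a grid just large
    enough to hold them; returns ``(vol4d, mask)``.
    """
    n = ts.N
    if dims is None:
        side = int(np.ceil(n ** (1.0 / 3.0)))
        dims = (side, side, max(side, 1))
    total = int(np.prod(dims))
    if total < n:
        raise ValueError(f"grid {dims} too small for {n} nodes")
    vol = np.zeros(dims + (ts.L,), dtype=np.float64)
    coords = np.stack(np.unravel_index(np.arange(n), dims), axis=1)
    vol[tuple(coords.T)] = ts.data.T
    mask = VoxelMask(dims=dims, voxel_index=coords)
    return vol, mask


# ----------------------------------------------------------------------
# benchmark graphs
# ----------------------------------------------------------------------

def gen_graph(kind: str, seed: int = 0, **params) -> BinaryGraph:
    """Deterministic benchmark graph of the named kind.

    Kinds and parameters:
      complete(n); cycle(n); path(n); star(n leaves + center);
      er(n, p); ring_lattice(n, k neighbors per side);
      watts_strogatz(n, k, p rewire); planted_partition(sizes, p_in, p_out);
      two_cliques(n per clique); barbell(n per clique, single bridge).
    """
    try:
        builder = _BUILDERS[kind]
    except KeyError:
        raise ValueError(f"unknown graph kind {kind!r}; "
                         f"choose from {sorted(_BUILDERS)}") from None
    return builder(seed=seed, **params)


def _complete(n: int, seed: int = 0) -> BinaryGraph:
    if n < 1:
        raise ValueError("need n >= 1")
    ii, jj = np.triu_indices(n, 1)
    return BinaryGraph.from_edges(n, np.stack([ii, jj], axis=1))


def _cycle(n: int, seed: int = 0) -> BinaryGraph:
    if n < 3:
        raise ValueError("cycle needs n >= 3")
    i = np.arange(n)
    return BinaryGraph.from_edges(n, np.stack([i, (i + 1) % n], axis=1))


def _path(n: int, seed: int = 0) -> BinaryGraph:
    if n < 2:
        raise ValueError("path needs n >= 2")
    i = np.arange(n - 1)
    return BinaryGraph.from_edges(n, np.stack([i, i + 1], axis=1))


def _star(n: int, seed: int = 0) -> BinaryGraph:
    """Center node 0 plus n leaves."""
    if n < 1:
        raise ValueError("star needs at least one leaf")
    leaves = np.arange(1, n + 1)
    return BinaryGraph.from_edges(n + 1,
                                  np.stack([np.zeros(n, np.int64), leaves], axis=1))


def _er(n: int, p: float, seed: int = 0) -> BinaryGraph:
    if n < 1 or not 0.0 <= p <= 1.0:
        raise ValueError("er needs n >= 1 and p in [0, 1]")
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n, 1)
    keep = rng.random(ii.size) < p
    return BinaryGraph.from_edges(n, np.stack([ii[keep], jj[keep]], axis=1))


def _ring_lattice(n: int, k: int, seed: int = 0) -> BinaryGraph:
    """Ring of n nodes, each linked to its k nearest neighbors per side."""
    if n < 3 or k < 1 or 2 * k >= n:
        raise ValueError("ring lattice needs n >= 3 and 1 <= k < n/2")
    edges = []
    for off in range(1, k + 1):
        i = np.arange(n)
        edges.append(np.stack([i, (i + off) % n], axis=1))
    return BinaryGraph.from_edges(n, np.concatenate(edges))


def _watts_strogatz(n: int, k: int, p: float, seed: int = 0) -> BinaryGraph:
    """Ring lattice with each edge's far endpoint rewired with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("rewiring probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lattice = _ring_lattice(n, k)
    edge_set = {(int(a), int(b)) for a, b in lattice.edge_array()}
    for off in range(1, k + 1):
        for i in range(n):
            j = (i + off) % n
            e = (min(i, j), max(i, j))
            if e not in edge_set or rng.random() >= p:
                continue
            candidates = [w for w in range(n)
                          if w != i and (min(i, w), max(i, w)) not in edge_set]
            if not candidates:
                continue
            w = candidates[int(rng.integers(0, len(candidates)))]
            edge_set.discard(e)
            edge_set.add((min(i, w), max(i, w)))
    return BinaryGraph.from_edges(n, np.asarray(sorted(edge_set), dtype=np.int64))


def _planted_partition(sizes, p_in: float, p_out: float, seed: int = 0) -> BinaryGraph:
    sizes = [int(s) for s in np.atleast_1d(sizes)]
    if min(sizes) < 1 or not (0 <= p_out <= 1 and 0 <= p_in <= 1):
        raise ValueError("invalid planted-partition parameters")
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n, 1)
    p = np.where(labels[ii] == labels[jj], p_in, p_out)
    keep = rng.random(ii.size) < p
    return BinaryGraph.from_edges(n, np.stack([ii[keep], jj[keep]], axis=1))


def _two_cliques(n: int, seed: int = 0) -> BinaryGraph:
    """Two disconnected complete graphs of n nodes each."""
    if n < 2:
        raise ValueError("cliques need n >= 2")
    ii, jj = np.triu_indices(n, 1)
    e1 = np.stack([ii, jj], axis=1)
    return BinaryGraph.from_edges(2 * n, np.concatenate([e1, e1 + n]))


def _barbell(n: int, seed: int = 0) -> BinaryGraph:
    """Two n-cliques joined by a single bridge edge."""
    g = _two_cliques(n)
    edges = np.concatenate([g.edge_array(), [[n - 1, n]]])
    return BinaryGraph.from_edges(2 * n, edges)


_BUILDERS = {
    "complete": _complete,
    "cycle": _cycle,
    "path": _path,
    "star": _star,
    "er": _er,
    "ring_lattice": _ring_lattice,
    "watts_strogatz": _watts_strogatz,
    "planted_partition": _planted_partition,
    "two_cliques": _two_cliques,
    "barbell": _barbell,
}
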