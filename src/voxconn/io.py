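"""Readers and writers for the formats the pipeline touches.

Volumes are NIfTI-1 (via nibabel), adjacency graphs are Matrix Market
"pattern symmetric" files or two-column edge lists, dense correlation
matrices live in HDF5, and per-node reports are CSV/JSON.  A
:class:`VoxelMask` maps 3-D voxel coordinates to flat node indices; the
ordering is a raster scan with the last axis fastest (0-based), so node
order is a pure function of the mask and identical on every platform.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np
import scipy.io as sio
import scipy.sparse as sp

from .graph import BinaryGraph

__all__ = [
    "VoxelMask",
    "TimeSeriesSet",
    "binarize_mask",
    "read_timeseries",
    "write_voxel_map",
    "read_graph",
    "write_graph",
    "save_dense",
    "load_dense",
]


class FormatError(ValueError):
    """Raised when an on-disk object does not match the expected format."""


@dataclass(frozen=True)
class VoxelMask:
    """In-mask voxels of a 3-D grid, in deterministic node order.

    ``voxel_index[j]`` is the (i, j, k) coordinate of node ``j``.  The
    order is the raster scan of the grid with the last axis varying
    fastest, i.e. the order ``np.argwhere`` returns.
    """

    dims: tuple
    voxel_index: np.ndarray  # (N, 3) int array

    def __post_init__(self):
        vi = np.asarray(self.voxel_index, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "voxel_index", vi)
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if len(self.dims) != 3:
            raise FormatError("mask dims must be a 3-tuple")
        if vi.size:
            if vi.min() < 0 or np.any(vi >= np.asarray(self.dims)):
                raise FormatError("mask coordinate outside volume bounds")
        if np.unique(vi, axis=0).shape[0] != vi.shape[0]:
            raise FormatError("duplicate voxel coordinates in mask")

    @property
    def N(self) -> int:
        return self.voxel_index.shape[0]

    def flat_indices(self) -> np.ndarray:
        """Raveled (C-order) linear indices of the in-mask voxels."""
        return np.ravel_multi_index(self.voxel_index.T, self.dims)


@dataclass
class TimeSeriesSet:
    """L x N matrix of per-node signals (rows = time points)."""

    data: np.ndarray
    mask: VoxelMask | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError("time series must be a 2-D (L x N) matrix")
        if self.L < 3:
            raise FormatError("need at least 3 time points")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("time series contains non-finite values")
        if self.mask is not None and self.mask.N != self.N:
            raise FormatError(
                f"mask has {self.mask.N} voxels but series has {self.N} columns")

    @property
    def L(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[1]


# ----------------------------------------------------------------------
# NIfTI volumes
# ----------------------------------------------------------------------

def binarize_mask(prob_map, threshold: float = 0.2) -> VoxelMask:
    """Threshold a 3-D probability map into a :class:`VoxelMask`.

    A voxel is included iff its value is strictly greater than
    ``threshold`` (gray-matter masks conventionally use 0.2).  Accepts a
    numpy array, a nibabel image, or a path.
    """
    vol = _as_volume(prob_map, expected_ndim=3)
    if not np.all(np.isfinite(vol)):
        raise FormatError("probability map contains non-finite values")
    coords = np.argwhere(vol > threshold)
    if coords.shape[0] == 0:
        raise FormatError("mask is empty at this threshold")
    return VoxelMask(dims=vol.shape, voxel_index=coords)


def read_timeseries(path_4d, mask: VoxelMask, subject_id: str = "") -> TimeSeriesSet:
    """Extract the in-mask voxel time courses of a 4-D volume.

    Column ``j`` of the result is the time course of mask voxel ``j``.
    """
    vol = _as_volume(path_4d, expected_ndim=4)
    if vol.shape[:3] != mask.dims:
        raise FormatError(
            f"volume grid {vol.shape[:3]} does not match mask dims {mask.dims}")
    flat = vol.reshape(-1, vol.shape[3])  # (voxels, L), C-order
    data = flat[mask.flat_indices()].T  # (L, N)
    return TimeSeriesSet(data=np.ascontiguousarray(data), mask=mask,
                         subject_id=subject_id)


def write_voxel_map(values, mask: VoxelMask, path, affine=None) -> None:
    """Write one value per node into a 3-D NIfTI volume (0 outside the mask)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size != mask.N:
        raise FormatError(f"{values.size} values for a {mask.N}-voxel mask")
    vol = np.zeros(mask.dims, dtype=np.float64)
    vol[tuple(mask.voxel_index.T)] = values
    img = nib.Nifti1Image(vol, np.eye(4) if affine is None else affine)
    nib.save(img, os.fspath(path))


def write_volume(vol4d: np.ndarray, path, affine=None) -> None:
    """Write a raw 3-D/4-D array as NIfTI (used by the simulator)."""
    img = nib.Nifti1Image(np.asarray(vol4d, dtype=np.float64),
                          np.eye(4) if affine is None else affine)
    nib.save(img, os.fspath(path))


def _as_volume(obj, expected_ndim: int) -> np.ndarray:
    if isinstance(obj, (str, os.PathLike)):
        obj = nib.load(os.fspath(obj))
    if isinstance(obj, nib.spatialimages.SpatialImage):
        arr = np.asarray(obj.get_fdata())
    else:
        arr = np.asarray(obj, dtype=np.float64)
    if arr.ndim != expected_ndim:
        raise FormatError(f"expected a {expected_ndim}-D volume, got {arr.ndim}-D")
    return arr


# ----------------------------------------------------------------------
# graphs on disk
# ----------------------------------------------------------------------

def write_graph(g: BinaryGraph, path) -> None:
    """Write a graph as Matrix Market pattern-symmetric (.mtx) or TSV edge list.

    Only the upper triangle (i < j) is stored; format is chosen by
    extension (``.mtx`` vs anything else).
    """
    path = os.fspath(path)
    edges = g.edge_array()
    if path.endswith(".mtx"):
        # the Matrix Market symmetric convention stores the lower triangle
        coo = sp.coo_matrix(
            (np.ones(edges.shape[0], dtype=bool), (edges[:, 1], edges[:, 0])),
            shape=(g.N, g.N))
        sio.mmwrite(path, coo, field="pattern", symmetry="symmetric")
    else:
        header = f"# nodes: {g.N}\n"
        with open(path, "w") as fh:
            fh.write(header)
            for i, j in edges:
                fh.write(f"{i}\t{j}\n")


def read_graph(path) -> BinaryGraph:
    """Read a Matrix Market or edge-list graph; symmetric closure applied.

    Self-loops and duplicate undirected edges are rejected.
    """
    path = os.fspath(path)
    if path.endswith(".mtx"):
        coo = sio.mmread(path)
        if not sp.issparse(coo):
            raise FormatError("expected a sparse Matrix Market file")
        coo = coo.tocoo()
        n = coo.shape[0]
        if coo.shape[0] != coo.shape[1]:
            raise FormatError("adjacency matrix must be square")
        # mmread mirrors symmetric storage; fold back to canonical pairs and
        # detect duplicates that were present in the file itself.
        lo = np.minimum(coo.row, coo.col)
        hi = np.maximum(coo.row, coo.col)
        if np.any(lo == hi):
            raise FormatError("self-loop in graph file")
        pairs = np.stack([lo, hi], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        # symmetric mmread yields each off-diagonal entry twice at most
        if np.any(counts > 2):
            raise FormatError("duplicate edge in graph file")
        return BinaryGraph.from_edges(n, uniq)
    # edge list
    n = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "nodes:" in line:
                    n = int(line.split("nodes:")[1])
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"malformed edge line: {line!r}")
            rows.append((int(parts[0]), int(parts[1])))
    edges = np.asarray(rows, dtype=np.int64).reshape(-1, 2)
    if edges.size and np.any(edges[:, 0] == edges[:, 1]):
        raise FormatError("self-loop in graph file")
    if n is None:
        n = int(edges.max()) + 1 if edges.size else 0
    lo = np.minimum(edges[:, 0], edges[:, 1])
    hi = np.maximum(edges[:, 0], edges[:, 1])
    pairs = np.stack([lo, hi], axis=1) if edges.size else edges
    if pairs.size and np.unique(pairs, axis=0).shape[0] != pairs.shape[0]:
        raise FormatError("duplicate edge in graph file")
    return BinaryGraph.from_edges(n, pairs)


# ----------------------------------------------------------------------
# dense matrices in HDF5
# ----------------------------------------------------------------------

def save_dense(path, name: str, matrix: np.ndarray, chunk: int = 2048) -> None:
    """Store a dense matrix as an HDF5 dataset with block-sized chunking."""
    matrix = np.asarray(matrix)
    c = (min(chunk, matrix.shape[0]), min(chunk, matrix.shape[1]))
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        fh.create_dataset(name, data=matrix, chunks=c)


def load_dense(path, name: str) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        if name not in fh:
            raise FormatError(f"dataset {name!r} not found in {path}")
        return fh[name][...]


def list_datasets(path) -> list:
    with h5py.File(path, "r") as fh:
        return sorted(fh.keys())
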