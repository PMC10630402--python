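"""Functional connectivity matrices and their edge-vector representation.

Node timecourses (framewise averages of an atlas parcellation, e.g. the
268-node Shen atlas) are turned into symmetric Fisher-z Pearson correlation
matrices, and those matrices are flattened into the fixed-order edge vectors
that connectome-based predictive modeling consumes.  A 268-node parcellation
yields 268*267/2 = 35,778 edges.

The edge-index convention is row-major over the strict upper triangle with
0-based internal node indices: edge k <-> node pair (i, j), i < j, ordered
(0,1), (0,2), ..., (0,n-1), (1,2), ...  At I/O boundaries nodes are 1-based
and edges are labelled ``n{i}_n{j}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Controlled vocabulary of macroscale anatomical regions used in lobewise
#: edge summaries.
LOBES = (
    "Occipital",
    "Parietal",
    "Temporal",
    "Prefrontal",
    "Cerebellum",
    "MotorStrip",
    "Subcortical",
    "Limbic",
)

ATLAS_COLUMNS = (
    "node_id",
    "name",
    "hemisphere",
    "lobe",
    "network",
    "ba",
    "mni_x",
    "mni_y",
    "mni_z",
)


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between node pairs (i, j), i < j, and flat edge indices.

    Row-major over the strict upper triangle; 0-based node indices
    internally, 1-based node ids in edge labels.
    """

    n_nodes: int
    _rows: np.ndarray = field(init=False, repr=False, compare=False)
    _cols: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("an edge index map needs at least 2 nodes")
        rows, cols = np.triu_indices(self.n_nodes, k=1)
        object.__setattr__(self, "_rows", rows)
        object.__setattr__(self, "_cols", cols)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def to_index(self, i: int, j: int) -> int:
        """Flat edge index of node pair (i, j), 0-based, any order."""
        if i == j:
            raise ValueError("diagonal entries are not edges")
        if i > j:
            i, j = j, i
        if not 0 <= i < j < self.n_nodes:
            raise ValueError(f"node pair ({i}, {j}) out of range for {self.n_nodes} nodes")
        return i * self.n_nodes - i * (i + 1) // 2 + (j - i - 1)

    def to_pair(self, k: int) -> tuple[int, int]:
        """Node pair (i, j), i < j, of flat edge index k."""
        if not 0 <= k < self.n_edges:
            raise ValueError(f"edge index {k} out of range for {self.n_edges} edges")
        return int(self._rows[k]), int(self._cols[k])

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (rows, cols) of node indices for every edge, in edge order."""
        return self._rows, self._cols

    def edge_labels(self) -> list[str]:
        """``n{i}_n{j}`` labels with 1-based node ids, in edge order."""
        return [f"n{i + 1}_n{j + 1}" for i, j in zip(self._rows, self._cols)]


def parcellate(voxel_signals: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Average voxel timecourses into node timecourses.

    Parameters
    ----------
    voxel_signals : (n_voxels, n_frames) array
        Already-extracted voxel signals (no image I/O here).
    labels : (n_voxels,) int array
        Node assignment of each voxel, nodes numbered 0..n_nodes-1.

    Returns
    -------
    (n_nodes, n_frames) array of framewise node means.
    """
    voxel_signals = np.asarray(voxel_signals, dtype=float)
    labels = np.asarray(labels)
    if voxel_signals.ndim != 2:
        raise ValueError("voxel_signals must be 2-D (voxels x frames)")
    if labels.shape != (voxel_signals.shape[0],):
        raise ValueError("labels must have one entry per voxel")
    n_nodes = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_nodes)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"nodes with no voxels: {empty.tolist()}")
    out = np.zeros((n_nodes, voxel_signals.shape[1]))
    np.add.at(out, labels, voxel_signals)
    return out / counts[:, None]


def connectivity(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson connectivity matrix of node timecourses.

    Off-diagonal entry (i, j) is atanh(pearson(ts_i, ts_j)).  The diagonal
    is set to 0 and must never be consumed downstream (z of r = 1 is
    infinite).

    Parameters
    ----------
    timeseries : (n_nodes, n_frames) array

    Raises
    ------
    ValueError
        If any node has zero variance, fewer than 3 frames are given, or an
        off-diagonal correlation is exactly +/-1 (duplicate signals).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("timeseries must be n_nodes x n_frames with >= 3 frames")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance nodes: {dead.tolist()}")
    r = np.corrcoef(ts)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        i, j = np.argwhere((np.abs(r) >= 1.0) & off)[0]
        raise ValueError(f"degenerate |r|=1 between nodes {i} and {j}")
    z = np.arctanh(r, where=off, out=np.zeros_like(r))
    np.fill_diagonal(z, 0.0)
    return z


def vectorize_upper(matrix: np.ndarray, *, atol: float = 1e-10) -> np.ndarray:
    """Flatten a symmetric connectivity matrix into the row-major
    upper-triangle edge vector.

    ``devectorize(vectorize_upper(m))`` reproduces ``m`` off-diagonal
    exactly.  Asymmetry beyond ``atol`` is an error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(m, m.T, atol=atol, rtol=0.0):
        raise ValueError(f"matrix asymmetric beyond tolerance {atol}")
    rows, cols = np.triu_indices(m.shape[0], k=1)
    return m[rows, cols].copy()


def devectorize(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    n_expected = n_nodes * (n_nodes - 1) // 2
    if edges.shape != (n_expected,):
        raise ValueError(f"expected {n_expected} edges for {n_nodes} nodes, got {edges.shape}")
    m = np.zeros((n_nodes, n_nodes))
    rows, cols = np.triu_indices(n_nodes, k=1)
    m[rows, cols] = edges
    m[cols, rows] = edges
    return m


def validate_atlas(atlas: pd.DataFrame, n_nodes: int | None = None) -> pd.DataFrame:
    """Check an atlas node table: required columns, unique contiguous
    1-based ids, lobe labels drawn from the controlled vocabulary."""
    missing = [c for c in ATLAS_COLUMNS if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas table missing columns: {missing}")
    ids = atlas["node_id"].to_numpy()
    n = n_nodes if n_nodes is not None else len(atlas)
    if len(atlas) != n or not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
        raise ValueError("atlas node_id must be unique and contiguous from 1")
    bad = sorted(set(atlas["lobe"]) - set(LOBES))
    if bad:
        raise ValueError(f"unknown lobe labels {bad}; allowed: {list(LOBES)}")
    return atlas.sort_values("node_id").reset_index(drop=True)
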