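"""Cell subpopulation identification: batch-trained SOM plus metaclustering.

The standard cytometry workflow maps cells onto a small self-organizing map
(typically 10x10 nodes) and then groups the node codebook vectors into a
modest number of metaclusters, interpreted as cell subpopulations. Clustering
uses lineage-class proteins only, on the arcsinh scale, because lineage
markers define cell identity while functional markers respond to treatment.

The SOM here is batch-trained (all cells per epoch, Gaussian neighborhood
with a linearly decaying radius), which makes training deterministic given
the seed. Metaclustering is average-linkage hierarchical clustering of the
codebook rows — a deterministic stand-in for consensus metaclustering that
adds no second stochastic layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .data import CellTable

__all__ = [
    "SOMGrid",
    "ClusterAssignment",
    "train_som",
    "metacluster",
    "assign_clusters",
    "cluster_proportions",
    "cluster_cells",
]

log = logging.getLogger(__name__)


@dataclass
class SOMGrid:
    codebook: np.ndarray  # (rows*cols) x n_features
    grid_dims: tuple[int, int]
    lineage_names: list[str]
    training_seed: int

    @property
    def n_nodes(self) -> int:
        return self.grid_dims[0] * self.grid_dims[1]


@dataclass
class ClusterAssignment:
    node_id: np.ndarray  # per-cell SOM node index, 0-based
    metacluster_id: np.ndarray  # per-cell metacluster, 1..n_meta
    n_meta: int

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=int)
        self.metacluster_id = np.asarray(self.metacluster_id, dtype=int)
        if self.metacluster_id.min(initial=1) < 1 or (
            self.metacluster_id.max(initial=1) > self.n_meta
        ):
            raise ValueError("metacluster ids must lie in 1..n_meta")


def _grid_coords(grid_dims: tuple[int, int]) -> np.ndarray:
    rows, cols = grid_dims
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def train_som(
    cells: CellTable,
    lineage_names: list[str],
    grid_dims: tuple[int, int] = (10, 10),
    seed: int = 0,
    n_epochs: int = 10,
) -> SOMGrid:
    """Train a batch SOM on the lineage columns of an arcsinh-scale table.

    Each epoch computes the best-matching node for every cell, then replaces
    every codebook vector by the neighborhood-weighted mean of the cells,
    with a Gaussian neighborhood whose radius decays linearly from half the
    larger grid dimension to ~0.5 over the epochs.
    """
    if not lineage_names:
        raise ValueError("lineage_names must not be empty")
    cols = cells.column_index(list(lineage_names))
    X = cells.values[:, cols]
    n_nodes = grid_dims[0] * grid_dims[1]
    if X.shape[0] < n_nodes:
        raise ValueError(
            f"need at least {n_nodes} cells to train a {grid_dims} grid"
        )
    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(X.shape[0], size=n_nodes, replace=False)].copy()

    coords = _grid_coords(grid_dims)
    grid_d2 = cdist(coords, coords, metric="sqeuclidean")
    r0 = max(grid_dims) / 2.0
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        radius = max(r0 * (1.0 - frac), 0.5)
        h = np.exp(-grid_d2 / (2.0 * radius**2))  # nodes x nodes
        bmu = np.argmin(cdist(X, codebook, metric="sqeuclidean"), axis=1)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, X)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        num = h @ sums
        den = (h @ counts)[:, None]
        ok = den[:, 0] > 0
        codebook[ok] = num[ok] / den[ok]
    return SOMGrid(
        codebook=codebook,
        grid_dims=tuple(grid_dims),
        lineage_names=list(lineage_names),
        training_seed=seed,
    )


def metacluster(grid: SOMGrid, n_meta: int, seed: int = 0) -> np.ndarray:
    """Group SOM nodes into ``n_meta`` metaclusters.

    Average-linkage hierarchical clustering of the codebook rows; fully
    deterministic (the seed is accepted for interface symmetry and recorded
    by callers). Returns a length-n_nodes array of metacluster ids 1..n_meta,
    relabelled in order of first node appearance.
    """
    n_nodes = grid.n_nodes
    if not 1 <= n_meta <= n_nodes:
        raise ValueError(f"n_meta must be in 1..{n_nodes}, got {n_meta}")
    if n_meta == n_nodes:
        return np.arange(1, n_nodes + 1)
    Z = linkage(grid.codebook, method="average", metric="euclidean")
    raw = fcluster(Z, t=n_meta, criterion="maxclust")
    # relabel contiguously by first occurrence so ids are stable
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        out[i] = mapping[r]
    return out


def assign_clusters(
    cells: CellTable, grid: SOMGrid, node_to_meta: np.ndarray
) -> ClusterAssignment:
    """Map each cell to its nearest codebook node, then to that node's
    metacluster. Distance ties go to the lowest node index (argmin order)."""
    cols = cells.column_index(grid.lineage_names)
    X = cells.values[:, cols]
    node = np.argmin(cdist(X, grid.codebook, metric="sqeuclidean"), axis=1)
    node_to_meta = np.asarray(node_to_meta, dtype=int)
    if node_to_meta.shape[0] != grid.n_nodes:
        raise ValueError("node_to_meta length must equal number of SOM nodes")
    return ClusterAssignment(
        node_id=node,
        metacluster_id=node_to_meta[node],
        n_meta=int(node_to_meta.max()),
    )


def cluster_proportions(
    assignment: ClusterAssignment, cells: CellTable
) -> pd.DataFrame:
    """Per-sample metacluster proportion vectors (rows sum to 1).

    Clusters absent from a sample appear with proportion 0, so vectors are
    directly comparable across samples.
    """
    if len(assignment.metacluster_id) != cells.n_cells:
        raise ValueError("assignment not aligned with cell table")
    df = pd.DataFrame(
        {"sample_id": cells.sample_id, "metacluster": assignment.metacluster_id}
    )
    counts = (
        df.groupby(["sample_id", "metacluster"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(1, assignment.n_meta + 1), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def cluster_cells(
    cells: CellTable,
    lineage_names: list[str],
    n_meta: int = 20,
    grid_dims: tuple[int, int] = (10, 10),
    seed: int = 0,
) -> tuple[ClusterAssignment, SOMGrid]:
    """Convenience pipeline: train SOM, metacluster, assign every cell."""
    grid = train_som(cells, lineage_names, grid_dims=grid_dims, seed=seed)
    mapping = metacluster(grid, n_meta=n_meta, seed=seed)
    assignment = assign_clusters(cells, grid, mapping)
    log.info(
        "clustered %d cells into %d metaclusters on a %sx%s grid",
        cells.n_cells,
        assignment.n_meta,
        *grid.grid_dims,
    )
    return assignment, grid
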