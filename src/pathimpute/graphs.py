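"""Heterogeneous graph construction.

Two undirected edge sets over the same cells: a spatial proximity graph
(edge iff Euclidean distance between coordinates is at most a threshold)
and an expression-similarity graph (symmetrised union of a top-k nearest
neighbour relation over highly variable gene expression).  The two edge
sets are built independently and share nothing but the node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .io import ExpressionDataset, HVGSelection

logger = logging.getLogger(__name__)

__all__ = [
    "CellGraph",
    "HeteroGraph",
    "build_spatial_graph",
    "build_gene_graph",
    "build_hetero_graph",
    "auto_distance_threshold",
    "save_graph",
    "load_graph",
]


@dataclass
class CellGraph:
    """An undirected simple graph over cells.

    ``edges`` is an (E, 2) integer array with each pair stored once as
    (i, j), i < j.  ``knn`` optionally retains the asymmetric top-k
    relation the edges were symmetrised from (diagnostics only).
    """

    n_nodes: int
    edges: np.ndarray
    kind: str
    knn: np.ndarray | None = None
    _indptr: np.ndarray | None = field(default=None, repr=False, compare=False)
    _indices: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if len(edges):
            if (edges[:, 0] == edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            if edges.min() < 0 or edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint outside [0, n_nodes)")
            edges = np.sort(edges, axis=1)
            edges = np.unique(edges, axis=0)
        self.edges = edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def adjacency(self):
        """CSR neighbour structure (indptr, indices) with sorted neighbours."""
        if self._indptr is None:
            counts = np.zeros(self.n_nodes, dtype=int)
            if len(self.edges):
                both = np.concatenate([self.edges, self.edges[:, ::-1]])
                order = np.lexsort((both[:, 1], both[:, 0]))
                both = both[order]
                counts = np.bincount(both[:, 0], minlength=self.n_nodes)
                self._indices = both[:, 1].copy()
            else:
                self._indices = np.empty(0, dtype=int)
            self._indptr = np.concatenate([[0], np.cumsum(counts)])
        return self._indptr, self._indices

    def neighbors(self, node: int) -> np.ndarray:
        indptr, indices = self.adjacency()
        return indices[indptr[node] : indptr[node + 1]]

    def degrees(self) -> np.ndarray:
        indptr, _ = self.adjacency()
        return np.diff(indptr)

    def has_edge(self, i: int, j: int) -> bool:
        return j in self.neighbors(i)


@dataclass
class HeteroGraph:
    """The spatial and gene-similarity graphs over one set of cells."""

    spatial: CellGraph
    gene: CellGraph

    def __post_init__(self) -> None:
        if self.spatial.n_nodes != self.gene.n_nodes:
            raise ValueError(
                f"graphs disagree on node count: "
                f"{self.spatial.n_nodes} vs {self.gene.n_nodes}"
            )

    @property
    def n_nodes(self) -> int:
        return self.spatial.n_nodes


def build_spatial_graph(coords: np.ndarray, d_thr: float) -> CellGraph:
    """Connect every pair of cells whose Euclidean distance is <= ``d_thr``."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates contain non-finite values")
    if d_thr <= 0:
        raise ValueError("d_thr must be positive")
    n = len(coords)
    if n < 2:
        return CellGraph(n_nodes=n, edges=np.empty((0, 2), dtype=int), kind="spatial")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=d_thr, output_type="ndarray")
    return CellGraph(n_nodes=n, edges=pairs, kind="spatial")


def knn_neighbor_lists(x: np.ndarray, k: int) -> np.ndarray:
    """Exact k nearest neighbours per row under Euclidean distance.

    Self-distance excluded; ties at the k-th neighbour broken by ascending
    node index so builds are deterministic.  Returns an (n, k) index array.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not 1 <= k < n:
        raise ValueError(f"knn_k must satisfy 1 <= k < n (got k={k}, n={n})")
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    # lexsort: primary key distance, secondary key node index
    idx = np.arange(n)
    nbrs = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, d[i]))
        nbrs[i] = order[:k]
    return nbrs


def build_gene_graph(
    hvg_matrix: np.ndarray, knn_k: int, metric: str = "euclidean"
) -> CellGraph:
    """Symmetrised k-nearest-neighbour graph on HVG expression profiles.

    The directed top-k relation (each cell points to its ``knn_k`` most
    similar cells by Euclidean distance on the HVG submatrix) is stored on
    the returned graph as ``knn``; the edge set is its symmetrised union,
    so a walk can traverse similarity links in either direction.
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    nbrs = knn_neighbor_lists(hvg_matrix, knn_k)
    n = len(nbrs)
    src = np.repeat(np.arange(n), knn_k)
    edges = np.column_stack([src, nbrs.ravel()])
    return CellGraph(n_nodes=n, edges=edges, kind="gene", knn=nbrs)


def auto_distance_threshold(coords: np.ndarray, target_mean_degree: float = 6.0) -> float:
    """Smallest distance threshold giving spatial mean degree >= target.

    Mean degree 2E/n >= t needs at least ceil(t*n/2) pairs within range,
    so the threshold is that order statistic of the pairwise distances
    (taken from each node's nearest neighbours, which is sufficient for
    the small targets used here).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two cells")
    need = int(np.ceil(target_mean_degree * n / 2))
    k = min(n, max(16, int(2 * target_mean_degree) + 2))
    tree = cKDTree(coords)
    dists, idxs = tree.query(coords, k=k)
    # unique unordered pairs from the kNN lists
    src = np.repeat(np.arange(n), k)
    pairs = np.sort(np.column_stack([src, idxs.ravel()]), axis=1)
    keep = pairs[:, 0] != pairs[:, 1]
    pairs, dvals = pairs[keep], dists.ravel()[keep]
    _, first = np.unique(pairs, axis=0, return_index=True)
    dvals = np.sort(dvals[first])
    if need > len(dvals):
        need = len(dvals)
    return float(dvals[need - 1])


def build_hetero_graph(
    data: ExpressionDataset,
    hvg: HVGSelection,
    d_thr: float | None = None,
    knn_k: int = 6,
) -> HeteroGraph:
    """Build both halves of the heterogeneous graph from one dataset.

    ``d_thr=None`` picks the smallest threshold reaching spatial mean
    degree 6 (the hexagonal-lattice neighbour count).  Summary statistics
    are logged.
    """
    if data.coords is None:
        raise ValueError("dataset has no spatial coordinates")
    if d_thr is None:
        d_thr = auto_distance_threshold(data.coords)
        logger.info("auto spatial distance threshold: %.4g", d_thr)
    spatial = build_spatial_graph(data.coords, d_thr)
    hvg_matrix = data.dense()[:, hvg.gene_indices]
    gene = build_gene_graph(hvg_matrix, knn_k)
    hg = HeteroGraph(spatial=spatial, gene=gene)
    logger.info(
        "hetero graph: spatial %d edges (mean degree %.2f), "
        "gene %d edges (mean degree %.2f)",
        spatial.n_edges,
        spatial.mean_degree,
        gene.n_edges,
        gene.mean_degree,
    )
    return hg


def save_graph(graph: CellGraph, path: str | Path) -> None:
    """Write the edge list as TSV: node_i, node_j, kind (0-based)."""
    lines = [f"{i}\t{j}\t{graph.kind}" for i, j in graph.edges]
    header = f"# n_nodes={graph.n_nodes}"
    Path(path).write_text("\n".join([header] + lines) + "\n")


def load_graph(path: str | Path) -> CellGraph:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("# n_nodes="):
        raise ValueError(f"{path} is not a graph edge-list file")
    n_nodes = int(text[0].split("=", 1)[1])
    edges, kind = [], "spatial"
    for line in text[1:]:
        if not line:
            continue
        i, j, kind = line.split("\t")
        edges.append((int(i), int(j)))
    return CellGraph(
        n_nodes=n_nodes,
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
        kind=kind,
    )
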