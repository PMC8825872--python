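"""Cell-graph construction: KNN (Euclidean/Manhattan/cosine), PKNN
(Pearson correlation) and custom edge-list graphs.

The graph is simple — undirected, unweighted, no self-loops, no multi-edges.
Each cell's k nearest neighbours are computed on a chosen feature space
(optionally a KHVG gene subset and/or a PCA projection); the directed k-NN
lists are then symmetrized by union, so an edge survives if either endpoint
selected the other. Neighbour ties break towards the lower cell index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import ExpressionMatrix, select_hvg

__all__ = ["CellGraph", "build_graph", "load_custom_graph", "save_graph"]

METRICS = ("euclidean", "pearson", "cosine", "manhattan")


@dataclass
class CellGraph:
    """Undirected simple graph over cells, stored as sorted unique pairs."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int array, each row i < j

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if e.size:
            if e.min() < 0 or e.max() >= self.n_nodes:
                raise ValueError("edge index out of range")
            if np.any(e[:, 0] == e[:, 1]):
                raise ValueError("self-loops are not allowed")
            e = np.sort(e, axis=1)
            e = np.unique(e, axis=0)
        self.edges = e

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def edge_set(self) -> set:
        return {tuple(e) for e in self.edges}

    def neighbors(self, i: int) -> np.ndarray:
        mask0 = self.edges[:, 0] == i
        mask1 = self.edges[:, 1] == i
        return np.sort(np.concatenate([self.edges[mask0, 1], self.edges[mask1, 0]]))


def _pairwise_distances(x: np.ndarray, metric: str) -> np.ndarray:
    """Full pairwise distance matrix; for pearson/cosine smaller = closer
    (distance = 1 − similarity)."""
    if metric == "pearson":
        sd = x.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"cell row {dead[0]} has zero variance; Pearson correlation undefined")
        return 1.0 - np.corrcoef(x)
    if metric in ("euclidean", "cosine"):
        return cdist(x, x, metric=metric)
    if metric == "manhattan":
        return cdist(x, x, metric="cityblock")
    raise ValueError(f"unknown metric '{metric}' (choose from {METRICS})")


def knn_neighbor_lists(dist: np.ndarray, k: int) -> np.ndarray:
    """Per-row k nearest neighbours (excluding self), ties to lower index."""
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        order = np.lexsort((idx, d[i]))  # primary: distance; secondary: index
        out[i] = order[:k]
    return out


def build_graph(features: ExpressionMatrix | np.ndarray,
                k: int = 5,
                metric: str = "euclidean",
                khvg: int | None = None,
                use_pca: int | None = None,
                random_state: int = 0) -> CellGraph:
    """Build the union-symmetrized k-nearest-neighbour cell graph.

    Parameters
    ----------
    features
        Preprocessed expression matrix (or plain array) used to measure
        cell-cell proximity.
    k
        Neighbours per cell before symmetrization; must satisfy k < n_cells.
    metric
        'euclidean', 'manhattan', 'cosine', or 'pearson' (PKNN; highest
        correlation = nearest).
    khvg
        If given, restrict to the top-khvg most variable genes before
        measuring distances.
    use_pca
        If given, project the (possibly khvg-restricted) features onto this
        many principal components first.
    """
    if isinstance(features, ExpressionMatrix):
        if khvg is not None:
            features = features.subset_genes(select_hvg(features, khvg))
        x = features.values
    else:
        x = np.asarray(features, dtype=np.float64)
        if khvg is not None:
            raise ValueError("khvg requires an ExpressionMatrix with gene ids")
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if k < 1:
        raise ValueError("k must be positive")
    if use_pca is not None:
        from sklearn.decomposition import PCA
        x = PCA(n_components=min(use_pca, *x.shape),
                random_state=random_state).fit_transform(x)
    dist = _pairwise_distances(x, metric)
    nbrs = knn_neighbor_lists(dist, k)
    src = np.repeat(np.arange(n), k)
    pairs = np.stack([src, nbrs.ravel()], axis=1)
    return CellGraph(n_nodes=n, edges=pairs)  # constructor symmetrizes/dedups


def load_custom_graph(path, n_nodes: int) -> CellGraph:
    """Read a 2-column whitespace/tab-separated 0-based edge list.

    Self-loops are dropped with a warning; duplicates and reversed
    duplicates collapse to single undirected edges.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two integers, got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer edge {line!r}") from exc
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(
                    f"{path}:{lineno}: index out of range for {n_nodes} nodes")
            if i == j:
                warnings.warn(f"{path}:{lineno}: dropping self-loop on node {i}")
                continue
            edges.append((i, j))
    return CellGraph(n_nodes=n_nodes,
                     edges=np.asarray(edges, dtype=np.intp).reshape(-1, 2))


def save_graph(graph: CellGraph, path, header_comment: str | None = None) -> None:
    """Write the edge list as two 0-based tab-separated integer columns."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for i, j in graph.edges:
            fh.write(f"{i}\t{j}\n")
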