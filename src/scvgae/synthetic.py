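"""Seeded generators for scRNA-seq-like test data with known structure.

``generate_counts`` draws negative-binomial counts: each gene has a base
mean drawn log-normally, and each cluster multiplies its planted marker
genes' means by a fold change, giving a clean, fully known clustering
signal. ``generate_block_graph`` draws a stochastic block model for
link-prediction fixtures. Both are deterministic under their seed.

The generator emulates the count overdispersion and marker structure of
droplet scRNA-seq; it does not emulate library-size variation, batch
effects, dropouts beyond NB sampling, or gene-gene correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import CellGraph
from .preprocess import ExpressionMatrix

__all__ = ["SyntheticDataset", "generate_counts", "generate_block_graph"]


@dataclass
class SyntheticDataset:
    counts: ExpressionMatrix
    true_labels: np.ndarray
    marker_map: dict  # cluster -> array of marker gene indices (disjoint)
    seed: int


def _cluster_sizes(n_cells: int, n_clusters: int, imbalance) -> np.ndarray:
    if imbalance is None:
        base = n_cells // n_clusters
        sizes = np.full(n_clusters, base, dtype=int)
        sizes[: n_cells - base * n_clusters] += 1
        return sizes
    w = np.asarray(imbalance, dtype=float)
    if len(w) != n_clusters or np.any(w <= 0):
        raise ValueError("imbalance needs one positive weight per cluster")
    sizes = np.maximum(1, np.floor(w / w.sum() * n_cells).astype(int))
    while sizes.sum() > n_cells:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_cells:
        sizes[np.argmax(w)] += 1
    return sizes


def generate_counts(n_cells: int = 300, n_genes: int = 500, n_clusters: int = 3,
                    markers_per_cluster: int = 20, fold_change: float = 8.0,
                    dispersion: float = 2.0, base_mean: float = 1.0,
                    seed: int = 0, imbalance=None) -> SyntheticDataset:
    """Clustered negative-binomial counts with planted marker genes.

    Each gene's base mean is LogNormal(log(base_mean), 1); counts are
    NB(mean=m, dispersion=θ) with variance m + m²/θ. Cluster c's markers
    have their mean multiplied by ``fold_change``. Marker sets are disjoint
    across clusters. ``imbalance`` (optional per-cluster weights) skews
    cluster sizes, e.g. to plant a tiny population for rescue tests.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if markers_per_cluster * n_clusters > n_genes:
        raise ValueError("marker allocation exceeds the number of genes")
    rng = np.random.default_rng(seed)
    sizes = _cluster_sizes(n_cells, n_clusters, imbalance)
    labels = np.repeat(np.arange(n_clusters), sizes)
    gene_means = np.exp(rng.normal(np.log(base_mean), 1.0, size=n_genes))
    marker_map = {
        c: np.arange(c * markers_per_cluster, (c + 1) * markers_per_cluster)
        for c in range(n_clusters)
    }
    mean_matrix = np.tile(gene_means, (n_cells, 1))
    for c, genes in marker_map.items():
        mean_matrix[np.ix_(labels == c, genes)] *= fold_change
    # NB(mean m, dispersion θ): n=θ, p=θ/(θ+m)
    p = dispersion / (dispersion + mean_matrix)
    counts = rng.negative_binomial(dispersion, p).astype(float)
    # guarantee every cell has at least one count (empty cells are
    # unnormalizable and would be filtered in any real pipeline)
    dead = counts.sum(axis=1) == 0
    if dead.any():
        counts[dead, 0] += 1
    matrix = ExpressionMatrix(
        values=counts,
        cell_ids=[f"cell_{i:04d}" for i in range(n_cells)],
        gene_ids=[f"gene_{j:04d}" for j in range(n_genes)],
    )
    return SyntheticDataset(counts=matrix, true_labels=labels,
                            marker_map=marker_map, seed=seed)


def generate_block_graph(n_nodes: int = 30, n_blocks: int = 2,
                         p_in: float = 0.5, p_out: float = 0.05,
                         seed: int = 0) -> tuple[CellGraph, np.ndarray]:
    """Stochastic block model: within-block edge prob p_in, between p_out."""
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError("require 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    sizes = _cluster_sizes(n_nodes, n_blocks, None)
    labels = np.repeat(np.arange(n_blocks), sizes)
    iu, ju = np.triu_indices(n_nodes, k=1)
    probs = np.where(labels[iu] == labels[ju], p_in, p_out)
    keep = rng.random(len(probs)) < probs
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    return CellGraph(n_nodes=n_nodes, edges=edges), labels
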