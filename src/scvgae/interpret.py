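"""Model interpretability: attention summaries, encoder weight products and
learnt per-gene expression.

Three complementary views of a trained model:

1. **Attention.** Per-node overlays (mean incoming or outgoing attention)
   and the top-n attention graph — the n largest coefficients kept as a
   weighted, directed graph (α_ij and α_ji are distinct).
2. **Weight products.** Chaining the transposed encoder weight matrices,
   P_μ = W₁ᵀ·W₂ᵀ·…·W_μᵀ (D × L), links each input gene to each latent
   dimension; ranking |P_μ| columns retrieves candidate marker genes per
   cluster.
3. **Learnt expression.** E·g, the embedding projected onto one gene's
   loading vector g (a row of P_μ), gives a signed per-cell expression
   score — positive reads as high expression, negative as the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterAssignment
from .layers import AttentionRecord

__all__ = ["WeightProducts", "node_attention_overlay", "top_attention_edges",
           "attention_vs_latent_distance", "weight_products", "ranked_genes",
           "learnt_gene_expression", "GeneReport"]


@dataclass
class WeightProducts:
    """P_μ and P_σ, each genes × latent dimensions."""

    P_mu: np.ndarray
    P_sigma: np.ndarray

    def __post_init__(self):
        self.P_mu = np.asarray(self.P_mu, dtype=np.float64)
        self.P_sigma = np.asarray(self.P_sigma, dtype=np.float64)
        if self.P_mu.shape != self.P_sigma.shape:
            raise ValueError("P_mu and P_sigma shapes differ")
        if not (np.all(np.isfinite(self.P_mu)) and np.all(np.isfinite(self.P_sigma))):
            raise ValueError("weight products contain NaN or Inf")


def node_attention_overlay(attn: AttentionRecord, direction: str = "incoming",
                           head: int | None = None) -> np.ndarray:
    """Per-node mean attention coefficient.

    'incoming' averages the coefficients α_ij over each target node i's
    neighbourhood (the contribution the model assigns TO that node);
    'outgoing' averages over edges where the node is the source. With
    ``head=None`` coefficients are first averaged across heads.
    """
    if direction not in ("incoming", "outgoing"):
        raise ValueError("direction must be 'incoming' or 'outgoing'")
    alpha = attn.head_mean() if head is None else attn.alpha[head]
    anchor = attn.tgt if direction == "incoming" else attn.src
    sums = np.zeros(attn.n_nodes)
    counts = np.zeros(attn.n_nodes)
    np.add.at(sums, anchor, alpha)
    np.add.at(counts, anchor, 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), 0.0)
    return out


def top_attention_edges(attn: AttentionRecord, n: int,
                        head: int | None = None,
                        exclude_nodes=None,
                        weight_range: tuple | None = None) -> list[tuple]:
    """The n largest coefficients as (target, source, alpha) triples,
    weights non-increasing; ties broken lexicographically by (i, j).

    ``exclude_nodes`` drops any edge touching those nodes (e.g. a cell type
    to ignore); ``weight_range=(lo, hi)`` keeps only coefficients inside
    the closed interval, enabling analyses of e.g. the smaller weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = attn.head_mean() if head is None else attn.alpha[head]
    tgt, src = attn.tgt, attn.src
    mask = np.ones(len(alpha), dtype=bool)
    if exclude_nodes is not None:
        excl = set(int(x) for x in exclude_nodes)
        mask &= np.array([t not in excl and s not in excl
                          for t, s in zip(tgt, src)])
    if weight_range is not None:
        lo, hi = weight_range
        mask &= (alpha >= lo) & (alpha <= hi)
    idx = np.flatnonzero(mask)
    if n > idx.size:
        import warnings
        warnings.warn(f"requested top {n} but only {idx.size} coefficients exist")
        n = idx.size
    order = idx[np.lexsort((src[idx], tgt[idx], -alpha[idx]))]
    return [(int(tgt[e]), int(src[e]), float(alpha[e])) for e in order[:n]]


def attention_vs_latent_distance(attn: AttentionRecord, Z: np.ndarray,
                                 top_n: int = 80,
                                 head: int | None = None) -> list[tuple]:
    """For the top_n coefficients, pair each (rank, α) with the latent
    Euclidean distance of its cell pair — a redundancy check: high
    attention between latently distant cells means attention carries
    information the embedding alone does not."""
    Z = np.asarray(Z, dtype=np.float64)
    top = top_attention_edges(attn, top_n, head=head)
    out = []
    for rank, (i, j, a) in enumerate(top):
        d = float(np.linalg.norm(Z[i] - Z[j]))
        out.append((rank, a, d))
    return out


def weight_products(inner_weights, W_mu: np.ndarray,
                    W_sigma: np.ndarray) -> WeightProducts:
    """Chain the transposed encoder weights: P = W₁ᵀ·W₂ᵀ·…·W_outᵀ.

    ``inner_weights`` are the inner-layer matrices with per-head blocks
    already stacked to the concatenated width (each (K·D_i) × D_in of that
    layer); ``W_mu``/``W_sigma`` are the head-averaged output matrices
    (L × K·D_last). The result is D × L.
    """
    if isinstance(inner_weights, np.ndarray):
        inner_weights = [inner_weights]

    def chain(w_out):
        p = inner_weights[0].T
        for w in inner_weights[1:]:
            p = p @ w.T
        return p @ np.asarray(w_out).T

    p_mu, p_sigma = chain(W_mu), chain(W_sigma)
    return WeightProducts(P_mu=p_mu, P_sigma=p_sigma)


@dataclass
class GeneReport:
    """Per-cluster marker-gene ranking derived from |P_μ|.

    ``appearance`` maps cluster → list of (gene index, count) sorted by
    descending count (ties to lower gene index); ``top100_singletons`` maps
    cluster → genes that appeared exactly once but sit inside the global
    top-100 |P_μ| entries.
    """

    appearance: dict
    top100_singletons: dict
    dims_by_cluster: dict


def ranked_genes(products: WeightProducts, embedding: np.ndarray,
                 assignment, top_per_dim: int = 15,
                 top_weight_pool: int = 100) -> GeneReport:
    """Marker-gene retrieval per cluster from the μ weight products.

    For every cluster, latent dimensions are ranked by the mean |embedding|
    of the cluster's cells; for each dimension the ``top_per_dim`` genes
    with the largest |P_μ| entries are selected, and appearance counts are
    accumulated across dimensions. Genes appearing only once but whose
    |P_μ| entry is inside the global ``top_weight_pool`` largest values are
    reported as a secondary list.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) \
        else np.asarray(assignment, dtype=int)
    E = np.asarray(embedding, dtype=np.float64)
    if len(labels) != len(E):
        raise ValueError("cluster labels and embedding rows differ in length")
    P = np.abs(products.P_mu)
    n_genes, n_dims = P.shape
    if E.shape[1] != n_dims:
        raise ValueError("embedding width != latent dimension of P_mu")
    # genes per dimension, ranked by |P_mu|, ties to lower index
    gene_idx = np.arange(n_genes)
    per_dim_genes = [
        np.lexsort((gene_idx, -P[:, d]))[:top_per_dim] for d in range(n_dims)
    ]
    # global top-weight pool over all entries of |P_mu|
    flat_order = np.argsort(-P, axis=None, kind="stable")[:top_weight_pool]
    pool_genes = set(np.unravel_index(flat_order, P.shape)[0].tolist())

    appearance, singles, dims_by_cluster = {}, {}, {}
    for c in np.unique(labels[labels >= 0]):
        cells = labels == c
        relevance = np.abs(E[cells]).mean(axis=0)  # per latent dim
        dim_order = np.lexsort((np.arange(n_dims), -relevance))
        dims_by_cluster[int(c)] = dim_order.tolist()
        counts = np.zeros(n_genes, dtype=int)
        for d in dim_order:
            counts[per_dim_genes[d]] += 1
        seen = np.flatnonzero(counts > 0)
        order = seen[np.lexsort((seen, -counts[seen]))]
        appearance[int(c)] = [(int(g), int(counts[g])) for g in order]
        singles[int(c)] = sorted(
            int(g) for g in seen if counts[g] == 1 and g in pool_genes)
    return GeneReport(appearance=appearance, top100_singletons=singles,
                      dims_by_cluster=dims_by_cluster)


def learnt_gene_expression(embedding: np.ndarray, products: WeightProducts,
                           gene_index: int) -> np.ndarray:
    """Per-cell learnt expression E·g for one gene's loading vector g.

    The sign is preserved: positive values read as high expression,
    negative as the opposite.
    """
    E = np.asarray(embedding, dtype=np.float64)
    if not (0 <= gene_index < products.P_mu.shape[0]):
        raise IndexError(f"gene index {gene_index} out of range")
    g = products.P_mu[gene_index]
    return E @ g
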