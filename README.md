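# scvgae

Variational graph autoencoder with graph attention for single-cell RNA-seq
embedding, clustering and model interpretation.

## The problem

Dimensionality reduction of scRNA-seq data is usually done from the gene
expression values alone (PCA, t-SNE/UMAP, dense variational autoencoders).
`scvgae` instead treats the dataset as a **graph of cells** — each cell
connected to its k nearest neighbours by Euclidean distance (KNN) or
Pearson correlation (PKNN) — and learns per-cell latent variables with a
**variational graph autoencoder (VGAE)** whose encoder is built from
**graph attention (GAT) layers**. The cell graph acts as an inductive
bias: information propagates along cell-cell connections, which helps on
datasets where expression alone does not separate populations. The latent
space is then clustered density-based with HDBSCAN, and the trained model
itself is inspected through its attention coefficients and encoder
weights.

## The model

Given node features **X** (cells × genes, log-normalized, min-max scaled,
restricted to highly variable genes) and the cell-graph adjacency **A**,
the encoder is a stack of multi-head GAT layers:

- inner layers concatenate K attention heads with ReLU between layers,
- two parallel output layers (heads averaged) produce the posterior
  parameters μ and log σ per cell: q(z_i | X, A) = N(μ_i, diag σ_i²).

Each head scores a pair of cells as
e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j]) and normalizes the scores over each
cell's neighbourhood (its graph neighbours plus itself) with a softmax,
giving attention coefficients α_ij that sum to 1 per cell. GATv2 and plain
GCN layers are available as drop-in alternatives.

The decoder reconstructs edges by inner product,
p(A_ij = 1) = sigmoid(z_iᵀ z_j), trained as binary cross-entropy with
negative sampling (one random non-edge per edge per epoch). The latent
regularizer is the KL divergence to N(0, I) (weighted 1/N per the standard
VGAE convention) or, alternatively, a Gaussian-kernel MMD; a feature
reconstruction MSE term can be switched on.

Interpretation uses three views:

1. **Attention graphs** — the α_ij form a weighted, directed graph over
   cells; per-node mean attention overlays and top-n attention edge lists
   are exported.
2. **Weight products** — P_μ = W₁ᵀ·W₂ᵀ·…·W_μᵀ (genes × latent dims) links
   each input gene to each latent dimension; ranking |P_μ| per dimension
   retrieves candidate marker genes per cluster.
3. **Learnt expression** — E·g (embedding times one gene's loading row of
   P_μ) gives a signed per-cell expression score for any gene.

## Worked example

Everything is testable without downloads through the synthetic generator,
which plants marker genes into negative-binomial counts:

```python
from scvgae import (generate_counts, build_graph, fit, TrainingConfig,
                    cluster_latent, adjusted_rand_index,
                    log_normalize, minmax_scale, select_hvg)

ds = generate_counts(n_cells=300, n_genes=500, n_clusters=3,
                     markers_per_cluster=20, fold_change=8.0, seed=0)
logged = log_normalize(ds.counts)
features = minmax_scale(logged.subset_genes(select_hvg(logged, 250)))
graph = build_graph(minmax_scale(logged), k=5, metric="pearson")
config = TrainingConfig(epochs=200, inner_dims=(32,), n_heads=2,
                        latent_dim=16, seed=0, holdout_fraction=0.1)
model, embedding, attention, history = fit(features.values, graph, config)

clusters = cluster_latent(embedding.Z.detach())
ari = adjusted_rand_index(clusters.labels, ds.true_labels, drop_noise=True)

print(f"graph: {graph.n_nodes} cells, {graph.n_edges} edges")
print(f"final loss {history.loss[-1]:.3f}, "
      f"held-out edge AUC {history.holdout_auc[-1]:.3f}")
print(f"clusters found: {clusters.n_clusters} ({clusters.n_noise} noise cells)")
print(f"ARI vs planted labels: {ari:.3f}")
```

Output of this exact script:

```
graph: 300 cells, 1106 edges
final loss 0.578, held-out edge AUC 0.756
clusters found: 4 (20 noise cells)
ARI vs planted labels: 0.952
```

The three planted populations are recovered almost perfectly (ARI 0.95;
one cluster is split in two by HDBSCAN at this seed, and 20 cells are left
unassigned — HDBSCAN "noise", reported separately rather than forced into
a cluster). The held-out AUC is the ROC-AUC of the inner-product decoder
on 10% of edges removed before training, the convergence signal.

The same workflow runs from the shell on Matrix Market or CSV inputs:

```
scvgae --input counts.csv --graph pknn --k 5 --hvg 250 \
       --layer-dims 32 --heads 2 --latent 16 --epochs 200 \
       --seed 0 --outdir run/
```

writing the embedding, cluster labels, metrics JSON, attention TSV and the
per-cluster marker-gene report into `run/`.

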