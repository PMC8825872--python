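# Methods

## Model

`scvgae` learns per-cell latent variables z_i ∈ R^L from node features
**X** (N cells × D genes) and a simple, undirected cell graph **A**. The
inference model is q(z_i | X, A) = N(μ_i, diag σ_i²) with μ and log σ
produced by two parallel graph-attention output layers on top of a shared
stack of inner layers; the generative model reconstructs only the graph,
p(A_ij = 1 | z_i, z_j) = sigmoid(z_iᵀ z_j). Features are not reconstructed
by default — an optional linear decoder with an MSE term can be enabled
(`use_feature_recon`), which in our experience changes results little
while adding D×L parameters.

### Attention layers

A GAT head applies a shared linear map W (stored D_out × D_in, applied as
h Wᵀ) and scores each ordered pair as
e_ij = LeakyReLU(aᵀ[Wh_i ‖ Wh_j]), slope 0.2 (the published GAT default).
The attention neighbourhood of cell i is N(i) ∪ {i}: a self-loop is added
for attention only, so a cell can fall back on its own features; the cell
graph itself stays simple. Scores are softmax-normalized per cell, so
every attention row sums to 1 (asserted to 1e-6 in tests). Inner layers
concatenate K heads (output width K·D_out) with ReLU between layers;
output layers average heads. GATv2 (score aᵀLeakyReLU(W[h_i ‖ h_j]), with
separate target/source blocks of W) and the symmetric-normalized GCN rule
D̃^{-1/2}ÃD̃^{-1/2}hW (Ã = A + I) are provided behind the same interface;
GCN exposes no attention coefficients. Attention dropout is not applied
(knob reserved; default 0).

All layers, the autodiff engine behind them (reverse-mode over NumPy,
`scvgae.autodiff`) and the Adam optimizer are implemented in-package. The
engine provides exactly the primitives message passing needs — gather /
segment-sum / per-segment softmax with hand-derived adjoints — and is
validated by a central-difference gradient check (agreement to 1e-4
asserted; observed ≈ 1e-10).

### Loss

The minimized objective is `regularizer + edge BCE (+ optional MSE)`.

* **Edge BCE** — −(1/E)(Σ log ŷ_pos + Σ log(1 − ŷ_neg)) with one uniformly
  sampled non-edge per positive edge, re-drawn each epoch; E counts
  positives and negatives jointly. Probabilities are clamped at 1e-15.
* **KL** — Σ_dims 0.5(μ² + σ² − 1 − log σ²), averaged over cells, then
  weighted by 1/N (the convention of the reference VGAE implementations).
  The weighting matters: at full weight the per-node KL dominates the
  edge-mean BCE and the posterior collapses to the prior (μ→0, σ→1,
  held-out AUC 0.5) on every problem we tried. `reg_weight` overrides.
* **MMD** (alternative regularizer) — biased MMD² between the latent
  sample and fresh standard-normal draws, Gaussian kernel
  k(x,y) = exp(−‖x−y‖²/(2·bandwidth)), default bandwidth = L (a
  median-heuristic is deliberately not the default so the loss is
  deterministic given the sample); weighted 1.0 by default.

## Training and defaults

Full-graph gradient descent with Adam, lr 1e-2, 200 epochs. The defaults
follow the method's stated global choices — k = 5 neighbours, KL loss —
with one inner layer of 32 units × 2 heads and L = 16 latent dimensions
as a compact configuration that converges on hundreds-of-cells problems;
all of it is configurable. lr 1e-3 was tried first and converges too
slowly to be useful within 200 full-graph epochs. When
`holdout_fraction > 0`, that fraction of edges is removed before training
and the decoder's ROC-AUC on them (vs an equal number of sampled
non-edges) is logged per epoch as the convergence/overfitting signal.

The embedding handed downstream is **μ**, not a sample Z — downstream
clustering is therefore deterministic given a trained model. Divergence
(non-finite loss) aborts with a diagnostic rather than continuing.

## Preprocessing

Counts are scaled per cell to a fixed total (default 10 000) and log1p
transformed; every gene is then min-max scaled to [0, 1] (constant genes
map to 0 — they carry no signal and a constant bias feature is not
injected). Cells with zero total counts are an error, named explicitly.

HVGs are ranked by dispersion = variance/mean with ties to the lower gene
index. Dispersion is measured on the **normalized count scale** (expm1 of
the log data — the Seurat-v1 convention): on the log scale the statistic
is dominated by lowly expressed noisy genes and buries genuinely
structured genes; with the count-scale statistic the synthetic generator's
fold-8 markers occupy the top of the ranking, as they should. The number
of HVGs used as node features (`n_hvg`) and the number used to build the
graph (`khvg`) are independent.

## Graph construction

Each cell's k nearest neighbours are found under Euclidean, Manhattan,
cosine or Pearson distance (1 − r; ranking by distance or by raw r is
equivalent) on the scaled features, optionally restricted to `khvg` genes
and/or projected by PCA. Distances are computed as a full O(n²) matrix
with ties broken to the lower index, so graphs are exactly reproducible.
The directed k-NN lists are symmetrized by **union** (an edge survives if
either endpoint chose the other): union preserves connectivity, whereas
mutual-KNN can isolate boundary cells. Custom graphs are accepted as
0-based edge lists; self-loops are dropped with a warning, duplicates
collapse.

## Clustering

HDBSCAN (scikit-learn implementation) labels the latent μ; unassigned
cells are **noise** (label −1), counted and reported separately rather
than forced into clusters. Default min_cluster_size = max(5, 0.5% of
cells). An optional rescue pass re-clusters *only* the noise cells at a
smaller minimum size (`allow_single_cluster` enabled, since the noise set
typically hides at most one tiny group); it can only add clusters, never
modify existing ones — the conservative choice for catching very small
populations the main pass missed.

ARI treats noise cells either as excluded (default for comparisons where
noise is reported separately) or as per-point singletons; both modes are
exposed because reported scores in the literature are ambiguous on this
point. Silhouette always excludes noise and requires ≥ 2 clusters.

## Interpretability

* Overlay direction defaults to **incoming** attention (mean of α_ij over
  j for each target i — the contribution the model assigns *to* a cell);
  outgoing is exposed.
* `top_attention_edges` keeps α_ij and α_ji distinct (the attention graph
  is directed); ties break lexicographically for determinism.
* Weight products stack per-head W blocks of concat layers to the K·D
  width and average the head matrices of the mean-aggregated output
  layers, so P_μ equals the Jacobian of the activation-free,
  attention-frozen encoder path (checked numerically in tests).
* Cluster → latent-dimension relevance is the mean |embedding| of the
  cluster's cells per dimension — the linking statistic is not uniquely
  determined by prior art; this choice mirrors the DiffVAE-style weights
  analysis and is the main fidelity risk for reproducing specific gene
  lists. Gene ranking uses |P_μ| (sign carries direction, magnitude
  salience); per dimension the top 15 genes are kept, appearance counts
  accumulate per cluster, and once-appearing genes inside the global
  top-100 |P_μ| entries are reported separately. On the synthetic
  benchmark the edge-only training objective gives the weight products
  only a weak pull toward the planted markers (the integration test
  prints the recovered fraction rather than asserting a threshold);
  marker retrieval should be read as a hypothesis generator, not a
  differential-expression substitute.

## Synthetic data

`generate_counts` draws per-gene base means from LogNormal(log base_mean,
1), multiplies each cluster's disjoint marker genes by `fold_change`, and
samples negative-binomial counts with dispersion θ (default 2.0,
i.e. clearly overdispersed relative to Poisson; variance m + m²/θ).
Cluster sizes are balanced unless an `imbalance` weight vector is given
(for planting tiny populations). Cells that come out empty get one count
added to their first gene so normalization is defined. The generator
emulates count overdispersion and marker structure only — no library-size
gradients, batch effects, gene-gene correlation or ambient contamination —
so passing tests demonstrate correctness of the machinery, not performance
on real tissue. `generate_block_graph` draws a stochastic block model
(p_out ≤ p_in; equality gives Erdős–Rényi) for link-prediction fixtures.

Benchmark problem sizes used by tests and `scripts/acceptance.py`: the
recovery study uses 300 cells × 500 genes, 3 clusters, fold change 8,
20 markers/cluster, PKNN k = 5, 200 epochs, ten seeds (a scale at which
one run takes a few seconds); the link-prediction fixture uses 30 nodes,
p_in = 0.95, p_out = 0.02, 300 epochs, 30% of edges held out.

## Numerical choices and degenerate inputs

* Neighbour and gene-ranking ties always resolve to the lower index.
* Segment softmax subtracts the per-segment max before exponentiation.
* Decoder probabilities clamp at 1e-15 before the log.
* An all-identical latent matrix short-circuits HDBSCAN to one cluster
  (its density estimate is undefined there).
* A complete graph has no negative edges and is rejected; requesting more
  negatives than non-edges is an error, not silent truncation.
* All randomness — initialization, reparameterization noise, negative
  sampling, holdout splits, generators — flows from explicit seeds; same
  config and seed reproduce results bit-for-bit.

## Known limitations

Full-graph training is O(E) per epoch in attention storage and is meant
for datasets up to tens of thousands of cells on CPU; there is no
mini-batching or neighbour sampling. The KNN builder materializes the
O(n²) distance matrix. Only an inner-product edge decoder is provided (no
ZINB/count likelihoods). Attention heads are not regularized toward
diversity.
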