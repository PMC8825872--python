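"""Full-graph training loop with negative edge sampling and held-out edge
monitoring.

Each epoch draws a fresh set of negative (non-)edges, one per positive
edge, and takes one Adam step on the full-graph loss. When a holdout
fraction is given, that fraction of edges is removed from the training
graph up front and the decoder's ROC-AUC on held-out positives versus an
equal number of negatives is tracked per epoch as a convergence signal.
The embedding handed to downstream analysis is the posterior mean μ, so
clustering on a trained model is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor
from .graph import CellGraph
from .model import (VGAE, EncoderOutput, LatentEmbedding, decode_edge_prob,
                    feature_recon_loss, kl_loss, mmd_loss, recon_loss,
                    reparameterize, total_loss)

__all__ = ["TrainingConfig", "TrainingHistory", "Adam",
           "sample_negative_edges", "holdout_split", "fit"]


@dataclass
class TrainingConfig:
    """Hyperparameters for one training run.

    Graph defaults follow the method's stated global choices: k = 5
    neighbours and the KL regularizer; everything else is configurable.
    """

    k: int = 5
    khvg: int | None = None
    n_hvg: int | None = None
    inner_dims: tuple = (32,)
    n_heads: int | tuple = 2
    latent_dim: int = 16
    layer_kind: str = "gat"
    reg_kind: str = "kl"
    use_feature_recon: bool = False
    epochs: int = 200
    learning_rate: float = 1e-2
    seed: int = 0
    holdout_fraction: float = 0.0
    mmd_bandwidth: float | None = None
    # weight on the regularizer; None = 1/n_nodes, the Kipf/PyG VGAE
    # convention, which keeps the per-node KL from overwhelming the
    # edge-mean reconstruction term (full weight collapses the posterior)
    reg_weight: float | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.holdout_fraction < 0.5):
            raise ValueError("holdout_fraction must be in [0, 0.5)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    reg: list = field(default_factory=list)
    recon: list = field(default_factory=list)
    feature: list = field(default_factory=list)
    holdout_auc: list = field(default_factory=list)


class Adam:
    """Standard Adam over a flat list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sample_negative_edges(graph: CellGraph, n: int,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw `n` distinct non-edges (no self-loops) uniformly by rejection."""
    n_nodes = graph.n_nodes
    max_edges = n_nodes * (n_nodes - 1) // 2
    n_available = max_edges - graph.n_edges
    if n_available == 0:
        raise ValueError("graph is complete; no negative edges exist")
    if n > n_available:
        raise ValueError(f"requested {n} negatives but only {n_available} non-edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    existing = graph.edge_set()
    chosen: set = set()
    out = np.empty((n, 2), dtype=np.intp)
    filled = 0
    while filled < n:
        batch = rng.integers(0, n_nodes, size=(max(64, 2 * (n - filled)), 2))
        for i, j in batch:
            if i == j:
                continue
            pair = (i, j) if i < j else (j, i)
            if pair in existing or pair in chosen:
                continue
            chosen.add(pair)
            out[filled] = pair
            filled += 1
            if filled == n:
                break
    return out


def holdout_split(graph: CellGraph, fraction: float,
                  seed: int = 0) -> tuple[CellGraph, np.ndarray]:
    """Remove a random edge fraction for convergence monitoring.

    Returns (training graph, held-out positive edges). The node set is
    unchanged; with fraction 0 the input graph is returned untouched.
    """
    if fraction == 0:
        return graph, np.empty((0, 2), dtype=np.intp)
    n_hold = int(round(graph.n_edges * fraction))
    if graph.n_edges - n_hold < 1:
        raise ValueError("holdout fraction leaves no training edges")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(graph.n_edges)
    held = graph.edges[perm[:n_hold]]
    kept = graph.edges[perm[n_hold:]]
    return CellGraph(n_nodes=graph.n_nodes, edges=kept), held


def _holdout_auc(mu: np.ndarray, held_pos: np.ndarray, held_neg: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score
    def scores(edges):
        return decode_edge_prob(Tensor(mu[edges[:, 0]]),
                                Tensor(mu[edges[:, 1]])).detach()
    y = np.concatenate([np.ones(len(held_pos)), np.zeros(len(held_neg))])
    s = np.concatenate([scores(held_pos), scores(held_neg)])
    return float(roc_auc_score(y, s))


def fit(X: np.ndarray, graph: CellGraph, config: TrainingConfig,
        model: VGAE | None = None):
    """Train a VGAE on one full graph.

    Returns (model, LatentEmbedding of μ, last-epoch attention records,
    TrainingHistory). Raises ``RuntimeError`` on divergence (NaN loss).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != graph.n_nodes:
        raise ValueError("feature rows != graph nodes")
    rng = np.random.default_rng(config.seed)
    train_graph, held_pos = holdout_split(graph, config.holdout_fraction,
                                          seed=config.seed)
    held_neg = (sample_negative_edges(graph, len(held_pos), seed=rng)
                if len(held_pos) else np.empty((0, 2), dtype=np.intp))
    if model is None:
        model = VGAE(d_in=X.shape[1], inner_dims=config.inner_dims,
                     latent_dim=config.latent_dim, n_heads=config.n_heads,
                     layer_kind=config.layer_kind,
                     feature_recon=config.use_feature_recon, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    pos = train_graph.edges
    Xt = Tensor(X)
    records = []
    for epoch in range(config.epochs):
        neg = sample_negative_edges(train_graph, len(pos), seed=rng)
        enc, records = model.encode(Xt, train_graph)
        z = reparameterize(enc, eps=rng.standard_normal(enc.mu.shape))
        if config.reg_kind == "kl":
            reg_w = (1.0 / graph.n_nodes if config.reg_weight is None
                     else config.reg_weight)
            reg = kl_loss(enc) * reg_w
        else:
            reg_w = 1.0 if config.reg_weight is None else config.reg_weight
            prior = rng.standard_normal(z.Z.shape)
            reg = mmd_loss(z, prior, kernel_bandwidth=config.mmd_bandwidth) * reg_w
        recon = recon_loss(z, pos, neg)
        feat = None
        if config.use_feature_recon:
            feat = feature_recon_loss(z, Xt, model.recon_net)
        loss = total_loss(reg, recon, feat, reg_kind=config.reg_kind,
                          use_feature_recon=config.use_feature_recon)
        if not np.isfinite(loss.detach()):
            raise RuntimeError(f"training diverged at epoch {epoch}: loss is not finite")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.loss.append(float(loss.detach()))
        history.reg.append(float(reg.detach()))
        history.recon.append(float(recon.detach()))
        history.feature.append(float(feat.detach()) if feat is not None else 0.0)
        if len(held_pos):
            history.holdout_auc.append(
                _holdout_auc(enc.mu.detach(), held_pos, held_neg))
        else:
            history.holdout_auc.append(float("nan"))
    enc, records = model.encode(Tensor(X), train_graph)
    embedding = LatentEmbedding(Z=Tensor(enc.mu.detach().copy()), seed=config.seed)
    return model, embedding, records, history
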