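"""Variational graph autoencoder for cell graphs.

The encoder is a stack of inner graph-attention layers (multi-head,
concatenated, ReLU between layers) followed by two parallel output layers
(heads averaged) producing the per-cell posterior mean μ and log σ. The
decoder scores an edge (i, j) as sigmoid(z_i · z_j). Training minimizes

    loss = regularizer + edge BCE (+ optional feature-reconstruction MSE)

where the regularizer is either the analytic KL divergence to N(0, I) or a
kernel MMD between the latent sample and prior draws. The KL is averaged
over cells; the BCE is averaged jointly over positive and sampled negative
edges so losses are comparable across graph sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .graph import CellGraph
from .layers import GATLayer, GATv2Layer, GCNLayer

__all__ = ["EncoderOutput", "LatentEmbedding", "VGAE", "kl_loss", "mmd_loss",
           "recon_loss", "feature_recon_loss", "total_loss", "decode_edge_prob",
           "reparameterize"]

_LAYER_KINDS = {"gat": GATLayer, "gatv2": GATv2Layer, "gcn": GCNLayer}
_CLAMP = 1e-15


@dataclass
class EncoderOutput:
    """Posterior parameters per cell: mean and log standard deviation."""

    mu: Tensor
    log_sigma: Tensor

    def __post_init__(self):
        if self.mu.shape != self.log_sigma.shape:
            raise ValueError("mu and log_sigma shapes differ")


@dataclass
class LatentEmbedding:
    """A sampled latent matrix Z (cells × latent dims) and the seed used."""

    Z: Tensor
    seed: int | None = None


class VGAE:
    """Encoder/decoder pair; see the module docstring for the architecture.

    Parameters
    ----------
    d_in : input feature width (number of genes used as node features).
    inner_dims : per-head output width of each inner layer.
    latent_dim : width L of μ, log σ and Z.
    n_heads : attention heads, one entry per inner layer plus one for the
        two output layers (an int is broadcast to all layers).
    layer_kind : 'gat' (default), 'gatv2' or 'gcn'.
    """

    def __init__(self, d_in: int, inner_dims=(32,), latent_dim: int = 16,
                 n_heads=1, layer_kind: str = "gat", negative_slope: float = 0.2,
                 feature_recon: bool = False, seed: int = 0):
        if layer_kind not in _LAYER_KINDS:
            raise ValueError(f"unknown layer kind '{layer_kind}'")
        inner_dims = list(inner_dims)
        if not inner_dims:
            raise ValueError("at least one inner layer is required")
        n_layers = len(inner_dims) + 1
        if isinstance(n_heads, int):
            heads = [n_heads] * n_layers
        else:
            heads = list(n_heads)
            if len(heads) != n_layers:
                raise ValueError(
                    f"n_heads needs {n_layers} entries (inner layers + output)")
        cls = _LAYER_KINDS[layer_kind]
        rng = np.random.default_rng(seed)
        self.layer_kind = layer_kind
        self.d_in, self.inner_dims, self.latent_dim = d_in, inner_dims, latent_dim
        self.n_heads = heads
        self.inner_layers = []
        width = d_in
        for li, (d, k) in enumerate(zip(inner_dims, heads[:-1])):
            layer = cls(width, d, n_heads=k, aggregate="concat",
                        negative_slope=negative_slope, layer_id=li, rng=rng)
            self.inner_layers.append(layer)
            width = layer.out_dim
        self.mu_layer = cls(width, latent_dim, n_heads=heads[-1],
                            aggregate="mean", negative_slope=negative_slope,
                            layer_id=len(inner_dims), rng=rng)
        self.logsigma_layer = cls(width, latent_dim, n_heads=heads[-1],
                                  aggregate="mean", negative_slope=negative_slope,
                                  layer_id=len(inner_dims), rng=rng)
        self.recon_net = None
        if feature_recon:
            from .layers import _glorot
            self.recon_W = Tensor(_glorot(rng, (d_in, latent_dim)), requires_grad=True)
            self.recon_b = Tensor(np.zeros(d_in), requires_grad=True)
            self.recon_net = lambda z: z @ self.recon_W.T + self.recon_b.reshape(1, -1)

    def parameters(self) -> list[Tensor]:
        params = []
        for layer in self.inner_layers + [self.mu_layer, self.logsigma_layer]:
            params.extend(layer.parameters())
        if self.recon_net is not None:
            params.extend([self.recon_W, self.recon_b])
        return params

    def encode(self, X, graph: CellGraph):
        """Run the encoder; returns (EncoderOutput, list of AttentionRecord)."""
        h = X if isinstance(X, Tensor) else Tensor(X)
        records = []
        for i, layer in enumerate(self.inner_layers):
            if i > 0:
                h = h.relu()
            h, rec = layer(h, graph)
            if rec is not None:
                records.append(rec)
        h = h.relu()
        mu, rec_mu = self.mu_layer(h, graph)
        log_sigma, rec_sigma = self.logsigma_layer(h, graph)
        if rec_mu is not None:
            records.extend([rec_mu, rec_sigma])
        return EncoderOutput(mu=mu, log_sigma=log_sigma), records

    def save(self, path) -> None:
        """Checkpoint all parameters plus the architecture config (.npz)."""
        import json
        config = {
            "d_in": self.d_in, "inner_dims": self.inner_dims,
            "latent_dim": self.latent_dim, "n_heads": self.n_heads,
            "layer_kind": self.layer_kind,
            "feature_recon": self.recon_net is not None,
        }
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, config=json.dumps(config), **arrays)

    @classmethod
    def load(cls, path) -> "VGAE":
        import json
        with np.load(path, allow_pickle=False) as data:
            config = json.loads(str(data["config"]))
            model = cls(d_in=config["d_in"], inner_dims=config["inner_dims"],
                        latent_dim=config["latent_dim"],
                        n_heads=config["n_heads"],
                        layer_kind=config["layer_kind"],
                        feature_recon=config["feature_recon"])
            for i, p in enumerate(model.parameters()):
                loaded = data[f"param_{i}"]
                if loaded.shape != p.data.shape:
                    raise ValueError(f"checkpoint parameter {i} has shape "
                                     f"{loaded.shape}, expected {p.data.shape}")
                p.data = loaded.copy()
        return model

    # weight matrices for interpretability (heads stacked for concat layers,
    # averaged for the mean-aggregated output layers)
    def stacked_weights(self) -> dict:
        def stack(layer):
            return np.concatenate([w.data for w in layer.W], axis=0)

        def head_mean(layer):
            return np.mean([w.data for w in layer.W], axis=0)

        return {
            "inner": [stack(l) for l in self.inner_layers],
            "mu": head_mean(self.mu_layer),
            "sigma": head_mean(self.logsigma_layer),
        }


def reparameterize(enc: EncoderOutput, seed: int | None = 0,
                   eps: np.ndarray | None = None) -> LatentEmbedding:
    """Sample Z = μ + exp(log σ) ⊙ ε with ε ~ N(0, I); seeded and
    reproducible. Pass ``eps`` explicitly to force the noise (tests)."""
    if eps is None:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(enc.mu.shape)
    sigma = enc.log_sigma.exp()
    return LatentEmbedding(Z=enc.mu + sigma * Tensor(eps), seed=seed)


def decode_edge_prob(z_i, z_j):
    """Edge probability sigmoid(z_i · z_j); accepts vectors or row batches."""
    zi = z_i if isinstance(z_i, Tensor) else Tensor(z_i)
    zj = z_j if isinstance(z_j, Tensor) else Tensor(z_j)
    if zi.shape != zj.shape:
        raise ValueError("latent vectors must have equal shapes")
    if zi.ndim == 1:
        return (zi * zj).sum().sigmoid()
    return (zi * zj).sum(axis=1).sigmoid()


def kl_loss(enc: EncoderOutput) -> Tensor:
    """KL[N(μ, diag σ²) ‖ N(0, I)], summed over latent dims, mean over cells."""
    mu, log_sigma = enc.mu, enc.log_sigma
    per_cell = (mu.square() + (log_sigma * 2.0).exp()
                - 1.0 - log_sigma * 2.0).sum(axis=1) * 0.5
    return per_cell.mean()


def mmd_loss(Z, prior_samples, kernel_bandwidth: float | None = None) -> Tensor:
    """Biased MMD² between latent rows and prior draws, Gaussian kernel
    k(x, y) = exp(−‖x−y‖² / (2·bandwidth)). Default bandwidth = latent dim."""
    z = Z.Z if isinstance(Z, LatentEmbedding) else Z
    z = z if isinstance(z, Tensor) else Tensor(z)
    p = prior_samples if isinstance(prior_samples, Tensor) else Tensor(prior_samples)
    if z.data.size == 0 or p.data.size == 0:
        raise ValueError("empty sample set")
    if z.shape[1] != p.shape[1]:
        raise ValueError("dimensionality mismatch")
    if kernel_bandwidth is None:
        kernel_bandwidth = float(z.shape[1])

    def kernel_mean(a: Tensor, b: Tensor) -> Tensor:
        sq_a = a.square().sum(axis=1).reshape(-1, 1)
        sq_b = b.square().sum(axis=1).reshape(1, -1)
        d2 = sq_a + sq_b - (a @ b.T) * 2.0
        return (d2 * (-1.0 / (2.0 * kernel_bandwidth))).exp().mean()

    return kernel_mean(z, z) + kernel_mean(p, p) - kernel_mean(z, p) * 2.0


def recon_loss(Z, pos_edges: np.ndarray, neg_edges: np.ndarray) -> Tensor:
    """Edge binary cross-entropy with negative sampling, averaged jointly
    over all |pos| + |neg| edges; probabilities clamped away from 0/1."""
    z = Z.Z if isinstance(Z, LatentEmbedding) else Z
    z = z if isinstance(z, Tensor) else Tensor(z)
    pos_edges = np.asarray(pos_edges, dtype=np.intp).reshape(-1, 2)
    neg_edges = np.asarray(neg_edges, dtype=np.intp).reshape(-1, 2)
    if len(pos_edges) == 0:
        raise ValueError("at least one positive edge is required")
    from .autodiff import gather_rows
    total = len(pos_edges) + len(neg_edges)
    y_pos = decode_edge_prob(gather_rows(z, pos_edges[:, 0]),
                             gather_rows(z, pos_edges[:, 1]))
    loss = -(y_pos.clamp(_CLAMP, 1.0).log().sum())
    if len(neg_edges):
        y_neg = decode_edge_prob(gather_rows(z, neg_edges[:, 0]),
                                 gather_rows(z, neg_edges[:, 1]))
        loss = loss - ((1.0 - y_neg).clamp(_CLAMP, 1.0).log().sum())
    return loss * (1.0 / total)


def feature_recon_loss(Z, X, recon_net) -> Tensor:
    """Mean squared error between recon_net(Z) and the node features."""
    z = Z.Z if isinstance(Z, LatentEmbedding) else Z
    z = z if isinstance(z, Tensor) else Tensor(z)
    x = X if isinstance(X, Tensor) else Tensor(X)
    pred = recon_net(z)
    if pred.shape != x.shape:
        raise ValueError(f"reconstruction shape {pred.shape} != features {x.shape}")
    return (pred - x).square().mean()


def total_loss(reg, recon, feature=None, reg_kind: str = "kl",
               use_feature_recon: bool = False) -> Tensor:
    """Sum the loss components; the returned scalar is minimized."""
    if reg_kind not in ("kl", "mmd"):
        raise ValueError(f"unknown regularizer '{reg_kind}'")
    out = reg + recon
    if use_feature_recon:
        if feature is None:
            raise ValueError("feature reconstruction enabled but no term given")
        out = out + feature
    return out
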