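"""Graph convolution layers: multi-head graph attention (GAT), the GATv2
variant, and a symmetric-normalized GCN layer.

Conventions
-----------
* Weight matrices are stored ``(D_out, D_in)`` and applied as ``h @ W.T``.
* The attention neighbourhood of node *i* is its graph neighbours plus
  itself — a self-loop is added for attention only; the cell graph itself
  stays simple. For each head, ``alpha[i, j]`` over that neighbourhood is a
  softmax, so every attention row sums to 1.
* GAT scores each pair as ``LeakyReLU(a^T [W h_i || W h_j])`` (slope 0.2);
  GATv2 moves the nonlinearity inside, ``a^T LeakyReLU(W [h_i || h_j])``,
  which makes the ranking of neighbours input-dependent.
* Inner layers concatenate head outputs (width K·D_out); output layers
  average heads (width D_out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_softmax, segment_sum
from .graph import CellGraph

__all__ = ["AttentionRecord", "GATLayer", "GATv2Layer", "GCNLayer",
           "attention_edge_index"]


def attention_edge_index(graph: CellGraph) -> tuple[np.ndarray, np.ndarray]:
    """Directed (target, source) arrays: both directions of every undirected
    edge plus one self-loop per node, sorted by (target, source)."""
    n = graph.n_nodes
    if graph.n_edges:
        e = graph.edges
        tgt = np.concatenate([e[:, 0], e[:, 1], np.arange(n)])
        src = np.concatenate([e[:, 1], e[:, 0], np.arange(n)])
    else:
        tgt = src = np.arange(n)
    order = np.lexsort((src, tgt))
    return tgt[order], src[order]


@dataclass
class AttentionRecord:
    """Per-layer attention coefficients α_ij (target i attends to source j).

    ``alpha`` has shape (n_heads, n_directed_edges); the edge list includes
    self-loops. α_ij and α_ji are distinct entries, so the induced attention
    graph is weighted and directed.
    """

    layer_id: int
    tgt: np.ndarray
    src: np.ndarray
    alpha: np.ndarray
    n_nodes: int

    @property
    def n_heads(self) -> int:
        return self.alpha.shape[0]

    def head_mean(self) -> np.ndarray:
        """Coefficients averaged across attention heads, shape (n_edges,)."""
        return self.alpha.mean(axis=0)

    def row_sums(self, head: int) -> np.ndarray:
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.tgt, self.alpha[head])
        return out

    def to_rows(self):
        """Yield (layer, head, target, source, alpha) export tuples."""
        for h in range(self.n_heads):
            for t, s, a in zip(self.tgt, self.src, self.alpha[h]):
                yield (self.layer_id, h, int(t), int(s), float(a))


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[-2] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class GATLayer:
    """One multi-head graph attention layer.

    Parameters per head: weight ``W`` (d_out × d_in), attention vector ``a``
    (length 2·d_out, split into target and source halves), and a bias
    (zero-initialized). ``aggregate`` is 'concat' (inner layers) or 'mean'
    (output layers).
    """

    kind = "gat"

    def __init__(self, d_in: int, d_out: int, n_heads: int = 1,
                 aggregate: str = "concat", negative_slope: float = 0.2,
                 layer_id: int = 0, rng: np.random.Generator | None = None):
        if aggregate not in ("concat", "mean"):
            raise ValueError(f"unknown aggregate '{aggregate}'")
        if n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.d_in, self.d_out, self.n_heads = d_in, d_out, n_heads
        self.aggregate = aggregate
        self.negative_slope = negative_slope
        self.layer_id = layer_id
        self.W = [Tensor(_glorot(rng, (d_out, d_in)), requires_grad=True)
                  for _ in range(n_heads)]
        self.a_tgt = [Tensor(_glorot(rng, (d_out,)), requires_grad=True)
                      for _ in range(n_heads)]
        self.a_src = [Tensor(_glorot(rng, (d_out,)), requires_grad=True)
                      for _ in range(n_heads)]
        self.bias = Tensor(np.zeros(self.out_dim), requires_grad=True)

    @property
    def out_dim(self) -> int:
        return self.d_out * self.n_heads if self.aggregate == "concat" else self.d_out

    def parameters(self) -> list[Tensor]:
        return self.W + self.a_tgt + self.a_src + [self.bias]

    def _head_scores(self, wh: Tensor, tgt, src) -> Tensor:
        raise NotImplementedError

    def forward(self, h: Tensor, graph: CellGraph) -> tuple[Tensor, AttentionRecord]:
        if h.shape[1] != self.d_in:
            raise ValueError(f"feature width {h.shape[1]} != layer d_in {self.d_in}")
        n = graph.n_nodes
        if h.shape[0] != n:
            raise ValueError("feature rows != graph nodes")
        tgt, src = attention_edge_index(graph)
        head_outputs, head_alphas = [], []
        for k in range(self.n_heads):
            wh = h @ self.W[k].T  # (n, d_out)
            e = self._score(wh, h, tgt, src, k)
            alpha = segment_softmax(e, tgt, n)
            msgs = gather_rows(wh, src) * alpha.reshape(-1, 1)
            head_outputs.append(segment_sum(msgs, tgt, n))
            head_alphas.append(alpha.detach())
        if self.aggregate == "concat":
            out = concat(head_outputs, axis=1)
        else:
            out = head_outputs[0]
            for ho in head_outputs[1:]:
                out = out + ho
            out = out * (1.0 / self.n_heads)
        out = out + self.bias.reshape(1, -1)
        record = AttentionRecord(layer_id=self.layer_id, tgt=tgt, src=src,
                                 alpha=np.stack(head_alphas), n_nodes=n)
        return out, record

    __call__ = forward

    def _score(self, wh: Tensor, h: Tensor, tgt, src, k: int) -> Tensor:
        # e_ij = LeakyReLU(a_tgt . Wh_i + a_src . Wh_j)
        s_t = wh @ self.a_tgt[k].reshape(-1, 1)
        s_s = wh @ self.a_src[k].reshape(-1, 1)
        e = gather_rows(s_t, tgt) + gather_rows(s_s, src)
        return e.reshape(-1).leaky_relu(self.negative_slope)


class GATv2Layer(GATLayer):
    """GATv2: the LeakyReLU precedes the attention projection, so the
    attention ranking can depend on the target node ("dynamic" attention)."""

    kind = "gatv2"

    def __init__(self, d_in: int, d_out: int, n_heads: int = 1,
                 aggregate: str = "concat", negative_slope: float = 0.2,
                 layer_id: int = 0, rng: np.random.Generator | None = None):
        super().__init__(d_in, d_out, n_heads, aggregate, negative_slope,
                         layer_id, rng)
        rng2 = np.random.default_rng(0) if rng is None else rng
        # separate source-side transform (W acts on the concatenation
        # [h_i || h_j], split into target/source blocks)
        self.W_src = [Tensor(_glorot(rng2, (d_out, d_in)), requires_grad=True)
                      for _ in range(self.n_heads)]
        self.a = [Tensor(_glorot(rng2, (d_out,)), requires_grad=True)
                  for _ in range(self.n_heads)]

    def parameters(self) -> list[Tensor]:
        return self.W + self.W_src + self.a + [self.bias]

    def _score(self, wh: Tensor, h: Tensor, tgt, src, k: int) -> Tensor:
        lt = gather_rows(wh, tgt)
        rs = gather_rows(h @ self.W_src[k].T, src)
        z = (lt + rs).leaky_relu(self.negative_slope)
        return (z @ self.a[k].reshape(-1, 1)).reshape(-1)


class GCNLayer:
    """Kipf–Welling graph convolution: D̃^(−1/2) Ã D̃^(−1/2) h W with
    Ã = A + I. No attention coefficients are defined for this layer."""

    kind = "gcn"

    def __init__(self, d_in: int, d_out: int, layer_id: int = 0,
                 rng: np.random.Generator | None = None, **_ignored):
        rng = rng or np.random.default_rng(0)
        self.d_in, self.d_out = d_in, d_out
        self.layer_id = layer_id
        self.n_heads = 1
        self.aggregate = "none"
        self.W = [Tensor(_glorot(rng, (d_out, d_in)), requires_grad=True)]
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    @property
    def out_dim(self) -> int:
        return self.d_out

    def parameters(self) -> list[Tensor]:
        return self.W + [self.bias]

    def forward(self, h: Tensor, graph: CellGraph):
        if h.shape[1] != self.d_in:
            raise ValueError(f"feature width {h.shape[1]} != layer d_in {self.d_in}")
        n = graph.n_nodes
        tgt, src = attention_edge_index(graph)
        deg = np.zeros(n)
        np.add.at(deg, tgt, 1.0)  # includes the self-loop
        coef = 1.0 / np.sqrt(deg[tgt] * deg[src])
        wh = h @ self.W[0].T
        msgs = gather_rows(wh, src) * Tensor(coef.reshape(-1, 1))
        out = segment_sum(msgs, tgt, n) + self.bias.reshape(1, -1)
        return out, None

    __call__ = forward
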