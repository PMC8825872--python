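import warnings

import numpy as np
import pytest

from scvgae.graph import CellGraph
from scvgae.preprocess import ExpressionMatrix

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def small_matrix():
    """4 cells × 3 genes with simple integer counts."""
    values = np.array([
        [2.0, 0.0, 1.0],
        [4.0, 0.0, 1.0],
        [0.0, 3.0, 1.0],
        [1.0, 5.0, 1.0],
    ])
    return ExpressionMatrix(values=values,
                            cell_ids=[f"c{i}" for i in range(4)],
                            gene_ids=[f"g{j}" for j in range(3)])


@pytest.fixture
def path_graph():
    """0 – 1 path on two nodes."""
    return CellGraph(n_nodes=2, edges=np.array([[0, 1]]))


@pytest.fixture
def six_node_graph():
    return CellGraph(6, np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 5],
                                  [0, 5], [1, 4]]))


def dense_gat_oracle(h, Ws, a_tgts, a_srcs, graph, aggregate="concat",
                     negative_slope=0.2, variant="gat", W_srcs=None, a_vs=None):
    """Brute-force dense-loop GAT/GATv2 forward (no autodiff, O(n²) loops).

    Kept deliberately independent of scvgae.layers: adjacency handled via a
    dense matrix, softmax computed per row with explicit loops.
    """
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    A = graph.adjacency() + np.eye(n)  # attention neighbourhood incl. self
    outs, alphas = [], []
    for k in range(len(Ws)):
        W = np.asarray(Ws[k])
        wh = h @ W.T
        e = np.full((n, n), -np.inf)
        for i in range(n):
            for j in range(n):
                if A[i, j] == 0:
                    continue
                if variant == "gat":
                    raw = a_tgts[k] @ wh[i] + a_srcs[k] @ wh[j]
                    e[i, j] = raw if raw > 0 else negative_slope * raw
                else:  # gatv2
                    z = wh[i] + h[j] @ np.asarray(W_srcs[k]).T
                    z = np.where(z > 0, z, negative_slope * z)
                    e[i, j] = a_vs[k] @ z
        alpha = np.zeros((n, n))
        for i in range(n):
            nbr = np.flatnonzero(np.isfinite(e[i]))
            ex = np.exp(e[i, nbr] - e[i, nbr].max())
            alpha[i, nbr] = ex / ex.sum()
        out = np.zeros((n, W.shape[0]))
        for i in range(n):
            for j in range(n):
                out[i] += alpha[i, j] * wh[j]
        outs.append(out)
        alphas.append(alpha)
    if aggregate == "concat":
        return np.concatenate(outs, axis=1), alphas
    return np.mean(outs, axis=0), alphas


def dense_gcn_oracle(h, W, graph):
    """Brute-force D̃^(-1/2) Ã D̃^(-1/2) h Wᵀ with dense matrices."""
    n = graph.n_nodes
    A = graph.adjacency() + np.eye(n)
    d = A.sum(axis=1)
    norm = np.diag(d ** -0.5) @ A @ np.diag(d ** -0.5)
    return norm @ (np.asarray(h) @ np.asarray(W).T)


def brute_force_knn_edges(x, k, metric="euclidean"):
    """O(n²) KNN-union oracle with lower-index tie-breaks."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    edges = set()
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            if metric == "euclidean":
                d = float(np.sqrt(((x[i] - x[j]) ** 2).sum()))
            elif metric == "manhattan":
                d = float(np.abs(x[i] - x[j]).sum())
            elif metric == "cosine":
                d = 1.0 - float(x[i] @ x[j] /
                                (np.linalg.norm(x[i]) * np.linalg.norm(x[j])))
            elif metric == "pearson":
                d = 1.0 - float(np.corrcoef(x[i], x[j])[0, 1])
            dists.append((d, j))
        dists.sort()
        for _, j in dists[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges
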