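"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the primitives the graph-attention encoder and its losses
need: elementwise arithmetic, matrix products, row gather / segment
scatter-add (the sparse message-passing pair), a numerically stable
per-segment softmax, and the usual nonlinearities. Gradients are accumulated
by reverse topological sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate ``.grad`` after
    ``backward()`` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                pg = _unbroadcast(pg, parent.data.shape)
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(self.data + other.data, parents=(self, other),
                      backward=lambda g: ((self, g), (other, g)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: ((self, g * other.data), (other, g * self.data)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: ((self, g / other.data),
                                          (other, -g * self.data / other.data ** 2)))

    def __matmul__(self, other):
        other = self._lift(other)
        return Tensor(self.data @ other.data, parents=(self, other),
                      backward=lambda g: ((self, g @ other.data.T),
                                          (other, self.data.T @ g)))

    @property
    def T(self):
        return Tensor(self.data.T, parents=(self,), backward=lambda g: ((self, g.T),))

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=lambda g: ((self, g.reshape(old)),))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor(out, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: ((self, g * out),))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,),
                      backward=lambda g: ((self, g / self.data),))

    def square(self):
        return Tensor(self.data ** 2, parents=(self,),
                      backward=lambda g: ((self, 2.0 * g * self.data),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, parents=(self,),
                      backward=lambda g: ((self, g * out * (1.0 - out)),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,),
                      backward=lambda g: ((self, g * mask),))

    def leaky_relu(self, negative_slope: float = 0.2):
        slope = np.where(self.data > 0, 1.0, negative_slope)
        return Tensor(self.data * slope, parents=(self,),
                      backward=lambda g: ((self, g * slope),))

    def clamp(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor(np.clip(self.data, lo, hi), parents=(self,),
                      backward=lambda g: ((self, g * mask),))


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        return tuple(
            (t, np.take(g, range(offsets[i], offsets[i + 1]), axis=axis))
            for i, t in enumerate(tensors)
        )

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]``; backward scatter-adds into the source."""
    index = np.asarray(index, dtype=np.intp)

    def bwd(g):
        out = np.zeros_like(t.data)
        np.add.at(out, index, g)
        return ((t, out),)

    return Tensor(t.data[index], parents=(t,), backward=bwd)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given by `segment_ids`."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + t.data.shape[1:])
    np.add.at(out, segment_ids, t.data)
    return Tensor(out, parents=(t,), backward=lambda g: ((t, g[segment_ids]),))


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within each segment (stable, shifted).

    Used to normalize attention logits over each node's neighbourhood.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    s = scores.data
    # subtract per-segment max for stability
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, s)
    shifted = s - seg_max[segment_ids]
    ex = np.exp(shifted)
    denom = np.zeros(num_segments)
    np.add.at(denom, segment_ids, ex)
    alpha = ex / denom[segment_ids]

    def bwd(g):
        # d e_k = alpha_k * (g_k - sum_{j in seg(k)} alpha_j g_j)
        dot = np.zeros(num_segments)
        np.add.at(dot, segment_ids, alpha * g)
        return ((scores, alpha * (g - dot[segment_ids])),)

    return Tensor(alpha, parents=(scores,), backward=bwd)
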