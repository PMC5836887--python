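"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the encoder/decoder/discriminator networks in this
package: dense layers, 1-d convolutions, GRU cells, SELU/sigmoid/tanh
non-linearities and a fused log-softmax.  Graphs are built eagerly; calling
:meth:`Tensor.backward` on a scalar accumulates gradients into every reachable
tensor with ``requires_grad=True``.  The :func:`no_grad` context disables graph
recording for inference-time forward passes.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True

# SELU constants (self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        def bwd(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._coerce(other)
        def bwd(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))
        return Tensor._make(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g, out: (-g,))

    def __mul__(self, other):
        other = self._coerce(other)
        def bwd(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        def bwd(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data ** 2, other.shape),
            )
        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)
        def bwd(g, out):
            return (g @ other.data.T, self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), bwd)

    def __getitem__(self, idx):
        def bwd(g, out):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return (gx,)
        return Tensor._make(self.data[idx], (self,), bwd)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        def bwd(g, out):
            return (g.reshape(self.shape),)
        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise non-linearities ----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g, out: (g * out.data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g, out: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g, out: (g * (1.0 - out.data ** 2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        return Tensor._make(
            out_data, (self,), lambda g, out: (g * out.data * (1.0 - out.data),)
        )

    def selu(self):
        pos = self.data > 0
        out_data = np.where(
            pos, _SELU_SCALE * self.data, _SELU_SCALE * _SELU_ALPHA * np.expm1(self.data)
        ).astype(np.float32)
        def bwd(g, out):
            return (
                g
                * np.where(
                    pos, _SELU_SCALE, out.data + _SELU_SCALE * _SELU_ALPHA
                ).astype(np.float32),
            )
        return Tensor._make(out_data, (self,), bwd)

    # -- backward -----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=np.float32)
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self):
        self.grad = None


# -- fused ops ---------------------------------------------------------------

def concat(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    def bwd(g, out):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    def bwd(g, out):
        sm = np.exp(out.data)
        return (g - sm * g.sum(axis=axis, keepdims=True),)
    return Tensor._make(out_data, (x,), bwd)


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``x[..., idx]`` along the last axis (one index per leading cell)."""
    leading = np.ix_(*[np.arange(s) for s in x.shape[:-1]])
    sel = leading + (idx,)
    def bwd(g, out):
        gx = np.zeros_like(x.data)
        np.add.at(gx, sel, g)
        return (gx,)
    return Tensor._make(x.data[sel], (x,), bwd)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """'valid' 1-d convolution.

    x: (B, L, C_in); weight: (K*C_in, C_out); bias: (C_out,).
    Returns (B, L-K+1, C_out).
    """
    B, L, C = x.data.shape
    KC, F = weight.data.shape
    K = KC // C
    Lout = L - K + 1
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)
    # cols: (B, Lout, C, K) -> (B*Lout, K*C)
    cols2 = cols.transpose(0, 1, 3, 2).reshape(B * Lout, K * C)
    out_data = (cols2 @ weight.data + bias.data).reshape(B, Lout, F)
    def bwd(g, out):
        g2 = g.reshape(B * Lout, F)
        gw = cols2.T @ g2
        gb = g2.sum(axis=0)
        gcols = (g2 @ weight.data.T).reshape(B, Lout, K, C)
        gx = np.zeros_like(x.data)
        for k in range(K):
            gx[:, k : k + Lout, :] += gcols[:, :, k, :]
        return (gx, gw, gb)
    return Tensor._make(out_data, (x, weight, bias), bwd)
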