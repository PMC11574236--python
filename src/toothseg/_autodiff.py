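"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network needs only a small closed set of differentiable
operations (affine maps, gather/scatter over neighbor indices, symmetric
pooling, softmax, layer normalization), so the engine implements exactly
those, in float64, with deterministic CPU semantics.  A module-level
*guided* mode alters the backward rule of the rectifier so that guided
backpropagation (negative upstream gradients suppressed at every
rectification) falls out of the ordinary ``backward`` call.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "linear", "layer_norm", "edge_features",
           "guided_gradients", "is_guided", "default_dtype"]

_GUIDED = False
_DTYPE = np.dtype(np.float64)


@contextlib.contextmanager
def default_dtype(dtype):
    """Context manager: dtype for tensors created inside (float64 is the
    default; float32 trades precision for speed during training)."""
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = prev


@contextlib.contextmanager
def guided_gradients():
    """Context manager: suppress negative gradients at each rectification."""
    global _GUIDED
    prev = _GUIDED
    _GUIDED = True
    try:
        yield
    finally:
        _GUIDED = prev


def is_guided() -> bool:
    return _GUIDED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (topological order)."""
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -----------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def sqrt(self):
        return self.pow(0.5)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient flows to the first argmax (ties)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = Tensor(out_data, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            if not keepdims:
                g = np.expand_dims(g, axis)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- shape manipulation ---------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def slice_cols(self, lo: int, hi: int):
        out = Tensor(self.data[..., lo:hi], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[..., lo:hi] = g
                self._accumulate(full)

        out._backward = bwd
        return out

    def gather_rows(self, index: np.ndarray):
        """Advanced row indexing ``self[index]``; backward scatter-adds."""
        index = np.asarray(index)
        out = Tensor(self.data[index], parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- nonlinearities --------------------------------------------------

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, slope * self.data),
                     parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if _GUIDED:
                # guided backprop: suppress negative upstream gradients at
                # the rectification in addition to the usual local gate
                g = np.maximum(g, 0.0)
            self._accumulate(np.where(pos, g, slope * g))

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - inner))

        out._backward = bwd
        return out

    def cross_entropy(self, labels: np.ndarray):
        """Mean softmax cross-entropy; ``self`` is an M×C logit matrix."""
        labels = np.asarray(labels, dtype=np.intp)
        z = self.data - self.data.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
        logp = z - logsumexp
        m = self.data.shape[0]
        out = Tensor(-logp[np.arange(m), labels].mean(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                probs = np.exp(logp)
                probs[np.arange(m), labels] -= 1.0
                self._accumulate(g * probs / m)

        out._backward = bwd
        return out


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Fused affine map ``x @ weight + bias`` (one graph node)."""
    data = x.data @ weight.data
    data += bias.data
    out = Tensor(data, parents=(x, weight, bias))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g @ weight.data.T)
        if weight.requires_grad:
            weight._accumulate(x.data.T @ g)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=0))

    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Fused per-row normalization over the last axis with affine gain."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(
                (g * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    out._backward = bwd
    return out


def edge_features(x: Tensor, index: np.ndarray, mode: str) -> Tensor:
    """Fused per-edge feature construction over an M×k neighbor index.

    mode 'diff' → x_j − x_i; 'concat_diff' → (x_i ‖ x_j − x_i);
    'concat_raw' → (x_i ‖ x_j).  Returns an (M, k, ·) tensor.
    """
    index = np.asarray(index)
    m, k = index.shape
    d = x.data.shape[1]
    xj = x.data[index]                       # (M, k, d)
    xi = x.data[:, None, :]
    if mode == "diff":
        data = xj - xi
    elif mode == "concat_diff":
        data = np.concatenate([np.broadcast_to(xi, xj.shape), xj - xi],
                              axis=-1)
    elif mode == "concat_raw":
        data = np.concatenate([np.broadcast_to(xi, xj.shape), xj], axis=-1)
    else:  # pragma: no cover - internal
        raise ValueError(mode)
    out = Tensor(data, parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        grad = np.zeros_like(x.data)
        if mode == "diff":
            g_j, g_i = g, -g.sum(axis=1)
        elif mode == "concat_diff":
            g_self, g_diff = g[..., :d], g[..., d:]
            g_j = g_diff
            g_i = g_self.sum(axis=1) - g_diff.sum(axis=1)
        else:
            g_self, g_j = g[..., :d], g[..., d:]
            g_i = g_self.sum(axis=1)
        np.add.at(grad, index, g_j)
        grad += g_i
        x._accumulate(grad)

    out._backward = bwd
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out
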