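"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the spectral regression backbones need:
broadcast arithmetic, matmul, relu/exp/log/softplus, reductions, reshaping,
column slicing, elementwise maximum, valid-mode 1-D convolution and max
pooling. Gradients accumulate into ``Tensor.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "maxpool1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        val = np.exp(np.clip(self.data, -60.0, 60.0))

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * val)

        return self._make(val, (self,), backward)

    def log(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def softplus(self):
        x = self.data
        val = np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30.0))))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * sig)

        return self._make(val, (self,), backward)

    def maximum(self, other):
        other = self._wrap(other)
        take_self = self.data >= other.data

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.data.shape))

        return self._make(np.maximum(self.data, other.data), (self, other), backward)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    # -- autograd ----------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad, t)

    def zero_grad(self) -> None:
        self.grad = None


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-mode 1-D convolution (cross-correlation), stride 1.

    ``x``: (N, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    Output: (N, C_out, L - K + 1).
    """
    K = w.data.shape[2]
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)  # (N,C,Lo,K)
    out_data = np.einsum("nclk,ock->nol", cols, w.data, optimize=True) + b.data[None, :, None]
    out = Tensor(out_data)
    if x.requires_grad or w.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (x, w, b)

        def backward(g, _):
            if w.requires_grad:
                w._accum(np.einsum("nol,nclk->ock", g, cols, optimize=True))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                dcols = np.einsum("nol,ock->nclk", g, w.data, optimize=True)
                dx = np.zeros_like(x.data)
                Lo = g.shape[2]
                for k in range(K):
                    dx[:, :, k : k + Lo] += dcols[:, :, :, k]
                x._accum(dx)

        out._backward = backward
    return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along the last axis (trailing remainder dropped)."""
    N, C, L = x.data.shape
    Lo = L // pool
    view = x.data[:, :, : Lo * pool].reshape(N, C, Lo, pool)
    idx = view.argmax(axis=3)
    out = Tensor(np.take_along_axis(view, idx[..., None], axis=3)[..., 0])
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g, _):
            dview = np.zeros_like(view)
            np.put_along_axis(dview, idx[..., None], g[..., None], axis=3)
            dx = np.zeros_like(x.data)
            dx[:, :, : Lo * pool] = dview.reshape(N, C, Lo * pool)
            x._accum(dx)

        out._backward = backward
    return out
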