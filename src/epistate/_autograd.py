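"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the two-tailed network needs: dense linear
algebra, 1-D convolution/pooling, elementwise nonlinearities, reductions,
concatenation and masked selection.  Gradients are accumulated in float64.

A module-level ``guided`` flag switches ReLU backward to guided
backpropagation (upstream gradients clamped at zero), used only for
saliency extraction, never for training.
"""

from __future__ import annotations

import numpy as np

# When True, ReLU backward zeroes negative upstream gradients (guided backprop).
_GUIDED = False


def set_guided(flag: bool) -> None:
    global _GUIDED
    _GUIDED = bool(flag)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ---- graph traversal -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes) if axes else None

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv) if inv is not None else g.T)

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape).copy(), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))

        out._backward = bwd
        return out

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int):
        """Max-reduce over one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.max(self.data, axis=axis), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                grid = np.indices(out.shape)
                sel = list(grid)
                sel.insert(axis if axis >= 0 else self.ndim + axis, idx)
                full[tuple(sel)] = g
                self._accum(full)

        out._backward = bwd
        return out

    # ---- nonlinearities --------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                if _GUIDED:
                    g = np.maximum(g, 0.0)
                self._accum(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bwd
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = bwd
        return out


def concat(tensors: list, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution (cross-correlation). x: (B,Cin,L), w: (Cout,Cin,K)."""
    K = w.shape[-1]
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)  # B,Cin,Lo,K
    y = np.einsum("bclk,ock->bol", cols, w.data, optimize=True) + b.data[None, :, None]
    out = Tensor(y, _prev=(x, w, b))

    def bwd(g):
        if w.requires_grad:
            w._accum(np.einsum("bclk,bol->ock", cols, g, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gpad = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
            gcols = np.lib.stride_tricks.sliding_window_view(gpad, K, axis=2)
            wflip = w.data[:, :, ::-1]
            x._accum(np.einsum("bolk,ock->bcl", gcols, wflip, optimize=True))

    out._backward = bwd
    return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling over the last axis; trailing remainder dropped."""
    if pool == 1:
        return x
    B, C, L = x.shape
    Lo = L // pool
    xv = x.data[:, :, : Lo * pool].reshape(B, C, Lo, pool)
    idx = np.argmax(xv, axis=3)
    out = Tensor(np.max(xv, axis=3), _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros((B, C, Lo, pool))
            bb, cc, ll = np.indices((B, C, Lo))
            full[bb, cc, ll, idx] = g
            gx = np.zeros_like(x.data)
            gx[:, :, : Lo * pool] = full.reshape(B, C, Lo * pool)
            x._accum(gx)

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: list, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
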