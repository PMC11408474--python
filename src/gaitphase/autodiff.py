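"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's networks (patch transformer, convolutional and recurrent
baselines) are small enough that a compact tape-based engine is sufficient:
every operation records its parents and a closure that accumulates vector-
Jacobian products, and :meth:`Tensor.backward` walks the tape in reverse
topological order.  Shapes broadcast exactly as numpy broadcasts; gradients
of broadcast operands are reduced back to the operand shape.

All floating point work is float64.  The engine is gradient-checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                _unbroadcast(ga, self.data.shape),
                _unbroadcast(gb, other.data.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out_data = self.data.reshape(shape)
        return Tensor._from_op(out_data, (self,), lambda g: (g.reshape(src),))

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)
        return Tensor._from_op(out_data, (self,), lambda g: (np.swapaxes(g, a, b),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)
        return Tensor._from_op(out_data, (self,), lambda g: (np.transpose(g, inv),))

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, self.data.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(
            out_data, (self,), lambda g: (g * out_data * (1 - out_data),)
        )

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        return Tensor._from_op(
            out_data, (self,), lambda g: (g * (self.data > 0),)
        )

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        from scipy.special import erf

        x = self.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * phi

        def backward(g):
            pdf = np.exp(-0.5 * x**2) / math.sqrt(2.0 * math.pi)
            return (g * (phi + x * pdf),)

        return Tensor._from_op(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._from_op(out_data, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize the last axis to zero mean / unit variance, then affine."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out_data = xhat * gamma.data + beta.data
        d = x.shape[-1]

        def backward(g):
            gxhat = g * gamma.data
            gx = inv * (
                gxhat
                - gxhat.mean(axis=-1, keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True)
            )
            ggamma = _unbroadcast(g * xhat, gamma.data.shape)
            gbeta = _unbroadcast(g, beta.data.shape)
            return (gx, ggamma, gbeta)

        return Tensor._from_op(out_data, (self, gamma, beta), backward)

    def dropout(self, p: float, rng: np.random.Generator):
        """Inverted dropout; identity when p == 0."""
        if p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)

    # -- backward pass ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += pgrad


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid (stride-1) 1-D cross-correlation.

    x: (B, C, L), w: (F, C, K), b: (F,) -> (B, F, L-K+1).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    B, C, L = x.data.shape
    F, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError("channel mismatch between input and kernel")
    windows = sliding_window_view(x.data, K, axis=-1)  # (B, C, Lout, K)
    out_data = np.einsum("bclk,fck->bfl", windows, w.data) + b.data[:, None]

    def backward(g):
        gw = np.einsum("bfl,bclk->fck", g, windows)
        gb = g.sum(axis=(0, 2))
        gpad = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
        gwin = sliding_window_view(gpad, K, axis=-1)  # (B, F, L, K)
        gx = np.einsum("bflk,fck->bcl", gwin, w.data[:, :, ::-1])
        return (gx, gw, gb)

    return Tensor._from_op(out_data, (x, w, b), backward)


def avg_pool1d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling on the last axis (truncating)."""
    B, C, L = x.data.shape
    Lout = L // factor
    return x[:, :, : Lout * factor].reshape(B, C, Lout, factor).mean(axis=-1)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


class Adam:
    """Adaptive-moment estimation optimizer over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
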