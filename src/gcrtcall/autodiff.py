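"""Compact reverse-mode automatic differentiation on numpy arrays.

The network layers in this package are built from the differentiable
primitives defined here: a :class:`Tensor` wraps an ``ndarray`` together with
a gradient slot and a closure that propagates upstream gradients to its
parents.  Calling :meth:`Tensor.backward` on a scalar loss walks the recorded
graph in reverse topological order.

Only the primitives the basecaller needs are implemented (broadcast
arithmetic, batched matmul, elementwise transcendentals, reductions, shape
ops, gather/pad/slice, softmax, fused layer-norm and 1-D convolution
kernels).  Gradients follow the standard closed forms; broadcasting is
undone by summing over broadcast axes.

Memory discipline: a backward closure passes each parent a gradient array
with an ``own`` flag — ``True`` when the recipient may adopt (and later
mutate) the buffer because no other live gradient shares it, ``False`` when
the buffer must be copied before accumulation.  Once a tensor's backward has
run its own ``grad`` buffer is dead and may be adopted downstream.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["Tensor", "as_tensor", "concat", "pad", "embedding_lookup",
           "log_softmax", "softmax", "layer_norm", "no_grad",
           "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` down to ``shape``.

    Returns a freshly allocated array iff a reduction happened; the second
    element of the returned tuple says so.
    """
    if grad.shape == shape:
        return grad, False
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad, True


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        if grad.dtype != self.data.dtype:
            grad = grad.astype(self.data.dtype)
            own = True
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, processed = stack.pop()
            if processed:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype), own=True)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- introspection -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            took_raw = False
            if self.requires_grad:
                ga, fresh = _sum_to_shape(g, self.data.shape)
                self._accum(ga, own=True)   # raw child grad is dead: adoptable
                took_raw = not fresh
            if other.requires_grad:
                gb, fresh = _sum_to_shape(g, other.data.shape)
                # only one parent may adopt the raw buffer
                other._accum(gb, own=fresh or not took_raw)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                ga, _ = _sum_to_shape(g * other.data, self.data.shape)
                self._accum(ga, own=True)
            if other.requires_grad:
                gb, _ = _sum_to_shape(g * self.data, other.data.shape)
                other._accum(gb, own=True)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other._reciprocal()

    def __rtruediv__(self, other):
        return as_tensor(other) * self._reciprocal()

    def _reciprocal(self):
        out_data = 1.0 / self.data

        def backward(g):
            if self.requires_grad:
                ga, _ = _sum_to_shape(-g * out_data * out_data, self.data.shape)
                self._accum(ga, own=True)

        return Tensor._make(out_data, (self,), backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1), own=True)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga, _ = _sum_to_shape(g @ np.swapaxes(other.data, -1, -2),
                                      self.data.shape)
                self._accum(ga, own=True)
            if other.requires_grad:
                gb, _ = _sum_to_shape(np.swapaxes(self.data, -1, -2) @ g,
                                      other.data.shape)
                other._accum(gb, own=True)

        return Tensor._make(out_data, (self, other), backward)

    # -- transcendentals ---------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (out_data * (1.0 - out_data)), own=True)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data * out_data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def swish(self):
        """x * sigmoid(x) — the activation used throughout the network."""
        s = _sigmoid(self.data)
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + out_data * (1.0 - s)), own=True)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy(), own=True)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                # view of the (dead) child grad: sole recipient, adoptable
                self._accum(np.ascontiguousarray(g).reshape(orig), own=True)

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv), own=True)

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        advanced = any(isinstance(i, np.ndarray) for i in
                       (idx if isinstance(idx, tuple) else (idx,)))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if advanced:  # repeated indices must accumulate
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accum(full, own=True)

        return Tensor._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        # disjoint views of the dead child grad: each adoptable
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece, own=True)

    return Tensor._make(out_data, tuple(tensors), backward)


def pad(t: Tensor, pad_width) -> Tensor:
    """Zero-pad; ``pad_width`` as for :func:`numpy.pad`."""
    t = as_tensor(t)
    out_data = np.pad(t.data, pad_width)
    slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, t.data.shape))

    def backward(g):
        if t.requires_grad:
            t._accum(g[slices], own=True)

    return Tensor._make(out_data, (t,), backward)


def embedding_lookup(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``weight[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx)
    out_data = weight.data[idx]

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, idx, g)
            weight._accum(full, own=True)

    return Tensor._make(out_data, (weight,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    x = t.data
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if t.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            t._accum(out_data * (g - dot), own=True)

    return Tensor._make(out_data, (t,), backward)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    x = t.data
    m = x.max(axis=axis, keepdims=True)
    s = x - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    out_data = s - lse

    def backward(g):
        if t.requires_grad:
            t._accum(g - np.exp(out_data) * g.sum(axis=axis, keepdims=True),
                     own=True)

    return Tensor._make(out_data, (t,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    d = x.data
    mu = d.mean(axis=-1, keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accum((g * xhat).sum(axis=axes), own=True)
        if beta.requires_grad:
            axes = tuple(range(g.ndim - 1))
            beta._accum(g.sum(axis=axes), own=True)
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            x._accum((gy - m1 - xhat * m2) * inv, own=True)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def conv1d(x: Tensor, weight: Tensor, stride: int = 1) -> Tensor:
    """Fused 1-D convolution core on an already-padded input.

    ``x``: (B, L, C_in); ``weight``: (kernel, C_in, C_out); output frame t
    is ``sum_tap x[:, t*stride + tap, :] @ weight[tap]``.
    """
    B, L, C = x.shape
    k, _, C_out = weight.shape
    L_out = (L - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)
    win = win[:, ::stride]                         # (B, L_out, C, k)
    cols = win.transpose(0, 1, 3, 2).reshape(B, L_out, k * C)
    w2 = weight.data.reshape(k * C, C_out)
    out_data = cols @ w2

    def backward(g):
        if weight.requires_grad:
            gw = cols.reshape(-1, k * C).T @ g.reshape(-1, C_out)
            weight._accum(gw.reshape(k, C, C_out), own=True)
        if x.requires_grad:
            dcols = (g @ w2.T).reshape(B, L_out, k, C)
            dx = np.zeros_like(x.data)
            for tap in range(k):
                end = tap + (L_out - 1) * stride + 1
                dx[:, tap:end:stride, :] += dcols[:, :, tap, :]
            x._accum(dx, own=True)

    return Tensor._make(out_data, (x, weight), backward)


def depthwise_conv1d(x: Tensor, weight: Tensor) -> Tensor:
    """Fused depthwise 1-D convolution core on an already-padded input.

    ``x``: (B, L, C); ``weight``: (kernel, C); one filter per channel.
    """
    B, L, C = x.shape
    k, _ = weight.shape
    L_out = L - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)
    out_data = np.einsum("blck,kc->blc", win, weight.data, optimize=True)

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("blck,blc->kc", win, g, optimize=True)
            weight._accum(gw, own=True)
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for tap in range(k):
                dx[:, tap:tap + L_out, :] += g * weight.data[tap]
            x._accum(dx, own=True)

    return Tensor._make(out_data, (x, weight), backward)
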