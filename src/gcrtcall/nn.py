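"""Neural-network layers on the autodiff engine.

Conventions: activations are channel-last, ``(batch, time, channels)``.
Convolutions use "same" padding so the output length is
``floor((L - 1) / stride) + 1``, which keeps the frontend's 10x
downsampling arithmetic exact.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, depthwise_conv1d, is_grad_enabled, \
    layer_norm, pad

__all__ = ["Module", "Parameter", "Linear", "Conv1d", "DepthwiseConv1d",
           "LayerNorm", "BatchNorm1d", "Dropout", "Embedding",
           "sinusoidal_encoding"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for prefix, mod in self._named_modules():
            for name, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    yield (f"{prefix}{name}", v)

    def _named_modules(self, prefix=""):
        yield prefix, self
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for prefix, mod in self._named_modules():
            for name, v in getattr(mod, "_buffers", {}).items():
                state[f"{prefix}{name}"] = v.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        buffers = {}
        for prefix, mod in self._named_modules():
            for name in getattr(mod, "_buffers", {}):
                buffers[f"{prefix}{name}"] = (mod, name)
        for key, value in state.items():
            if key in own:
                if own[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                own[key].data = value.astype(own[key].data.dtype).copy()
            elif key in buffers:
                mod, name = buffers[key]
                mod._buffers[name] = value.copy()
            else:
                raise KeyError(f"unexpected key {key!r} in state dict")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True, *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, n_in, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def same_pad_amount(L: int, kernel: int, stride: int) -> tuple[int, int]:
    L_out = (L - 1) // stride + 1
    total = max((L_out - 1) * stride + kernel - L, 0)
    return total // 2, total - total // 2


class Conv1d(Module):
    """1-D convolution over (B, T, C_in) with same padding.

    Implemented as a sum of strided slices times per-tap weight matrices, so
    the gradient comes for free from the autodiff primitives.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 bias: bool = True, *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel, self.stride = kernel, stride
        self.weight = Parameter(_kaiming(rng, c_in * kernel, (kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        lo, hi = same_pad_amount(L, self.kernel, self.stride)
        xp = pad(x, ((0, 0), (lo, hi), (0, 0)))
        out = conv1d(xp, self.weight, self.stride)
        if self.bias is not None:
            out = out + self.bias
        return out


class DepthwiseConv1d(Module):
    """Per-channel 1-D convolution (one filter per channel), same padding."""

    def __init__(self, channels: int, kernel: int, bias: bool = True, *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.weight = Parameter(_kaiming(rng, kernel, (kernel, channels)))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        lo, hi = same_pad_amount(L, self.kernel, 1)
        xp = pad(x, ((0, 0), (lo, hi), (0, 0)))
        out = depthwise_conv1d(xp, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class BatchNorm1d(Module):
    """Batch normalization over (B, T) per channel; running stats at eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel())
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel())
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            xhat = (x - mu) * Tensor((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, *, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0 or not is_grad_enabled():
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0, 0.02, (n_tokens, dim)).astype(np.float32))

    def forward(self, idx: np.ndarray) -> Tensor:
        from .autodiff import embedding_lookup
        return embedding_lookup(self.weight, np.asarray(idx))


def sinusoidal_encoding(positions: np.ndarray, dim: int) -> np.ndarray:
    """Standard sin/cos encoding; accepts negative (relative) positions."""
    positions = np.asarray(positions, dtype=np.float64)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / half)
    ang = positions[:, None] * freqs[None, :]
    enc = np.zeros((len(positions), dim), dtype=np.float32)
    enc[:, 0::2] = np.sin(ang)
    enc[:, 1::2] = np.cos(ang)
    return enc
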