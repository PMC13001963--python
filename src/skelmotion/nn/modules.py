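"""Neural building blocks on top of the autograd engine.

Initialisation is explicit: every module takes a `numpy.random.Generator`
so whole networks are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "FeedForward",
    "Conv1d",
    "MultiheadAttention",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)
        elif isinstance(value, dict):
            for v in value.values():
                Module._collect_value(v, params, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        self._state("", out)
        return out

    def _state(self, prefix: str, out: dict) -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value.data.copy()
            elif isinstance(value, Module):
                value._state(key + ".", out)
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._state(f"{key}.{i}.", out)
                    elif isinstance(v, Parameter):
                        out[f"{key}.{i}"] = v.data.copy()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        current = {}
        self._state_refs("", current)
        missing = set(state) ^ set(current)
        if missing:
            raise KeyError(f"state dict key mismatch: {sorted(missing)[:5]}")
        for key, param in current.items():
            if param.data.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            param.data[...] = state[key]

    def _state_refs(self, prefix: str, out: dict) -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                value._state_refs(key + ".", out)
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._state_refs(f"{key}.{i}.", out)
                    elif isinstance(v, Parameter):
                        out[f"{key}.{i}"] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_dim, out_dim))
        else:
            w = _glorot(rng, in_dim, out_dim, (in_dim, out_dim))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 1:  # promote vectors so matmul gradients stay 2-D
            return (x.reshape(1, -1) @ self.weight + self.bias).reshape(-1)
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


class FeedForward(Module):
    """Two-layer MLP with ReLU; `zero_init` zeroes the output projection so
    the surrounding residual block starts as the identity."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 out_dim: int | None = None, zero_init: bool = False,
                 activation: str = "relu"):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim if out_dim is not None else dim, rng, zero_init=zero_init)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        h = h.tanh() if self.activation == "tanh" else h.relu()
        return self.fc2(h)


class Conv1d(Module):
    """Temporal convolution with same padding over (..., T, C) inputs."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel must be odd and positive")
        self.kernel = kernel
        fan = in_ch * kernel
        self.weight = Parameter(_glorot(rng, fan, out_ch, (kernel, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        t_axis = x.ndim - 2
        length = x.shape[t_axis]
        if self.kernel > length:
            raise ValueError(f"kernel {self.kernel} longer than sequence {length}")
        half = self.kernel // 2
        padded = x.pad_axis(t_axis, half, half)
        out = None
        sl = [slice(None)] * x.ndim
        for tap in range(self.kernel):
            sl[t_axis] = slice(tap, tap + length)
            term = padded[tuple(sl)] @ self.weight[tap]
            out = term if out is None else out + term
        return out + self.bias


class MultiheadAttention(Module):
    """Scaled dot-product attention; self-attention when kv is None.

    `zero_init` zeroes the output projection so a residual wrapper starts
    as the identity.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, zero_init: bool = False):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng, zero_init=zero_init)

    def forward(self, x: Tensor, kv: Tensor | None = None) -> Tensor:
        if kv is None:
            kv = x
        if x.shape[-1] != kv.shape[-1]:
            raise ValueError("query/key feature dims differ")
        q, k, v = self.wq(x), self.wk(kv), self.wv(kv)
        dh = self.dim // self.heads
        scores_scale = 1.0 / np.sqrt(dh)

        def split(t: Tensor) -> Tensor:
            # (..., T, dim) -> (..., heads, T, dh)
            new_shape = t.shape[:-1] + (self.heads, dh)
            t = t.reshape(new_shape)
            return t.swapaxes(-2, -3)

        qh, kh, vh = split(q), split(k), split(v)
        attn = (qh @ kh.swapaxes(-1, -2) * scores_scale).softmax(axis=-1)
        ctx = attn @ vh
        ctx = ctx.swapaxes(-2, -3)
        ctx = ctx.reshape(ctx.shape[:-2] + (self.dim,))
        return self.wo(ctx)
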