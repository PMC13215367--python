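"""Neural-network building blocks on top of the autodiff core.

Provides 3D convolution (via im2col), instance normalisation, linear layers,
layer norm, multi-head self-attention and transformer blocks — the pieces a
hybrid CNN-encoder / ViT-bottleneck / CNN-decoder segmentation model needs.
Weight initialisation is driven by an explicit ``numpy.random.Generator`` so
that model construction is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, conv3d

DTYPE = np.float32   # network weights/activations; losses may run in float64


class Module:
    """Base class: parameter collection by attribute introspection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad is not None and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
        collect(self)
        return params

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape).astype(DTYPE),
                  requires_grad=True)


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution, optional stride, 'same'-style padding."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3,
                 stride: int = 1, padding: int | None = None):
        self.k, self.stride = k, stride
        self.padding = (k // 2) if padding is None else padding
        fan_in = c_in * k ** 3
        self.weight = _param(rng, (c_out, c_in, k, k, k),
                             np.sqrt(2.0 / fan_in))
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class InstanceNorm3d(Module):
    """Per-channel, per-sample normalisation over spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=DTYPE),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=DTYPE),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        centred = x - mu
        var = (centred ** 2).mean(axis=(2, 3, 4), keepdims=True)
        return centred * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class ConvBlock(Module):
    """conv -> instance norm -> leaky ReLU (slope 0.01, nnU-Net style)."""

    def __init__(self, rng, c_in: int, c_out: int, stride: int = 1):
        self.conv = Conv3d(rng, c_in, c_out, stride=stride)
        self.norm = InstanceNorm3d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).leaky_relu(0.01)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        self.weight = _param(rng, (d_in, d_out), np.sqrt(1.0 / d_in))
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred ** 2).mean(axis=-1, keepdims=True)
        return centred * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadAttention(Module):
    def __init__(self, rng, dim: int, heads: int):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.dh = dim // heads
        self.q = Linear(rng, dim, dim)
        self.k = Linear(rng, dim, dim)
        self.v = Linear(rng, dim, dim)
        self.out = Linear(rng, dim, dim)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, dim = x.shape

        def split(t: Tensor) -> Tensor:                  # B L d -> B h L dh
            return t.reshape(B, L, self.heads, self.dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, dim)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm transformer block: LN->MHA->residual, LN->MLP->residual."""

    def __init__(self, rng, dim: int, heads: int, mlp_ratio: int = 2):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(rng, dim, heads)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(rng, dim, mlp_ratio * dim)
        self.fc2 = Linear(rng, mlp_ratio * dim, dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    return concatenate([a, b], axis=1)
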