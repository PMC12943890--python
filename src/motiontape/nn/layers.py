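"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, softmax, stack

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "MLP",
    "Conv1d",
    "LSTM",
    "LayerNorm",
    "TransformerEncoderLayer",
    "sinusoidal_positions",
]


class Module:
    """Lightweight parameter container with flat state-dict support."""

    def parameters(self) -> Iterator[Tensor]:
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(state):
            raise ValueError(
                f"state dict has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    scale = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = _glorot(rng, in_dim, out_dim, (in_dim, out_dim))
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    # unit-scale init: condition embeddings must be separable against the
    # unit-Gaussian latent noise they are summed with
    def __init__(self, n_items: int, dim: int, rng: np.random.Generator, scale: float = 1.0):
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_items, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class MLP(Module):
    """Stack of linear layers with tanh activations between them."""

    def __init__(self, dims: list[int], rng: np.random.Generator, final_activation: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = x.tanh()
        return x


class Conv1d(Module):
    """1-D convolution over (batch, channels, time); no padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int,
        rng: np.random.Generator,
    ):
        fan_in = in_channels * kernel_size
        self.weight = _glorot(
            rng, fan_in, out_channels, (kernel_size, in_channels, out_channels)
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.kernel_size = kernel_size
        self.stride = stride

    def out_length(self, t: int) -> int:
        return (t - self.kernel_size) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        t = x.shape[-1]
        length = self.out_length(t)
        if length < 1:
            raise ValueError(f"input length {t} shorter than kernel {self.kernel_size}")
        out = None
        for k in range(self.kernel_size):
            xk = x[:, :, k : k + (length - 1) * self.stride + 1 : self.stride]
            term = xk.transpose(0, 2, 1) @ self.weight[k]  # (B, L, Cout)
            out = term if out is None else out + term
        return (out + self.bias).transpose(0, 2, 1)


class LSTM(Module):
    """Multi-layer LSTM over (batch, time, features); returns full sequence."""

    def __init__(self, in_dim: int, hidden_dim: int, n_layers: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.w_ih: list[Tensor] = []
        self.w_hh: list[Tensor] = []
        self.bias_l: list[Tensor] = []
        for layer in range(n_layers):
            d = in_dim if layer == 0 else hidden_dim
            self.w_ih.append(_glorot(rng, d, 4 * hidden_dim, (d, 4 * hidden_dim)))
            self.w_hh.append(
                _glorot(rng, hidden_dim, 4 * hidden_dim, (hidden_dim, 4 * hidden_dim))
            )
            b = np.zeros(4 * hidden_dim)
            b[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias
            self.bias_l.append(Tensor(b, requires_grad=True))

    def parameters(self) -> Iterator[Tensor]:
        yield from self.w_ih
        yield from self.w_hh
        yield from self.bias_l

    def __call__(self, x: Tensor) -> Tensor:
        batch, t, _ = x.shape
        h_dim = self.hidden_dim
        seq = x
        for w_ih, w_hh, bias in zip(self.w_ih, self.w_hh, self.bias_l):
            h = Tensor(np.zeros((batch, h_dim)))
            c = Tensor(np.zeros((batch, h_dim)))
            outs = []
            for step in range(t):
                gates = seq[:, step, :] @ w_ih + h @ w_hh + bias
                i_g = gates[:, :h_dim].sigmoid()
                f_g = gates[:, h_dim : 2 * h_dim].sigmoid()
                g_g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
                o_g = gates[:, 3 * h_dim :].sigmoid()
                c = f_g * c + i_g * g_g
                h = o_g * c.tanh()
                outs.append(h)
            seq = stack(outs, axis=1)
        return seq


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class TransformerEncoderLayer(Module):
    """Single-head self-attention encoder block (pre-norm residual)."""

    def __init__(self, dim: int, ff_dim: int, rng: np.random.Generator):
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.scale = 1.0 / math.sqrt(dim)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        q, k, v = self.wq(h), self.wk(h), self.wv(h)
        scores = q @ k.transpose(0, 2, 1) * self.scale
        attn = softmax(scores, axis=-1)
        x = x + self.wo(attn @ v)
        h = self.norm2(x)
        return x + self.ff2(self.ff1(h).relu())


def sinusoidal_positions(t: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding of shape (t, dim)."""
    pos = np.arange(t)[:, None].astype(np.float64)
    half = (dim + 1) // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    angles = pos * freqs[None, :]
    enc = np.zeros((t, dim))
    enc[:, 0::2] = np.sin(angles)[:, : enc[:, 0::2].shape[1]]
    enc[:, 1::2] = np.cos(angles)[:, : enc[:, 1::2].shape[1]]
    return enc
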