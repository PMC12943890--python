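"""Denoising-diffusion generators (DDPM-style, epsilon prediction).

The denoiser is a residual MLP of the configured width/depth; the timestep
embedding and the condition embedding (class label or encoded strain series)
are summed into its hidden state.  Sampling runs the full ancestral loop
over ``sampling_steps`` steps.
"""

from __future__ import annotations

import numpy as np

from ..nn import Adam, Embedding, Linear, Module, Tensor, sinusoidal_positions
from .base import DiffusionConfig, GeneratorModel
from .cvae import ConditionEncoder, _epoch_batches

__all__ = [
    "train_class_diffusion",
    "sample_class_diffusion",
    "train_translator_diffusion",
    "translate_diffusion",
    "build_diffusion_net",
]


def noise_schedule(config: DiffusionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (betas, alpha_bars) for the configured schedule."""
    n = config.sampling_steps
    if config.noise_schedule == "cosine":
        s = 0.008
        steps = np.arange(n + 1) / n
        f = np.cos((steps + s) / (1 + s) * np.pi / 2) ** 2
        alpha_bar = f / f[0]
        betas = np.clip(1.0 - alpha_bar[1:] / alpha_bar[:-1], 1e-8, 0.999)
    else:
        betas = np.linspace(1e-4, 0.02, n)
    alpha_bar = np.cumprod(1.0 - betas)
    return betas, alpha_bar


class DenoiserNet(Module):
    """Residual MLP epsilon-predictor with summed time/condition embeddings."""

    def __init__(
        self,
        data_dim: int,
        n_classes: int,
        n_channels: int,
        config: DiffusionConfig,
        rng,
        condition_mode: str,
    ):
        h = config.hidden_dim
        self.condition_mode = condition_mode
        self.inp = Linear(data_dim, h, rng)
        self.time_proj = Linear(h, h, rng)
        self.hidden = [Linear(h, h, rng) for _ in range(config.decoder_layers)]
        self.out = Linear(h, data_dim, rng)
        if condition_mode == "class_label":
            self.label_emb = Embedding(n_classes, h, rng)
            self.cond_encoder = None
        else:
            self.label_emb = None
            self.cond_encoder = ConditionEncoder(n_channels, h, h, rng)
        self.time_table = sinusoidal_positions(config.sampling_steps, h)

    def condition_embedding(self, labels=None, strain: Tensor | None = None) -> Tensor:
        if self.condition_mode == "class_label":
            return self.label_emb(labels)
        return self.cond_encoder(strain)

    def __call__(self, x: Tensor, t_idx: np.ndarray, cond: Tensor) -> Tensor:
        t_emb = Tensor(self.time_table[np.asarray(t_idx, dtype=np.intp)])
        h = self.inp(x).tanh() + self.time_proj(t_emb) + cond
        for layer in self.hidden:
            h = h + layer(h).tanh()
        return self.out(h)


def build_diffusion_net(
    condition_mode: str,
    data_dim: int,
    n_classes: int,
    n_steps: int,
    n_channels: int,
    config: DiffusionConfig,
    rng,
) -> DenoiserNet:
    return DenoiserNet(data_dim, n_classes, n_channels, config, rng, condition_mode)


def _train_diffusion(
    target_flat: np.ndarray,
    cond_fn,
    data_dim: int,
    net: DenoiserNet,
    config: DiffusionConfig,
    rng: np.random.Generator,
) -> list[float]:
    _, alpha_bar = noise_schedule(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    n = target_flat.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for idx in _epoch_batches(n, config.batch_size, rng):
            x0 = target_flat[idx]
            t_idx = rng.integers(0, config.sampling_steps, size=len(idx))
            eps = rng.standard_normal(x0.shape)
            ab = alpha_bar[t_idx][:, None]
            xt = Tensor(np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps)
            pred = net(xt, t_idx, cond_fn(idx))
            loss = ((pred - Tensor(eps)) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return history


def _sample_loop(
    net: DenoiserNet,
    cond: Tensor,
    n: int,
    data_dim: int,
    config: DiffusionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    betas, alpha_bar = noise_schedule(config)
    alphas = 1.0 - betas
    x = rng.standard_normal((n, data_dim))
    for t in range(config.sampling_steps - 1, -1, -1):
        pred = net(Tensor(x), np.full(n, t), cond).data
        ab = alpha_bar[t]
        x0_hat = np.clip((x - np.sqrt(1.0 - ab) * pred) / np.sqrt(ab), -1.0, 1.0)
        if t > 0:
            ab_prev = alpha_bar[t - 1]
            coef0 = np.sqrt(ab_prev) * betas[t] / (1.0 - ab)
            coeft = np.sqrt(alphas[t]) * (1.0 - ab_prev) / (1.0 - ab)
            mean = coef0 * x0_hat + coeft * x
            var = betas[t] * (1.0 - ab_prev) / (1.0 - ab)
            x = mean + np.sqrt(var) * rng.standard_normal(x.shape)
        else:
            x = x0_hat
    return np.clip(x, -1.0, 1.0)


def train_class_diffusion(
    x: np.ndarray, y: np.ndarray, labels: tuple[str, ...], n_steps: int, config: DiffusionConfig
) -> GeneratorModel:
    n, n_channels, _ = x.shape
    data_dim = n_channels * n_steps
    flat = x.reshape(n, data_dim)
    rng = np.random.default_rng(config.seed)
    net = build_diffusion_net("class_label", data_dim, len(labels), n_steps, n_channels, config, rng)
    history = _train_diffusion(flat, lambda idx: net.label_emb(y[idx]), data_dim, net, config, rng)
    return GeneratorModel(
        kind="diffusion",
        condition_mode="class_label",
        config=config,
        net=net,
        labels=labels,
        n_steps=n_steps,
        n_channels=n_channels,
        seed=config.seed,
        loss_history=history,
    )


def sample_class_diffusion(model: GeneratorModel, label_idx: int, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    net: DenoiserNet = model.net
    data_dim = model.n_channels * model.n_steps
    cond = net.label_emb(np.full(n, label_idx))
    out = _sample_loop(net, cond, n, data_dim, model.config, rng)
    return out.reshape(n, model.n_channels, model.n_steps)


def train_translator_diffusion(
    strain: np.ndarray, kin: np.ndarray, n_steps: int, config: DiffusionConfig
) -> GeneratorModel:
    n, n_channels, _ = strain.shape
    data_dim = n_channels * n_steps
    kin_flat = kin.reshape(n, data_dim)
    strain_btc = strain.transpose(0, 2, 1)
    rng = np.random.default_rng(config.seed)
    net = build_diffusion_net("mt_series", data_dim, 0, n_steps, n_channels, config, rng)
    history = _train_diffusion(
        kin_flat,
        lambda idx: net.cond_encoder(Tensor(strain_btc[idx])),
        data_dim,
        net,
        config,
        rng,
    )
    return GeneratorModel(
        kind="diffusion",
        condition_mode="mt_series",
        config=config,
        net=net,
        labels=(),
        n_steps=n_steps,
        n_channels=n_channels,
        seed=config.seed,
        loss_history=history,
    )


def translate_diffusion(model: GeneratorModel, strain: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    net: DenoiserNet = model.net
    data_dim = model.n_channels * model.n_steps
    cond = net.cond_encoder(Tensor(strain.T[None, :, :]))
    out = _sample_loop(net, cond, 1, data_dim, model.config, rng)
    return out.reshape(model.n_channels, model.n_steps)
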