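"""Conditional variational autoencoder generators.

Class-conditional variant: learned label embeddings are summed into the
encoder input and into the latent before decoding.  Series-conditional
variant (the kinematics translator): the conditioning strain series passes
through one self-attention encoder layer plus a linear projection, and the
resulting embedding is summed with the (reparameterized) kinematics latent.
"""

from __future__ import annotations

import numpy as np

from ..nn import (
    MLP,
    Adam,
    Embedding,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    sinusoidal_positions,
)
from .base import CVAEConfig, GeneratorModel

__all__ = [
    "train_class_cvae",
    "sample_class_cvae",
    "train_translator_cvae",
    "translate_cvae",
    "build_cvae_net",
]


class ConditionEncoder(Module):
    """Self-attention encoder + projection mapping a strain series to an
    embedding in the generator's latent space."""

    def __init__(self, in_channels: int, d_model: int, out_dim: int, rng):
        self.proj_in = Linear(in_channels, d_model, rng)
        self.block = TransformerEncoderLayer(d_model, 2 * d_model, rng)
        self.proj_out = Linear(d_model, out_dim, rng)
        self.d_model = d_model

    def __call__(self, strain: Tensor) -> Tensor:
        # strain: (B, T, C)
        t = strain.shape[1]
        h = self.proj_in(strain) + Tensor(sinusoidal_positions(t, self.d_model))
        h = self.block(h)
        return self.proj_out(h.mean(axis=1))


class CVAENet(Module):
    """Encoder/decoder MLPs with either label or series conditioning."""

    def __init__(
        self,
        data_dim: int,
        n_classes: int,
        n_steps: int,
        n_channels: int,
        config: CVAEConfig,
        rng,
        condition_mode: str,
    ):
        h, z, d = config.hidden_dim, config.latent_dim, config.decoder_layers
        self.condition_mode = condition_mode
        self.encoder = MLP([data_dim] + [h] * max(d - 1, 1), rng, final_activation=True)
        self.mu_head = Linear(h, z, rng)
        self.logvar_head = Linear(h, z, rng)
        self.decoder = MLP([z] + [h] * max(d - 1, 1) + [data_dim], rng)
        if condition_mode == "class_label":
            self.label_in = Embedding(n_classes, data_dim, rng)
            self.label_latent = Embedding(n_classes, z, rng)
            self.cond_encoder = None
        else:
            self.label_in = None
            self.label_latent = None
            self.cond_encoder = ConditionEncoder(n_channels, h, z, rng)

    # -- condition embeddings -----------------------------------------
    def latent_condition(self, labels=None, strain: Tensor | None = None) -> Tensor:
        if self.condition_mode == "class_label":
            return self.label_latent(labels)
        return self.cond_encoder(strain)

    def encode(self, x: Tensor, labels=None) -> tuple[Tensor, Tensor]:
        if self.condition_mode == "class_label":
            x = x + self.label_in(labels)
        h = self.encoder(x)
        return self.mu_head(h), self.logvar_head(h)

    def decode(self, z: Tensor) -> Tensor:
        return self.decoder(z).tanh()


def build_cvae_net(
    condition_mode: str,
    data_dim: int,
    n_classes: int,
    n_steps: int,
    n_channels: int,
    config: CVAEConfig,
    rng,
) -> CVAENet:
    return CVAENet(data_dim, n_classes, n_steps, n_channels, config, rng, condition_mode)


def _kl_term(mu: Tensor, logvar: Tensor) -> Tensor:
    return ((mu**2.0 + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_class_cvae(
    x: np.ndarray, y: np.ndarray, labels: tuple[str, ...], n_steps: int, config: CVAEConfig
) -> GeneratorModel:
    n, n_channels, _ = x.shape
    data_dim = n_channels * n_steps
    flat = x.reshape(n, data_dim)
    rng = np.random.default_rng(config.seed)
    net = build_cvae_net("class_label", data_dim, len(labels), n_steps, n_channels, config, rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _epoch_batches(n, config.batch_size, rng):
            xb = Tensor(flat[idx])
            yb = y[idx]
            mu, logvar = net.encode(xb, yb)
            eps = Tensor(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps + net.label_latent(yb)
            recon = net.decode(z)
            loss = ((recon - xb) ** 2.0).sum(axis=1).mean() + config.kl_weight * _kl_term(
                mu, logvar
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return GeneratorModel(
        kind="cvae",
        condition_mode="class_label",
        config=config,
        net=net,
        labels=labels,
        n_steps=n_steps,
        n_channels=n_channels,
        seed=config.seed,
        loss_history=history,
    )


def sample_class_cvae(model: GeneratorModel, label_idx: int, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    net: CVAENet = model.net
    z = Tensor(rng.standard_normal((n, model.config.latent_dim)))
    z = z + net.label_latent(np.full(n, label_idx))
    out = net.decode(z).data
    return out.reshape(n, model.n_channels, model.n_steps)


def train_translator_cvae(
    strain: np.ndarray, kin: np.ndarray, n_steps: int, config: CVAEConfig
) -> GeneratorModel:
    n, n_channels, _ = strain.shape
    data_dim = n_channels * n_steps
    kin_flat = kin.reshape(n, data_dim)
    strain_btc = strain.transpose(0, 2, 1)  # (N, T, C)
    rng = np.random.default_rng(config.seed)
    net = build_cvae_net("mt_series", data_dim, 0, n_steps, n_channels, config, rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _epoch_batches(n, config.batch_size, rng):
            kb = Tensor(kin_flat[idx])
            sb = Tensor(strain_btc[idx])
            mu, logvar = net.encode(kb)
            eps = Tensor(rng.standard_normal(mu.shape))
            c = net.cond_encoder(sb)
            z = mu + (logvar * 0.5).exp() * eps + c
            recon = net.decode(z)
            loss = ((recon - kb) ** 2.0).sum(axis=1).mean() + config.kl_weight * _kl_term(
                mu, logvar
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return GeneratorModel(
        kind="cvae",
        condition_mode="mt_series",
        config=config,
        net=net,
        labels=(),
        n_steps=n_steps,
        n_channels=n_channels,
        seed=config.seed,
        loss_history=history,
    )


def translate_cvae(model: GeneratorModel, strain: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    net: CVAENet = model.net
    c = net.cond_encoder(Tensor(strain.T[None, :, :]))
    z = Tensor(rng.standard_normal((1, model.config.latent_dim))) + c
    out = net.decode(z).data
    return out.reshape(model.n_channels, model.n_steps)
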