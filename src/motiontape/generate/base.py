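"""Shared types and public API for the conditional generative models.

Two condition modes exist:

* ``class_label`` — generate synthetic strain trials for a movement class
  (data augmentation);
* ``mt_series`` — generate kinematics trajectories conditioned on a full
  strain series (feature augmentation / translation).

Hyperparameters are shared between the two modes of a given model kind.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..preprocess import ProcessedTrial
from ..simdata import MOVEMENTS

__all__ = [
    "CVAEConfig",
    "DiffusionConfig",
    "ConditionSpec",
    "GeneratorModel",
    "train_class_conditional",
    "sample_synthetic_mt",
    "train_kinematics_translator",
    "translate_kinematics",
    "load_generator",
]


@dataclass(frozen=True)
class CVAEConfig:
    decoder_layers: int = 4
    hidden_dim: int = 12
    latent_dim: int = 12
    epochs: int = 500
    learning_rate: float = 1e-3
    kl_weight: float = 1.0
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if min(self.decoder_layers, self.hidden_dim, self.latent_dim, self.epochs) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass(frozen=True)
class DiffusionConfig:
    sampling_steps: int = 500
    hidden_dim: int = 64
    decoder_layers: int = 12
    noise_schedule: str = "cosine"
    epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.sampling_steps < 1:
            raise ValueError("sampling_steps must be >= 1")
        if self.noise_schedule not in ("cosine", "linear"):
            raise ValueError(f"unknown noise schedule: {self.noise_schedule!r}")


@dataclass(frozen=True)
class ConditionSpec:
    """Exactly one of a class label or a conditioning strain series."""

    mode: str  # "class_label" | "mt_series"
    class_label: str | None = None
    mt_series: np.ndarray | None = None

    def __post_init__(self):
        if self.mode == "class_label":
            if self.class_label is None or self.mt_series is not None:
                raise ValueError("class_label mode takes a label and no series")
        elif self.mode == "mt_series":
            if self.mt_series is None or self.class_label is not None:
                raise ValueError("mt_series mode takes a series and no label")
        else:
            raise ValueError(f"unknown condition mode: {self.mode!r}")


@dataclass
class GeneratorModel:
    """A trained conditional generator plus everything needed to re-run it."""

    kind: str  # "cvae" | "diffusion"
    condition_mode: str  # "class_label" | "mt_series"
    config: CVAEConfig | DiffusionConfig
    net: object
    labels: tuple[str, ...]
    n_steps: int
    n_channels: int = 6
    seed: int = 0
    loss_history: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.net.state_dict())
        manifest = {
            "kind": self.kind,
            "condition_mode": self.condition_mode,
            "config": dataclasses.asdict(self.config),
            "labels": list(self.labels),
            "n_steps": self.n_steps,
            "n_channels": self.n_channels,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def _check_dataset(dataset: list[ProcessedTrial], need_classes: bool) -> tuple[tuple[str, ...], int]:
    if not dataset:
        raise ValueError("empty training dataset")
    steps = {t.n_steps for t in dataset}
    if len(steps) != 1:
        raise ValueError(f"inconsistent trial lengths: {sorted(steps)}")
    present = {t.movement for t in dataset}
    labels = tuple(m for m in MOVEMENTS if m in present) or tuple(sorted(present))
    if need_classes and len(labels) < 2:
        raise ValueError("need at least 2 movement classes for class conditioning")
    return labels, steps.pop()


def train_class_conditional(
    kind: str,
    dataset: list[ProcessedTrial],
    config: CVAEConfig | DiffusionConfig | None = None,
) -> GeneratorModel:
    """Train a movement-class-conditioned strain generator."""
    labels, n_steps = _check_dataset(dataset, need_classes=True)
    x = np.stack([t.strain for t in dataset])  # (N, 6, T)
    y = np.array([labels.index(t.movement) for t in dataset])
    if kind == "cvae":
        from .cvae import train_class_cvae

        return train_class_cvae(x, y, labels, n_steps, config or CVAEConfig())
    if kind == "diffusion":
        from .diffusion import train_class_diffusion

        return train_class_diffusion(x, y, labels, n_steps, config or DiffusionConfig())
    if kind == "timegan":
        from .timegan import TimeGAN

        raise NotImplementedError(TimeGAN.EXCLUDED_MESSAGE)
    raise ValueError(f"unknown generator kind: {kind!r}")


def sample_synthetic_mt(
    model: GeneratorModel, movement: str, n: int, seed: int = 0
) -> list[ProcessedTrial]:
    """Draw ``n`` synthetic strain trials conditioned on ``movement``."""
    if model.condition_mode != "class_label":
        raise ValueError("model is not class-conditional")
    if movement not in model.labels:
        raise ValueError(f"unknown movement label: {movement!r}")
    if n == 0:
        return []
    if model.kind == "cvae":
        from .cvae import sample_class_cvae as sampler
    else:
        from .diffusion import sample_class_diffusion as sampler
    samples = sampler(model, model.labels.index(movement), n, seed)  # (n, 6, T)
    return [
        ProcessedTrial(
            subject_id="synthetic",
            movement=movement,
            repetition=i,
            strain=samples[i],
            synthetic=True,
            provenance=[f"generated({model.kind}, seed={seed})"],
        )
        for i in range(n)
    ]


def train_kinematics_translator(
    kind: str,
    paired: list[ProcessedTrial],
    config: CVAEConfig | DiffusionConfig | None = None,
) -> GeneratorModel:
    """Train a strain-series-conditioned kinematics generator."""
    if any(t.kinematics is None for t in paired):
        raise ValueError("every trial must carry paired kinematics")
    _, n_steps = _check_dataset(paired, need_classes=False)
    strain = np.stack([t.strain for t in paired])
    kin = np.stack([t.kinematics for t in paired])
    if kind == "cvae":
        from .cvae import train_translator_cvae

        return train_translator_cvae(strain, kin, n_steps, config or CVAEConfig())
    if kind == "diffusion":
        from .diffusion import train_translator_diffusion

        return train_translator_diffusion(strain, kin, n_steps, config or DiffusionConfig())
    if kind == "timegan":
        from .timegan import TimeGAN

        raise NotImplementedError(TimeGAN.EXCLUDED_MESSAGE)
    raise ValueError(f"unknown generator kind: {kind!r}")


def translate_kinematics(
    model: GeneratorModel, strain: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Generate a 6 x T kinematics series conditioned on a strain series."""
    if model.condition_mode != "mt_series":
        raise ValueError("model is not series-conditional")
    strain = np.asarray(strain, dtype=np.float64)
    if strain.shape != (model.n_channels, model.n_steps):
        raise ValueError(
            f"strain shape {strain.shape} does not match model "
            f"({model.n_channels}, {model.n_steps})"
        )
    if model.kind == "cvae":
        from .cvae import translate_cvae as translator
    else:
        from .diffusion import translate_diffusion as translator
    return translator(model, strain, seed)


def load_generator(path: str | Path) -> GeneratorModel:
    """Load a generator saved with :meth:`GeneratorModel.save`."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg_cls = CVAEConfig if manifest["kind"] == "cvae" else DiffusionConfig
    config = cfg_cls(**manifest["config"])
    if manifest["kind"] == "cvae":
        from .cvae import build_cvae_net as builder
    else:
        from .diffusion import build_diffusion_net as builder
    net = builder(
        manifest["condition_mode"],
        manifest["n_channels"] * manifest["n_steps"],
        len(manifest["labels"]),
        manifest["n_steps"],
        manifest["n_channels"],
        config,
        np.random.default_rng(manifest["seed"]),
    )
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state_dict(dict(data))
    return GeneratorModel(
        kind=manifest["kind"],
        condition_mode=manifest["condition_mode"],
        config=config,
        net=net,
        labels=tuple(manifest["labels"]),
        n_steps=manifest["n_steps"],
        n_channels=manifest["n_channels"],
        seed=manifest["seed"],
    )
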