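"""Frequency-domain channel augmentation and feature-tensor assembly."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureTensor", "dtft_channels", "assemble_features"]

_STRAIN_ROLES = tuple(f"strain{i}" for i in range(1, 7))
_DTFT_ROLES = tuple(f"dtft{i}" for i in range(1, 7))
_KIN_ROLES = tuple(f"kin{i}" for i in range(1, 7))


@dataclass
class FeatureTensor:
    """Stacked channels (strain, optional frequency, optional kinematics)."""

    values: np.ndarray  # (C, T')
    channel_roles: tuple[str, ...]
    label: str
    subject_id: str
    repetition: int
    synthetic: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (channels x time)")
        if self.values.shape[0] != len(self.channel_roles):
            raise ValueError("channel count must match role list length")
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError("channel roles must be unique")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def block(self, prefix: str) -> np.ndarray:
        """Slice out the channels whose role starts with ``prefix``."""
        idx = [i for i, r in enumerate(self.channel_roles) if r.startswith(prefix)]
        if not idx:
            raise KeyError(f"no channels with role prefix {prefix!r}")
        return self.values[idx]


def dtft_channels(strain: np.ndarray) -> np.ndarray:
    """Per-channel magnitude spectrum, stackable alongside the time channels.

    Returns |DFT(x)| / T for each channel: a length-T, two-sided magnitude
    sequence that is invariant to circular time shifts of the input.
    """
    strain = np.asarray(strain, dtype=np.float64)
    if strain.ndim != 2:
        raise ValueError("strain must be 2-D (channels x time)")
    t = strain.shape[1]
    if t < 2:
        raise ValueError("need at least 2 time steps")
    return np.abs(np.fft.fft(strain, axis=1)) / t


def assemble_features(
    strain: np.ndarray,
    dtft: np.ndarray | None = None,
    kinematics: np.ndarray | None = None,
    *,
    label: str = "",
    subject_id: str = "",
    repetition: int = 0,
    synthetic: bool = False,
) -> FeatureTensor:
    """Stack the provided 6-channel blocks into one feature tensor.

    Block order is fixed (strain, frequency, kinematics) so the channel count
    is 6, 12 or 18 depending on which blocks are supplied.
    """
    strain = np.asarray(strain, dtype=np.float64)
    if strain.shape[0] != 6:
        raise ValueError("strain block must have 6 channels")
    blocks = [strain]
    roles: list[str] = list(_STRAIN_ROLES)
    for block, block_roles, name in (
        (dtft, _DTFT_ROLES, "dtft"),
        (kinematics, _KIN_ROLES, "kinematics"),
    ):
        if block is None:
            continue
        block = np.asarray(block, dtype=np.float64)
        if block.shape != strain.shape:
            raise ValueError(
                f"{name} block shape {block.shape} does not match strain {strain.shape}"
            )
        blocks.append(block)
        roles.extend(block_roles)
    return FeatureTensor(
        values=np.concatenate(blocks, axis=0),
        channel_roles=tuple(roles),
        label=label,
        subject_id=subject_id,
        repetition=repetition,
        synthetic=synthetic,
    )
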