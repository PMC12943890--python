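"""Interface stub for an adversarial time-series generator.

Excluded from the shipped pipeline after poor generative quality in the
model comparison; the class documents the interface a future implementation
would need to satisfy.
"""

from __future__ import annotations

__all__ = ["TimeGAN"]


class TimeGAN:
    EXCLUDED_MESSAGE = (
        "The adversarial generator is excluded from this pipeline due to poor "
        "generative quality (mode collapse); only its interface is defined."
    )

    def __init__(self, *args, **kwargs):
        raise NotImplementedError(self.EXCLUDED_MESSAGE)

    def train(self, dataset, config):  # pragma: no cover - stub
        raise NotImplementedError(self.EXCLUDED_MESSAGE)

    def sample(self, condition, n, seed):  # pragma: no cover - stub
        raise NotImplementedError(self.EXCLUDED_MESSAGE)
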