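"""Generative-quality metrics: 1-D Wasserstein and discrete Fréchet distances.

Set-level reductions follow two conventions: the Wasserstein score pools all
values per channel across samples and time and averages the per-channel 1-D
distances; the Fréchet time-series score matches every synthetic sample to
its nearest real sample of the same class and reports the mean of those
minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # optional JIT for the O(T^2) dynamic program
    from numba import njit as _njit
except Exception:  # pragma: no cover - numba present in the target env
    _njit = None

__all__ = [
    "SeriesSet",
    "wasserstein_1d",
    "wasserstein_sets",
    "discrete_frechet",
    "ftsd_sets",
]


@dataclass
class SeriesSet:
    """A homogeneous collection of C x T series with class labels."""

    samples: list[np.ndarray]
    labels: list[str]
    role: str = "real"

    def __post_init__(self):
        self.samples = [np.asarray(s, dtype=np.float64) for s in self.samples]
        if len(self.samples) != len(self.labels):
            raise ValueError("one label per sample required")
        if self.samples:
            shape = self.samples[0].shape
            for s in self.samples:
                if s.shape != shape:
                    raise ValueError("all samples must share C and T")

    @property
    def n_channels(self) -> int:
        return self.samples[0].shape[0]


def wasserstein_1d(a: np.ndarray, b: np.ndarray) -> float:
    """Exact empirical W1 between two 1-D value samples.

    Computed from the quantile (sorted-sample) representation, which realizes
    the optimal coupling for 1-D marginals.
    """
    a = np.sort(np.asarray(a, dtype=np.float64).ravel())
    b = np.sort(np.asarray(b, dtype=np.float64).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if a.size == b.size:
        return float(np.mean(np.abs(a - b)))
    # unequal sizes: integrate |F_a(x) - F_b(x)| dx over the merged support
    grid = np.sort(np.concatenate([a, b]))
    deltas = np.diff(grid)
    cdf_a = np.searchsorted(a, grid[:-1], side="right") / a.size
    cdf_b = np.searchsorted(b, grid[:-1], side="right") / b.size
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def wasserstein_sets(a: SeriesSet, b: SeriesSet) -> float:
    """Channel-averaged pooled 1-D Wasserstein distance between two sets."""
    if not a.samples or not b.samples:
        raise ValueError("empty series set")
    if a.n_channels != b.n_channels:
        raise ValueError("channel count mismatch")
    c = a.n_channels
    pooled_a = np.concatenate([s.reshape(c, -1) for s in a.samples], axis=1)
    pooled_b = np.concatenate([s.reshape(c, -1) for s in b.samples], axis=1)
    return float(np.mean([wasserstein_1d(pooled_a[ch], pooled_b[ch]) for ch in range(c)]))


def _frechet_dp(dist: np.ndarray) -> float:
    n, m = dist.shape
    ca = np.empty((n, m))
    ca[0, 0] = dist[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], dist[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], dist[i, 0])
        for j in range(1, m):
            best = min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1])
            ca[i, j] = max(best, dist[i, j])
    return ca[n - 1, m - 1]


if _njit is not None:
    _frechet_dp = _njit(cache=False)(_frechet_dp)


def discrete_frechet(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete Fréchet distance between two point sequences.

    ``p`` and ``q`` are (T, C) sequences of C-dimensional points (1-D inputs
    are treated as scalar points).  The point metric is Euclidean across the C
    coordinates; the dynamic program minimizes, over monotone couplings of the
    two index sets, the maximum pointwise distance.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.ndim == 1:
        p = p[:, None]
    if q.ndim == 1:
        q = q[:, None]
    if p.size == 0 or q.size == 0:
        raise ValueError("empty sequence")
    if p.shape[1] != q.shape[1]:
        raise ValueError("point dimension mismatch")
    dist = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    return float(_frechet_dp(dist))


def series_frechet(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete Fréchet distance between two C x T series (points = time steps)."""
    return discrete_frechet(np.asarray(a).T, np.asarray(b).T)


def ftsd_sets(real: SeriesSet, synthetic: SeriesSet) -> float:
    """Mean over synthetic samples of the Fréchet distance to the nearest
    same-class real sample."""
    if not real.samples or not synthetic.samples:
        raise ValueError("empty series set")
    if real.samples[0].shape != synthetic.samples[0].shape:
        raise ValueError("shape mismatch between sets")
    by_class: dict[str, list[np.ndarray]] = {}
    for s, lab in zip(real.samples, real.labels):
        by_class.setdefault(lab, []).append(s)
    scores = []
    for s, lab in zip(synthetic.samples, synthetic.labels):
        if lab not in by_class:
            raise ValueError(f"class {lab!r} absent from the real set")
        scores.append(min(series_frechet(s, r) for r in by_class[lab]))
    return float(np.mean(scores))
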