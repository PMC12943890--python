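"""Processing chain from raw resistance trials to aligned, normalized trials.

Fixed stage order: baseline normalization -> (optional swap) 10-SD trial
exclusion -> Hampel outlier filtering -> temporal align/trim against paired
kinematics -> per-(subject, movement) min-max normalization to [-1, 1].
Every applied stage is recorded in the trial's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simdata import KinTrial, RawMTTrial

__all__ = [
    "ProcessedTrial",
    "PreprocessConfig",
    "baseline_normalize",
    "hampel_filter",
    "exclude_noisy_trials",
    "align_and_trim",
    "minmax_normalize_per_movement_trial",
    "process_cohort",
]

_MAD_SCALE = 1.4826  # MAD -> SD for Gaussian data


@dataclass
class ProcessedTrial:
    """A fully processed trial: strain (and optional kinematics) in [-1, 1]."""

    subject_id: str
    movement: str
    repetition: int
    strain: np.ndarray  # (6, T')
    kinematics: np.ndarray | None = None  # (6, T')
    synthetic: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=np.float64)
        if self.strain.ndim != 2 or self.strain.shape[0] != 6:
            raise ValueError("strain must have shape (6, T)")
        if self.kinematics is not None:
            self.kinematics = np.asarray(self.kinematics, dtype=np.float64)
            if self.kinematics.shape != self.strain.shape:
                raise ValueError("kinematics must match strain shape")

    @property
    def n_steps(self) -> int:
        return self.strain.shape[1]


@dataclass(frozen=True)
class PreprocessConfig:
    hampel_window: int = 11
    hampel_n_sigmas: float = 3.0
    exclude_n_sd: float = 10.0
    exclude_before_hampel: bool = True


def baseline_normalize(resistance: np.ndarray, baseline: float | np.ndarray) -> np.ndarray:
    """Relative resistance change (R - R0) / R0."""
    resistance = np.asarray(resistance, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if np.any(baseline <= 0):
        raise ValueError("baseline resistance must be positive")
    if baseline.ndim == 1 and resistance.ndim == 2:
        baseline = baseline[:, None]
    return (resistance - baseline) / baseline


def hampel_filter(
    x: np.ndarray, window: int = 11, n_sigmas: float = 3.0
) -> np.ndarray:
    """Sliding-window median/MAD outlier replacement.

    A point is replaced by its local median when it deviates from that median
    by more than ``n_sigmas`` robust standard deviations (1.4826 x MAD).
    Windows are centred and truncated at the series edges.  When the local MAD
    is zero the point is replaced only if it differs from the median at all,
    so constant series pass through unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return np.stack([hampel_filter(row, window, n_sigmas) for row in x])
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = x.size
    if window > n:
        window = n if n % 2 == 1 else n - 1
        if window < 3:
            return x.copy()
    half = window // 2
    padded = np.full(n + 2 * half, np.nan)
    padded[half : half + n] = x
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(padded, window)  # (n, window)
    med = np.nanmedian(windows, axis=1)
    mad = np.nanmedian(np.abs(windows - med[:, None]), axis=1)
    sigma = _MAD_SCALE * mad
    dev = np.abs(x - med)
    replace = np.where(sigma > 0, dev > n_sigmas * sigma, dev > 0)
    return np.where(replace, med, x)


def exclude_noisy_trials(
    trials: list[RawMTTrial | ProcessedTrial] | list[np.ndarray],
    n_sd: float = 10.0,
) -> tuple[list, list, list[dict]]:
    """Partition trials into (kept, dropped) by the per-channel spike rule.

    A trial is dropped iff any channel contains a value greater than that
    channel's within-trial mean plus ``n_sd`` standard deviations.  Returns
    (kept, dropped, reasons) where reasons describes each dropped trial.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    kept: list = []
    dropped: list = []
    reasons: list[dict] = []
    for i, trial in enumerate(trials):
        series = trial if isinstance(trial, np.ndarray) else _series_of(trial)
        mean = series.mean(axis=1, keepdims=True)
        sd = series.std(axis=1, keepdims=True)
        over = series > mean + n_sd * sd
        if over.any():
            dropped.append(trial)
            ch, at = np.argwhere(over)[0]
            reasons.append(
                {
                    "index": i,
                    "subject_id": getattr(trial, "subject_id", None),
                    "movement": getattr(trial, "movement", None),
                    "repetition": getattr(trial, "repetition", None),
                    "channel": int(ch),
                    "time_index": int(at),
                    "n_sd": float(n_sd),
                }
            )
        else:
            kept.append(trial)
    return kept, dropped, reasons


def _series_of(trial) -> np.ndarray:
    if isinstance(trial, RawMTTrial):
        return trial.resistance
    if isinstance(trial, ProcessedTrial):
        return trial.strain
    raise TypeError(f"unsupported trial type: {type(trial)!r}")


def align_and_trim(
    strain: np.ndarray, kinematics: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Trim both series (sharing t=0) to their common length."""
    strain = np.asarray(strain, dtype=np.float64)
    if kinematics is None:
        return strain, None
    kinematics = np.asarray(kinematics, dtype=np.float64)
    t = min(strain.shape[1], kinematics.shape[1])
    if t == 0:
        raise ValueError("empty overlap between strain and kinematics")
    return strain[:, :t], kinematics[:, :t]


def _minmax_map(block: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    out = np.zeros_like(block)
    # degenerate (constant-within-group) channels stay at 0
    for c in range(block.shape[0]):
        if span[c] > 0:
            out[c] = -1.0 + 2.0 * (block[c] - lo[c]) / span[c]
    return out


def minmax_normalize_per_movement_trial(
    trials: list[ProcessedTrial],
) -> list[ProcessedTrial]:
    """Scale each (subject, movement) group of repetitions to [-1, 1].

    Per group and per channel, the group minimum maps to -1 and the maximum
    to +1, applied identically to every repetition in the group.  Kinematics
    channels get the same treatment with their own group extrema.  A channel
    that is constant within its group maps to 0.
    """
    groups: dict[tuple[str, str], list[ProcessedTrial]] = {}
    for t in trials:
        groups.setdefault((t.subject_id, t.movement), []).append(t)
    out: list[ProcessedTrial] = []
    for key, members in groups.items():
        strain_all = np.concatenate([m.strain for m in members], axis=1)
        lo, hi = strain_all.min(axis=1), strain_all.max(axis=1)
        has_kin = all(m.kinematics is not None for m in members)
        if has_kin:
            kin_all = np.concatenate([m.kinematics for m in members], axis=1)
            klo, khi = kin_all.min(axis=1), kin_all.max(axis=1)
        for m in members:
            strain = _minmax_map(m.strain, lo, hi)
            kin = _minmax_map(m.kinematics, klo, khi) if has_kin else None
            out.append(
                ProcessedTrial(
                    subject_id=m.subject_id,
                    movement=m.movement,
                    repetition=m.repetition,
                    strain=strain,
                    kinematics=kin,
                    synthetic=m.synthetic,
                    provenance=m.provenance + ["minmax_per_movement_trial"],
                )
            )
    return out


def process_cohort(
    pairs: list[tuple[RawMTTrial, KinTrial | None]],
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[list[ProcessedTrial], list[dict]]:
    """Run the full processing chain on raw (strain, kinematics) pairs.

    Returns the processed trials and a drop report listing excluded trials.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one trial pair")
    staged: list[ProcessedTrial] = []
    for mt, kin in pairs:
        rn = baseline_normalize(mt.resistance, mt.baseline)
        staged.append(
            ProcessedTrial(
                subject_id=mt.subject_id,
                movement=mt.movement,
                repetition=mt.repetition,
                strain=rn,
                kinematics=None if kin is None else kin.angles,
                provenance=["baseline_normalize"],
            )
        )

    def apply_hampel(items: list[ProcessedTrial]) -> None:
        for t in items:
            t.strain = hampel_filter(t.strain, config.hampel_window, config.hampel_n_sigmas)
            t.provenance.append(
                f"hampel(window={config.hampel_window}, n_sigmas={config.hampel_n_sigmas})"
            )

    if config.exclude_before_hampel:
        kept, _, reasons = exclude_noisy_trials(staged, config.exclude_n_sd)
        apply_hampel(kept)
    else:
        apply_hampel(staged)
        kept, _, reasons = exclude_noisy_trials(staged, config.exclude_n_sd)
    for t in kept:
        t.provenance.append(f"exclude_noisy(n_sd={config.exclude_n_sd})")

    for t in kept:
        strain, kin = align_and_trim(t.strain, t.kinematics)
        t.strain, t.kinematics = strain, kin
        t.provenance.append("align_and_trim")

    return minmax_normalize_per_movement_trial(kept), reasons
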