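"""Seeded simulator for six-channel strain-sensor cohorts with paired kinematics.

The simulator emits trials with the qualitative structure of low-back
movement recordings from a 3x2 grid of skin-strain sensors: movement-specific
per-channel activation profiles, left/right asymmetry for lateral bends and
rotations, deliberately confusable rotation classes, per-subject amplitude
and timing variability, sensor noise, sparse resistance spikes and baseline
offsets.  Everything is reproducible from a single integer seed.

Sensor layout convention: channels ``mt1..mt6`` are rows (upper, middle,
lower) by columns (left, right), i.e. odd channels sit left of the spine and
even channels right; ``mt5``/``mt6`` are the lowest pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MOVEMENTS",
    "KIN_CHANNEL_ROLES",
    "CohortConfig",
    "RawMTTrial",
    "KinTrial",
    "movement_template",
    "kinematics_from_template",
    "make_cohort",
]

#: Canonical ordered movement label set.
MOVEMENTS: tuple[str, ...] = (
    "extension",
    "flexion",
    "lateral_bend_left",
    "lateral_bend_right",
    "rotation_left",
    "rotation_right",
)

#: Euler-angle channel order: upper-to-lower lumbar x/y/z, lower-to-pelvis x/y/z.
KIN_CHANNEL_ROLES: tuple[str, ...] = (
    "upper_lower_x",
    "upper_lower_y",
    "upper_lower_z",
    "lower_pelvis_x",
    "lower_pelvis_y",
    "lower_pelvis_z",
)

# Per-channel activation gains for the unit bump, order mt1..mt6.
# Flexion: tension everywhere, lowest sensor pair (5, 6) largest, then (3, 4).
# Extension: compression, largest at the top pair.
# Lateral bends: opposite signs across the left {1,3,5} / right {2,4,6} columns.
# Rotations: small-amplitude, row-alternating asymmetry; deliberately NOT exact
# mirrors so the overlap->1 limit keeps a nonzero shared template.
_GAINS: dict[str, np.ndarray] = {
    "flexion": np.array([0.35, 0.35, 0.65, 0.65, 1.0, 1.0]),
    "extension": np.array([-0.9, -0.9, -0.65, -0.65, -0.45, -0.45]),
    "lateral_bend_left": np.array([-0.7, 0.9, -0.6, 0.8, -0.5, 0.7]),
    "lateral_bend_right": np.array([0.9, -0.7, 0.8, -0.6, 0.7, -0.5]),
    "rotation_left": np.array([0.40, -0.35, -0.30, 0.28, 0.22, -0.20]),
    "rotation_right": np.array([-0.35, 0.42, 0.26, -0.32, -0.18, 0.24]),
}

_ROTATIONS = ("rotation_left", "rotation_right")

#: Nominal unstretched per-channel resistance (arbitrary units); the absolute
#: scale cancels under baseline normalization.
NOMINAL_BASELINE = 10.0


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated cohort."""

    n_subjects: int = 10
    movements: tuple[str, ...] = MOVEMENTS
    reps_per_movement: int = 3
    sample_period: float = 0.020
    duration: float = 6.0
    noise_sd: float = 0.02
    spike_rate: float = 0.0
    spike_magnitude: float = 5.0
    drift_amplitude: float = 0.0
    class_overlap: float = 0.5
    amplitude_sd: float = 0.15
    timing_sd: float = 0.05
    baseline_sd: float = 0.05
    length_jitter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.reps_per_movement < 1:
            raise ValueError("reps_per_movement must be >= 1")
        if not 0.0 <= self.class_overlap <= 1.0:
            raise ValueError("class_overlap must lie in [0, 1]")
        for m in self.movements:
            if m not in MOVEMENTS:
                raise ValueError(f"unknown movement label: {m!r}")
        if self.n_steps < 8:
            raise ValueError("duration / sample_period must give at least 8 steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.sample_period))

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class RawMTTrial:
    """One trial of raw six-channel resistance readings."""

    subject_id: str
    movement: str
    repetition: int
    resistance: np.ndarray  # (6, T)
    baseline: np.ndarray  # (6,)
    sample_period: float

    def __post_init__(self):
        self.resistance = np.asarray(self.resistance, dtype=np.float64)
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        if self.resistance.ndim != 2 or self.resistance.shape[0] != 6:
            raise ValueError("resistance must have shape (6, T)")
        if self.baseline.shape != (6,) or np.any(self.baseline <= 0):
            raise ValueError("baseline must be 6 positive values")

    @property
    def n_steps(self) -> int:
        return self.resistance.shape[1]


@dataclass
class KinTrial:
    """One trial of six Euler-angle channels paired with a strain trial."""

    subject_id: str
    movement: str
    repetition: int
    angles: np.ndarray  # (6, T)
    channel_roles: tuple[str, ...] = KIN_CHANNEL_ROLES

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.ndim != 2 or self.angles.shape[0] != 6:
            raise ValueError("angles must have shape (6, T)")
        if len(self.channel_roles) != 6:
            raise ValueError("exactly 6 kinematics channel roles required")

    @property
    def n_steps(self) -> int:
        return self.angles.shape[1]


def _bump(phase: np.ndarray) -> np.ndarray:
    """Smooth rise-hold-return activation on normalized phase in [0, 1]."""
    rise0, rise1, fall0, fall1 = 0.15, 0.40, 0.60, 0.85
    p = np.asarray(phase, dtype=np.float64)
    out = np.zeros_like(p)
    m = (p >= rise0) & (p < rise1)
    out[m] = 0.5 * (1.0 - np.cos(np.pi * (p[m] - rise0) / (rise1 - rise0)))
    out[(p >= rise1) & (p < fall0)] = 1.0
    m = (p >= fall0) & (p < fall1)
    out[m] = 0.5 * (1.0 + np.cos(np.pi * (p[m] - fall0) / (fall1 - fall0)))
    return out


def _gains(movement: str, class_overlap: float) -> np.ndarray:
    try:
        g = _GAINS[movement]
    except KeyError:
        raise ValueError(f"unknown movement label: {movement!r}") from None
    if movement in _ROTATIONS:
        shared = 0.5 * (_GAINS["rotation_left"] + _GAINS["rotation_right"])
        g = (1.0 - class_overlap) * g + class_overlap * shared
    return g


def _template_at(movement: str, phase: np.ndarray, class_overlap: float) -> np.ndarray:
    return np.outer(_gains(movement, class_overlap), _bump(phase))


def movement_template(movement: str, n_steps: int, class_overlap: float = 0.5) -> np.ndarray:
    """Deterministic noiseless 6 x T strain profile for one movement.

    Parameters
    ----------
    movement:
        One of :data:`MOVEMENTS`.
    n_steps:
        Number of time steps T (>= 8).
    class_overlap:
        In [0, 1]; pulls the two rotation templates toward their common mean,
        making them pairwise closer (identical at 1).
    """
    if n_steps < 8:
        raise ValueError("n_steps must be >= 8")
    if not 0.0 <= class_overlap <= 1.0:
        raise ValueError("class_overlap must lie in [0, 1]")
    phase = np.linspace(0.0, 1.0, n_steps)
    return _template_at(movement, phase, class_overlap)


# Linear read-out from strain channels to Euler-angle channels.  Rows follow
# KIN_CHANNEL_ROLES.  x channels respond to the symmetric (all-sensor) mean,
# y channels to the left-right column contrast, z channels to a row-alternating
# contrast that matches the rotation gain pattern.  Lower-to-pelvis angles are
# scaled larger than upper-to-lower ones.
_SYM = np.full(6, 1.0 / 6.0)
_LAT = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]) / 6.0
_ROT = np.array([1.0, -1.0, -1.0, 1.0, 1.0, -1.0]) / 6.0
_KIN_MAP = np.stack(
    [-40.0 * _SYM, 30.0 * _LAT, 45.0 * _ROT, -55.0 * _SYM, 38.0 * _LAT, 55.0 * _ROT]
)
_SMOOTH_WINDOW = 5


def kinematics_from_template(movement: str, template: np.ndarray) -> np.ndarray:
    """Map a 6 x T strain profile onto 6 Euler-angle channels.

    Deterministic linear map followed by a short moving-average smoothing;
    flexion/extension dominantly drive the x channels, lateral bends the y
    channels and rotations the z channels.  Serves as the ground-truth
    sensor-to-kinematics relation that the translator models must recover.
    """
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement label: {movement!r}")
    template = np.asarray(template, dtype=np.float64)
    if template.ndim != 2 or template.shape[0] != 6:
        raise ValueError("template must have shape (6, T)")
    angles = _KIN_MAP @ template
    kernel = np.full(_SMOOTH_WINDOW, 1.0 / _SMOOTH_WINDOW)
    return np.stack([np.convolve(row, kernel, mode="same") for row in angles])


def make_cohort(config: CohortConfig) -> list[tuple[RawMTTrial, KinTrial]]:
    """Generate the full cohort of paired (strain, kinematics) trials.

    Emits ``n_subjects x len(movements) x reps_per_movement`` pairs.  Subject
    variability is amplitude (lognormal around 1) and timing (speed factor);
    per-channel baselines are drawn around the nominal unstretched resistance.
    Measurement noise, sparse positive resistance spikes and slow drift are
    injected into the resistance signal only — kinematics stay clean, mimicking
    reference-grade motion capture.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = config.n_steps
    pairs: list[tuple[RawMTTrial, KinTrial]] = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        amp = float(rng.lognormal(mean=0.0, sigma=config.amplitude_sd))
        speed = float(np.clip(rng.normal(1.0, config.timing_sd), 0.87, 1.15))
        baseline = NOMINAL_BASELINE * (1.0 + config.baseline_sd * rng.standard_normal(6))
        baseline = np.clip(baseline, 0.1 * NOMINAL_BASELINE, None)
        for movement in config.movements:
            for rep in range(config.reps_per_movement):
                t = n_steps
                if config.length_jitter:
                    t = int(round(n_steps * rng.uniform(0.9, 1.1)))
                # repetition-level timing jitter shares timing_sd with the
                # subject-level draw, so within-subject timing variance matches
                # between-subject variance and timing is not a subject signature
                rep_speed = speed
                rep_amp = amp
                if config.timing_sd > 0:
                    rep_speed = float(
                        np.clip(rng.normal(speed, config.timing_sd), 0.87, 1.15)
                    )
                if config.amplitude_sd > 0:
                    rep_amp = amp * float(rng.lognormal(0.0, config.amplitude_sd))
                phase = np.clip(np.linspace(0.0, 1.0, t) * rep_speed, 0.0, 1.0)
                strain = rep_amp * _template_at(movement, phase, config.class_overlap)
                angles = _KIN_MAP @ strain
                kernel = np.full(_SMOOTH_WINDOW, 1.0 / _SMOOTH_WINDOW)
                angles = np.stack([np.convolve(r, kernel, mode="same") for r in angles])

                disturbance = np.zeros_like(strain)
                if config.noise_sd > 0:
                    disturbance += rng.normal(0.0, config.noise_sd, size=strain.shape)
                if config.drift_amplitude > 0:
                    slope = rng.uniform(-1.0, 1.0, size=6)
                    disturbance += config.drift_amplitude * np.outer(
                        slope, np.linspace(0.0, 1.0, t)
                    )
                if config.spike_rate > 0:
                    n_spikes = rng.poisson(config.spike_rate)
                    for _ in range(n_spikes):
                        ch = int(rng.integers(0, 6))
                        at = int(rng.integers(0, t))
                        disturbance[ch, at] += config.spike_magnitude * rng.uniform(1.0, 1.5)

                resistance = baseline[:, None] * (1.0 + strain + disturbance)
                pairs.append(
                    (
                        RawMTTrial(
                            subject_id=subject_id,
                            movement=movement,
                            repetition=rep,
                            resistance=resistance,
                            baseline=baseline.copy(),
                            sample_period=config.sample_period,
                        ),
                        KinTrial(
                            subject_id=subject_id,
                            movement=movement,
                            repetition=rep,
                            angles=angles,
                        ),
                    )
                )
    return pairs
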