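"""On-disk formats: wide per-trial CSVs plus a JSON cohort manifest.

Trial CSV columns are ``time_s, mt1..mt6`` and optionally ``ang1..ang6``.
Per-channel baselines, labels and flags live in the manifest so the CSV stays
a plain numeric table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ProcessedTrial
from .simdata import KinTrial, RawMTTrial

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_processed",
    "read_processed",
    "save_feature_tensors",
    "load_feature_tensors",
]

_MT_COLS = [f"mt{i}" for i in range(1, 7)]
_ANG_COLS = [f"ang{i}" for i in range(1, 7)]


def _trial_frame(series: np.ndarray, angles: np.ndarray | None, period: float) -> pd.DataFrame:
    t = series.shape[1]
    data = {"time_s": np.arange(t) * period}
    for i, col in enumerate(_MT_COLS):
        data[col] = series[i]
    if angles is not None:
        for i, col in enumerate(_ANG_COLS):
            data[col] = angles[i]
    return pd.DataFrame(data)


def write_cohort(
    pairs: list[tuple[RawMTTrial, KinTrial | None]], outdir: str | Path, seed: int = 0
) -> Path:
    """Write one CSV per raw trial plus ``manifest.json``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for mt, kin in pairs:
        name = f"{mt.subject_id}_{mt.movement}_r{mt.repetition}.csv"
        frame = _trial_frame(
            mt.resistance, None if kin is None else kin.angles, mt.sample_period
        )
        frame.to_csv(outdir / name, index=False)
        entries.append(
            {
                "subject": mt.subject_id,
                "movement": mt.movement,
                "repetition": mt.repetition,
                "file": name,
                "baseline": [float(b) for b in mt.baseline],
                "sample_period": mt.sample_period,
                "has_kinematics": kin is not None,
            }
        )
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"seed": seed, "trials": entries}, indent=2))
    return manifest


def read_cohort(indir: str | Path) -> list[tuple[RawMTTrial, KinTrial | None]]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    pairs = []
    for entry in manifest["trials"]:
        frame = pd.read_csv(indir / entry["file"])
        resistance = frame[_MT_COLS].to_numpy().T
        mt = RawMTTrial(
            subject_id=entry["subject"],
            movement=entry["movement"],
            repetition=entry["repetition"],
            resistance=resistance,
            baseline=np.array(entry["baseline"]),
            sample_period=entry["sample_period"],
        )
        kin = None
        if entry.get("has_kinematics"):
            kin = KinTrial(
                subject_id=entry["subject"],
                movement=entry["movement"],
                repetition=entry["repetition"],
                angles=frame[_ANG_COLS].to_numpy().T,
            )
        pairs.append((mt, kin))
    return pairs


def write_processed(
    trials: list[ProcessedTrial],
    outdir: str | Path,
    sample_period: float = 0.020,
    drop_report: list[dict] | None = None,
) -> Path:
    """Write processed trials in the same CSV dialect (strain in mt columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in trials:
        name = f"{t.subject_id}_{t.movement}_r{t.repetition}.csv"
        _trial_frame(t.strain, t.kinematics, sample_period).to_csv(outdir / name, index=False)
        entries.append(
            {
                "subject": t.subject_id,
                "movement": t.movement,
                "repetition": t.repetition,
                "file": name,
                "synthetic": t.synthetic,
                "has_kinematics": t.kinematics is not None,
                "provenance": t.provenance,
            }
        )
    manifest = outdir / "manifest.json"
    manifest.write_text(
        json.dumps({"processed": True, "trials": entries}, indent=2)
    )
    if drop_report is not None:
        (outdir / "drop_report.json").write_text(json.dumps(drop_report, indent=2))
    return manifest


def read_processed(indir: str | Path) -> list[ProcessedTrial]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    trials = []
    for entry in manifest["trials"]:
        frame = pd.read_csv(indir / entry["file"])
        trials.append(
            ProcessedTrial(
                subject_id=entry["subject"],
                movement=entry["movement"],
                repetition=entry["repetition"],
                strain=frame[_MT_COLS].to_numpy().T,
                kinematics=(
                    frame[_ANG_COLS].to_numpy().T if entry.get("has_kinematics") else None
                ),
                synthetic=entry.get("synthetic", False),
                provenance=list(entry.get("provenance", [])),
            )
        )
    return trials


def save_feature_tensors(tensors, path: str | Path) -> None:
    """NPZ container with channel-role metadata in a JSON sidecar."""
    from .features import FeatureTensor  # local import to avoid cycle

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"x{i}": t.values for i, t in enumerate(tensors)}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = [
        {
            "channel_roles": list(t.channel_roles),
            "label": t.label,
            "subject_id": t.subject_id,
            "repetition": t.repetition,
            "synthetic": t.synthetic,
        }
        for t in tensors
    ]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_feature_tensors(path: str | Path):
    from .features import FeatureTensor

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    out = []
    with np.load(path.with_suffix(".npz")) as data:
        for i, m in enumerate(meta):
            out.append(
                FeatureTensor(
                    values=data[f"x{i}"],
                    channel_roles=tuple(m["channel_roles"]),
                    label=m["label"],
                    subject_id=m["subject_id"],
                    repetition=m["repetition"],
                    synthetic=m["synthetic"],
                )
            )
    return out
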