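"""Evaluation protocol: splits, repeated trials, the four-arm ablation grid,
the subject-identifiability control and PCA projection.

Synthetic samples are never allowed into a test set; every split routine
asserts this invariant before returning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .classify import ClassifierConfig, score, train_classifier
from .features import FeatureTensor, assemble_features, dtft_channels
from .generate import (
    CVAEConfig,
    DiffusionConfig,
    sample_synthetic_mt,
    train_class_conditional,
    train_kinematics_translator,
    translate_kinematics,
)
from .preprocess import ProcessedTrial

__all__ = [
    "SplitPlan",
    "EvalReport",
    "ABLATION_ARMS",
    "make_split",
    "build_feature_tensors",
    "run_ablation",
    "subject_identifiability_control",
    "pca_projection",
]

ABLATION_ARMS = ("base", "data_augment", "feature_augment", "combined")


@dataclass(frozen=True)
class SplitPlan:
    kind: str = "stratified_sample"  # | "loso" | "kfold"
    test_fraction: float = 0.25
    folds: int = 5
    group_key: str = "subject"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.kind not in ("stratified_sample", "loso", "kfold"):
            raise ValueError(f"unknown split kind: {self.kind!r}")


@dataclass
class EvalReport:
    """Per-arm mean +/- SD accuracy over repeated seeded trials."""

    arms: dict[str, dict] = field(default_factory=dict)
    n_trials: int = 0
    master_seed: int = 0
    classifier_kind: str = ""
    generator_kind: str = ""

    def to_dict(self) -> dict:
        return {
            "arms": self.arms,
            "n_trials": self.n_trials,
            "master_seed": self.master_seed,
            "classifier_kind": self.classifier_kind,
            "generator_kind": self.generator_kind,
        }


def _assert_no_synthetic(dataset, test_idx) -> None:
    for i in test_idx:
        if getattr(dataset[i], "synthetic", False):
            raise AssertionError("synthetic sample leaked into a test split")


def _label_of(item) -> str:
    return item.label if isinstance(item, FeatureTensor) else item.movement


def make_split(dataset: list, plan: SplitPlan):
    """Train/test index sets (or a fold list for loso/kfold).

    Accepts processed trials or feature tensors.  Synthetic samples are
    forced into the train side of every split.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(plan.seed)
    synthetic_idx = [i for i in range(n) if getattr(dataset[i], "synthetic", False)]
    real_idx = [i for i in range(n) if not getattr(dataset[i], "synthetic", False)]

    if plan.kind == "stratified_sample":
        by_class: dict[str, list[int]] = {}
        for i in real_idx:
            by_class.setdefault(_label_of(dataset[i]), []).append(i)
        n_test = int(round(len(real_idx) * plan.test_fraction))
        quotas = {c: len(v) * plan.test_fraction for c, v in by_class.items()}
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        remainder = n_test - sum(base.values())
        order = sorted(
            by_class, key=lambda c: (-(quotas[c] - base[c]), rng.random())
        )
        for c in order[:remainder]:
            base[c] += 1
        test_idx: list[int] = []
        for c, members in by_class.items():
            members = list(members)
            rng.shuffle(members)
            test_idx.extend(members[: base[c]])
        test_idx = sorted(test_idx)
        train_idx = sorted(set(range(n)) - set(test_idx))
        _assert_no_synthetic(dataset, test_idx)
        return train_idx, test_idx

    if plan.kind == "loso":
        subjects = sorted({dataset[i].subject_id for i in real_idx})
        if len(subjects) < 2:
            raise ValueError("leave-one-subject-out needs at least 2 subjects")
        folds = []
        for subject in subjects:
            test_idx = [i for i in real_idx if dataset[i].subject_id == subject]
            train_idx = sorted(set(range(n)) - set(test_idx))
            _assert_no_synthetic(dataset, test_idx)
            folds.append((train_idx, test_idx))
        return folds

    # stratified k-fold over real samples
    if len(real_idx) < plan.folds:
        raise ValueError("fewer real samples than folds")
    by_class = {}
    for i in real_idx:
        by_class.setdefault(_label_of(dataset[i]), []).append(i)
    assignment: dict[int, int] = {}
    for members in by_class.values():
        members = list(members)
        rng.shuffle(members)
        for j, i in enumerate(members):
            assignment[i] = j % plan.folds
    folds = []
    for f in range(plan.folds):
        test_idx = sorted(i for i, g in assignment.items() if g == f)
        train_idx = sorted(set(range(n)) - set(test_idx))
        _assert_no_synthetic(dataset, test_idx)
        folds.append((train_idx, test_idx))
    return folds


def build_feature_tensors(
    trials: list[ProcessedTrial],
    use_dtft: bool = False,
    kin_source: str = "none",  # "none" | "real" | "translated"
    translator=None,
    seed: int = 0,
    label_by: str = "movement",
) -> list[FeatureTensor]:
    """Assemble feature tensors for a trial list.

    ``kin_source='real'`` uses each trial's recorded kinematics;
    ``'translated'`` generates them from the strain series with the given
    translator model (one seeded draw per trial).
    """
    out = []
    for i, t in enumerate(trials):
        dtft = dtft_channels(t.strain) if use_dtft else None
        if kin_source == "real":
            if t.kinematics is None:
                raise ValueError("trial lacks recorded kinematics")
            kin = t.kinematics
        elif kin_source == "translated":
            if translator is None:
                raise ValueError("translated kinematics require a translator model")
            kin = translate_kinematics(translator, t.strain, seed=seed + i)
        elif kin_source == "none":
            kin = None
        else:
            raise ValueError(f"unknown kin_source: {kin_source!r}")
        out.append(
            assemble_features(
                t.strain,
                dtft=dtft,
                kinematics=kin,
                label=t.movement if label_by == "movement" else t.subject_id,
                subject_id=t.subject_id,
                repetition=t.repetition,
                synthetic=t.synthetic,
            )
        )
    return out


def run_ablation(
    dataset: list[ProcessedTrial],
    classifier_config: ClassifierConfig = ClassifierConfig(),
    generator_kind: str = "cvae",
    generator_config: CVAEConfig | DiffusionConfig | None = None,
    n_trials: int = 5,
    test_fraction: float = 0.25,
    per_class_synthetic: int = 20,
    arms: tuple[str, ...] = ABLATION_ARMS,
    master_seed: int = 0,
) -> EvalReport:
    """Execute the augmentation ablation grid.

    Arms: ``base`` (6 strain channels, real data only), ``data_augment``
    (+synthetic strain trials in train only), ``feature_augment`` (+frequency
    and RECORDED kinematics channels, real data only) and ``combined``
    (synthetic strain + frequency channels + TRANSLATED kinematics).
    Generators are trained per trial on that trial's training split only.
    """
    unknown = set(arms) - set(ABLATION_ARMS)
    if unknown:
        raise ValueError(f"unknown ablation arms: {sorted(unknown)}")
    needs_kin = {"feature_augment", "combined"} & set(arms)
    if needs_kin and any(t.kinematics is None for t in dataset):
        raise ValueError("feature-augmentation arms require paired kinematics")

    accuracies: dict[str, list[float]] = {arm: [] for arm in arms}
    for trial in range(n_trials):
        seed = master_seed * 10_000 + trial
        plan = SplitPlan(kind="stratified_sample", test_fraction=test_fraction, seed=seed)
        train_idx, test_idx = make_split(dataset, plan)
        train = [dataset[i] for i in train_idx]
        test = [dataset[i] for i in test_idx]
        _assert_no_synthetic(dataset, test_idx)

        synthetic: list[ProcessedTrial] = []
        if {"data_augment", "combined"} & set(arms):
            gen = train_class_conditional(
                generator_kind, train, generator_config
            )
            for lab in gen.labels:
                synthetic.extend(
                    sample_synthetic_mt(gen, lab, per_class_synthetic, seed=seed + 1)
                )
        translator = None
        if "combined" in arms:
            translator = train_kinematics_translator(
                generator_kind, train, generator_config
            )

        cfg = classifier_config.with_(seed=seed)
        for arm in arms:
            if arm == "base":
                tr = build_feature_tensors(train)
                te = build_feature_tensors(test)
            elif arm == "data_augment":
                tr = build_feature_tensors(train + synthetic)
                te = build_feature_tensors(test)
            elif arm == "feature_augment":
                tr = build_feature_tensors(train, use_dtft=True, kin_source="real")
                te = build_feature_tensors(test, use_dtft=True, kin_source="real")
            else:  # combined
                tr = build_feature_tensors(
                    train + synthetic,
                    use_dtft=True,
                    kin_source="translated",
                    translator=translator,
                    seed=seed + 2,
                )
                te = build_feature_tensors(
                    test,
                    use_dtft=True,
                    kin_source="translated",
                    translator=translator,
                    seed=seed + 3,
                )
            model = train_classifier(tr, cfg)
            accuracies[arm].append(score(model, te)["accuracy"])

    report = EvalReport(
        n_trials=n_trials,
        master_seed=master_seed,
        classifier_kind=classifier_config.kind,
        generator_kind=generator_kind,
    )
    for arm, accs in accuracies.items():
        report.arms[arm] = {
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs)),
            "accuracies": [float(a) for a in accs],
        }
    return report


def subject_identifiability_control(
    dataset: list[ProcessedTrial],
    folds: int = 5,
    classifier_config: ClassifierConfig | None = None,
    seed: int = 0,
) -> dict:
    """Train a subject classifier under k-fold CV; near-chance accuracy means
    the features carry no strong subject signature."""
    subjects = sorted({t.subject_id for t in dataset})
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    cfg = classifier_config or ClassifierConfig(kind="cnn_lstm", epochs=30)
    tensors = build_feature_tensors(dataset, label_by="subject")
    plan = SplitPlan(kind="kfold", folds=folds, seed=seed)
    fold_list = make_split(tensors, plan)
    accs = []
    for f, (train_idx, test_idx) in enumerate(fold_list):
        model = train_classifier([tensors[i] for i in train_idx], cfg.with_(seed=seed + f))
        accs.append(score(model, [tensors[i] for i in test_idx])["accuracy"])
    return {
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs)),
        "fold_accuracies": [float(a) for a in accs],
        "chance": 1.0 / len(subjects),
        "n_subjects": len(subjects),
        "folds": folds,
    }


def pca_projection(dataset: list[FeatureTensor], n_components: int = 2) -> dict:
    """Principal-component coordinates of flattened feature vectors."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 samples")
    x = np.stack([t.values.ravel() for t in dataset])
    n_components = min(n_components, min(x.shape))
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(x)
    return {
        "coordinates": coords,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "subjects": [t.subject_id for t in dataset],
        "movements": [t.label for t in dataset],
    }
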