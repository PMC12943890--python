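# motiontape

Classification pipeline for six low-back movements recorded with a 3×2 grid
of wearable strain sensors ("motion tape"), including:

- **`simdata`** — a seeded cohort simulator that emulates the statistical
  structure of such recordings (movement-specific per-sensor activation
  profiles, left/right asymmetry for lateral bends and rotations, confusable
  rotation classes, subject amplitude/timing variability, sensor noise,
  sparse resistance spikes) together with paired ground-truth Euler-angle
  kinematics generated by a known strain→angle map.
- **`preprocess`** — baseline normalization `(R − R0)/R0`, Hampel outlier
  filtering, 10-SD noisy-trial exclusion, temporal align/trim, and
  per-(subject, movement) min-max scaling to [−1, 1].
- **`features`** — per-channel DFT-magnitude frequency channels and assembly
  of 6/12/18-channel feature tensors.
- **`generate`** — conditional generative models (C-VAE and DDPM-style
  diffusion) in two condition modes: movement-class-conditioned synthesis of
  strain trials (data augmentation) and strain-series-conditioned synthesis
  of kinematics via a self-attention condition encoder (feature
  augmentation / translation). An adversarial generator exists only as an
  interface stub.
- **`metrics`** — exact empirical 1-D Wasserstein distance and the discrete
  Fréchet time-series distance (Eiter–Mannila dynamic program), with
  set-level reductions.
- **`classify`** — CNN-LSTM, transformer-encoder and gradient-boosted-tree
  classifier heads.
- **`experiments`** — stratified / leave-one-subject-out / k-fold splits
  with a synthetic-leakage guard, the four-arm augmentation ablation grid,
  a subject-identifiability control and PCA projection.

The deep models run on a small, gradient-checked numpy reverse-mode
autodiff engine (`motiontape.nn`), so the package has no deep-learning
framework dependency.

## Test

```sh
python -m pytest -q tests/
```

The suite includes oracle tests (brute-force Fréchet coupling enumeration,
scipy Wasserstein cross-checks, point-by-point Hampel reference), property
tests (hypothesis) and `tests/test_acceptance.py`, which implements the
acceptance criteria end to end.

## CLI

All stages are exposed through one entry point:

```sh
motiontape simulate --config cohort.yaml --out raw/ --seed 1
motiontape preprocess --in raw/ --out proc/ --hampel-window 11 --hampel-sigmas 3 --exclude-sd 10
motiontape train-generator --kind cvae --condition class --in proc/ --out gen --seed 1
motiontape generate --model gen --per-class 20 --out synth/
motiontape train-generator --kind cvae --condition mt --in proc/ --out translator
motiontape translate --model translator --in proc/ --out translated/
motiontape featurize --in proc/ --out features --dtft --kinematics real
motiontape train-classifier --kind cnn_lstm --in features --out clf.pkl
motiontape score --model clf.pkl --in features --out table.csv
motiontape evaluate-generator --real proc/ --synthetic synth/ --out metrics.json
motiontape run-experiment --config experiment.yaml --out report/ --seed 1
```

Trial data lives in wide CSVs (`time_s, mt1..mt6[, ang1..ang6]`) plus a
JSON manifest; the same dialect is used for simulated and ingested cohorts.

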