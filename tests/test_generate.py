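"""Generator contracts: conditioning, determinism, shapes, translator."""

import copy

import numpy as np
import pytest

from motiontape.generate import (
    ConditionSpec,
    CVAEConfig,
    DiffusionConfig,
    TimeGAN,
    load_generator,
    sample_synthetic_mt,
    train_class_conditional,
    train_kinematics_translator,
    translate_kinematics,
)
from motiontape.metrics import series_frechet


class TestConditionSpec:
    def test_class_mode(self):
        spec = ConditionSpec(mode="class_label", class_label="flexion")
        assert spec.class_label == "flexion"

    def test_series_mode(self):
        ConditionSpec(mode="mt_series", mt_series=np.zeros((6, 10)))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "class_label"},
            {"mode": "mt_series"},
            {"mode": "class_label", "class_label": "flexion", "mt_series": np.zeros((6, 2))},
            {"mode": "banana", "class_label": "flexion"},
        ],
    )
    def test_invalid_payloads_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConditionSpec(**kwargs)


class TestConfigs:
    def test_defaults_match_tuned_values(self):
        cvae = CVAEConfig()
        assert (cvae.decoder_layers, cvae.hidden_dim) == (4, 12)
        diff = DiffusionConfig()
        assert (diff.sampling_steps, diff.hidden_dim, diff.decoder_layers) == (500, 64, 12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CVAEConfig(decoder_layers=0)
        with pytest.raises(ValueError):
            DiffusionConfig(sampling_steps=0)
        with pytest.raises(ValueError):
            DiffusionConfig(noise_schedule="bogus")


class TestClassConditional:
    def test_loss_decreases_early(self, clean_processed):
        model = train_class_conditional("cvae", clean_processed, CVAEConfig(epochs=5, seed=1))
        assert model.loss_history[0] > model.loss_history[2] > model.loss_history[4]

    def test_seeded_reproducibility(self, clean_processed, fast_cvae):
        a = train_class_conditional("cvae", clean_processed, fast_cvae)
        b = train_class_conditional("cvae", clean_processed, fast_cvae)
        sa = sample_synthetic_mt(a, "flexion", 3, seed=7)
        sb = sample_synthetic_mt(b, "flexion", 3, seed=7)
        for x, y in zip(sa, sb):
            np.testing.assert_array_equal(x.strain, y.strain)

    def test_single_class_rejected(self, clean_processed):
        only_flexion = [t for t in clean_processed if t.movement == "flexion"]
        with pytest.raises(ValueError, match="2 movement classes"):
            train_class_conditional("cvae", only_flexion, CVAEConfig(epochs=1))

    def test_inconsistent_lengths_rejected(self, clean_processed):
        broken = [copy.copy(t) for t in clean_processed[:6]]
        broken[0].strain = broken[0].strain[:, :-3]
        with pytest.raises(ValueError, match="inconsistent"):
            train_class_conditional("cvae", broken, CVAEConfig(epochs=1))

    def test_unknown_kind_rejected(self, clean_processed):
        with pytest.raises(ValueError, match="unknown generator kind"):
            train_class_conditional("gan2", clean_processed, None)

    def test_timegan_is_excluded_stub(self, clean_processed):
        with pytest.raises(NotImplementedError, match="excluded"):
            train_class_conditional("timegan", clean_processed, None)
        with pytest.raises(NotImplementedError):
            TimeGAN()


class TestSampling:
    @pytest.fixture(scope="class")
    @staticmethod
    def cvae_model(clean_processed, fast_cvae):
        return train_class_conditional("cvae", clean_processed, fast_cvae)

    def test_counts_per_class(self, cvae_model):
        samples = []
        for lab in cvae_model.labels:
            samples.extend(sample_synthetic_mt(cvae_model, lab, 20, seed=3))
        assert len(samples) == 120

    def test_zero_samples(self, cvae_model):
        assert sample_synthetic_mt(cvae_model, "flexion", 0, seed=3) == []

    def test_output_range_and_flags(self, cvae_model):
        for s in sample_synthetic_mt(cvae_model, "rotation_left", 4, seed=3):
            assert s.synthetic
            assert s.movement == "rotation_left"
            assert s.strain.shape == (6, cvae_model.n_steps)
            assert s.strain.min() >= -1.0 and s.strain.max() <= 1.0

    def test_wrong_condition_mode_rejected(self, clean_processed, fast_cvae):
        translator = train_kinematics_translator(
            "cvae", clean_processed, CVAEConfig(epochs=2, seed=0)
        )
        with pytest.raises(ValueError, match="not class-conditional"):
            sample_synthetic_mt(translator, "flexion", 1, seed=0)

    def test_diffusion_sampler_contract(self, clean_processed, fast_diffusion):
        model = train_class_conditional("diffusion", clean_processed, fast_diffusion)
        samples = sample_synthetic_mt(model, "extension", 2, seed=5)
        assert len(samples) == 2
        for s in samples:
            assert s.strain.shape == (6, model.n_steps)
            assert np.abs(s.strain).max() <= 1.0

    def test_save_load_roundtrip(self, cvae_model, tmp_path):
        cvae_model.save(tmp_path / "gen")
        loaded = load_generator(tmp_path / "gen")
        a = sample_synthetic_mt(cvae_model, "flexion", 2, seed=9)
        b = sample_synthetic_mt(loaded, "flexion", 2, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.strain, y.strain)


class TestTranslator:
    @pytest.fixture(scope="class")
    @staticmethod
    def translator(clean_processed):
        return train_kinematics_translator("cvae", clean_processed, CVAEConfig(epochs=40, seed=2))

    def test_requires_kinematics(self, clean_processed):
        broken = [copy.copy(t) for t in clean_processed[:6]]
        broken[2].kinematics = None
        with pytest.raises(ValueError, match="paired kinematics"):
            train_kinematics_translator("cvae", broken, CVAEConfig(epochs=1))

    def test_output_shape_matches_input(self, translator, clean_processed):
        out = translate_kinematics(translator, clean_processed[0].strain, seed=4)
        assert out.shape == clean_processed[0].strain.shape

    def test_fixed_seed_deterministic(self, translator, clean_processed):
        a = translate_kinematics(translator, clean_processed[0].strain, seed=4)
        b = translate_kinematics(translator, clean_processed[0].strain, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_distinct_classes_give_distinct_outputs(self, translator, clean_processed):
        flexion = next(t for t in clean_processed if t.movement == "flexion")
        lateral = next(t for t in clean_processed if t.movement == "lateral_bend_left")
        a = translate_kinematics(translator, flexion.strain, seed=4)
        b = translate_kinematics(translator, lateral.strain, seed=4)
        assert series_frechet(a, b) > 0.1  # no mode collapse

    def test_shape_mismatch_rejected(self, translator):
        with pytest.raises(ValueError, match="does not match"):
            translate_kinematics(translator, np.zeros((6, 10)), seed=0)

    def test_zeroed_condition_path_ignores_strain(self, clean_processed):
        model = train_kinematics_translator("cvae", clean_processed, CVAEConfig(epochs=2, seed=0))
        enc = model.net.cond_encoder
        enc.proj_out.weight.data[:] = 0.0
        enc.proj_out.bias.data[:] = 0.0
        a = translate_kinematics(model, clean_processed[0].strain, seed=11)
        b = translate_kinematics(model, clean_processed[-1].strain, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_shared_hyperparameters_between_modes(self, clean_processed, fast_cvae):
        gen = train_class_conditional("cvae", clean_processed, fast_cvae)
        tr = train_kinematics_translator("cvae", clean_processed, fast_cvae)
        assert gen.config == tr.config

    def test_beats_shuffled_pairing_on_heldout_loss(self, clean_processed):
        # supervised recovery: true pairings must beat label-destroyed pairings
        rng = np.random.default_rng(0)
        order = rng.permutation(len(clean_processed))
        cut = int(0.75 * len(order))
        train = [clean_processed[i] for i in order[:cut]]
        test = [clean_processed[i] for i in order[cut:]]
        true_model = train_kinematics_translator("cvae", train, CVAEConfig(epochs=50, seed=3))
        shuffled = [copy.copy(t) for t in train]
        kins = [t.kinematics for t in shuffled]
        perm = rng.permutation(len(kins))
        for t, j in zip(shuffled, perm):
            t.kinematics = kins[j]
        ctrl_model = train_kinematics_translator("cvae", shuffled, CVAEConfig(epochs=50, seed=3))

        def heldout_mse(model):
            errs = []
            for t in test:
                pred = translate_kinematics(model, t.strain, seed=20)
                errs.append(np.mean((pred - t.kinematics) ** 2))
            return np.mean(errs)

        assert heldout_mse(true_model) < heldout_mse(ctrl_model)

    def test_diffusion_translator_contract(self, clean_processed, fast_diffusion):
        model = train_kinematics_translator("diffusion", clean_processed, fast_diffusion)
        out = translate_kinematics(model, clean_processed[0].strain, seed=1)
        assert out.shape == clean_processed[0].strain.shape
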