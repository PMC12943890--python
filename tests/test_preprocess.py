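"""Processing-chain contracts: normalization arithmetic, Hampel behavior,
exclusion rule, alignment and min-max bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motiontape.preprocess import (
    PreprocessConfig,
    ProcessedTrial,
    align_and_trim,
    baseline_normalize,
    exclude_noisy_trials,
    hampel_filter,
    minmax_normalize_per_movement_trial,
    process_cohort,
)
from motiontape.simdata import CohortConfig, make_cohort


class TestBaselineNormalize:
    def test_arithmetic(self):
        np.testing.assert_allclose(
            baseline_normalize(np.array([10.0, 11.0, 9.0]), 10.0), [0.0, 0.1, -0.1]
        )

    def test_constant_equals_baseline(self):
        np.testing.assert_array_equal(baseline_normalize(np.full(5, 10.0), 10.0), np.zeros(5))

    def test_single_value(self):
        np.testing.assert_allclose(baseline_normalize(np.array([12.5]), 10.0), [0.25])

    def test_per_channel_baseline(self):
        r = np.array([[10.0, 20.0], [5.0, 10.0]])
        out = baseline_normalize(r, np.array([10.0, 5.0]))
        np.testing.assert_allclose(out, [[0.0, 1.0], [0.0, 1.0]])

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            baseline_normalize(np.ones(3), 0.0)


def brute_hampel(x, window, n_sigmas):
    """Independent point-by-point reference implementation."""
    half = window // 2
    out = x.copy()
    for i in range(len(x)):
        local = x[max(0, i - half) : i + half + 1]
        med = np.median(local)
        mad = np.median(np.abs(local - med))
        sigma = 1.4826 * mad
        dev = abs(x[i] - med)
        if (sigma > 0 and dev > n_sigmas * sigma) or (sigma == 0 and dev > 0):
            out[i] = med
    return out


class TestHampel:
    def test_constant_unchanged(self):
        x = np.full(20, 3.5)
        np.testing.assert_array_equal(hampel_filter(x, 5, 3.0), x)

    def test_spike_replaced_by_median(self):
        x = np.array([0.0, 0, 0, 100.0, 0, 0, 0])
        out = hampel_filter(x, 5, 3.0)
        np.testing.assert_array_equal(out, np.zeros(7))

    def test_linear_ramp_unchanged(self):
        x = np.linspace(0, 10, 11)
        out = hampel_filter(x, 5, 3.0)
        np.testing.assert_allclose(out, brute_hampel(x, 5, 3.0))
        np.testing.assert_allclose(out, x)

    @given(st.lists(st.floats(-10, 10), min_size=5, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce(self, values):
        x = np.array(values)
        np.testing.assert_allclose(hampel_filter(x, 5, 3.0), brute_hampel(x, 5, 3.0))

    def test_idempotent_on_spiky_signal(self, rng):
        x = np.sin(np.linspace(0, 6, 200)) + 0.05 * rng.standard_normal(200)
        x[[30, 77, 150]] += 20.0
        once = hampel_filter(x, 11, 3.0)
        twice = hampel_filter(once, 11, 3.0)
        np.testing.assert_array_equal(once, twice)
        assert np.abs(once).max() < 5.0

    def test_window_clamped_to_series(self):
        x = np.array([1.0, 2.0, 3.0, 50.0, 5.0])
        out = hampel_filter(x, 21, 3.0)
        assert out[3] != 50.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            hampel_filter(np.zeros(10), 4, 3.0)

    def test_2d_applies_per_channel(self, rng):
        x = rng.standard_normal((6, 50))
        out = hampel_filter(x, 5, 3.0)
        for c in range(6):
            np.testing.assert_allclose(out[c], hampel_filter(x[c], 5, 3.0))


class TestExclusion:
    def test_clean_cohort_keeps_all(self, tiny_cohort):
        kept, dropped, reasons = exclude_noisy_trials([mt for mt, _ in tiny_cohort])
        assert dropped == [] and reasons == []
        assert len(kept) == len(tiny_cohort)

    def test_spiked_trial_dropped_matches_direct_computation(self):
        cfg = CohortConfig(
            n_subjects=1, reps_per_movement=1, duration=6.0, noise_sd=0.02,
            spike_rate=4.0, seed=13,
        )
        trials = [mt for mt, _ in make_cohort(cfg)]
        kept, dropped, reasons = exclude_noisy_trials(trials, n_sd=10.0)
        expected_drop = []
        for t in trials:
            r = t.resistance
            z = (r - r.mean(axis=1, keepdims=True)) / r.std(axis=1, keepdims=True)
            expected_drop.append(bool((z > 10.0).any()))
        assert any(expected_drop)  # the construction actually produced spikes
        assert [t in dropped for t in trials] == expected_drop

    def test_infinite_threshold_drops_nothing(self, tiny_cohort):
        trials = [mt for mt, _ in tiny_cohort]
        kept, dropped, _ = exclude_noisy_trials(trials, n_sd=np.inf)
        assert dropped == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            exclude_noisy_trials([])


class TestAlignTrim:
    def test_trims_to_min_length(self, rng):
        s, k = align_and_trim(rng.standard_normal((6, 300)), rng.standard_normal((6, 290)))
        assert s.shape == k.shape == (6, 290)

    def test_equal_lengths_unchanged(self, rng):
        a = rng.standard_normal((6, 50))
        b = rng.standard_normal((6, 50))
        s, k = align_and_trim(a, b)
        np.testing.assert_array_equal(s, a)
        np.testing.assert_array_equal(k, b)

    def test_missing_kinematics_passthrough(self, rng):
        a = rng.standard_normal((6, 50))
        s, k = align_and_trim(a, None)
        np.testing.assert_array_equal(s, a)
        assert k is None

    def test_empty_overlap_rejected(self, rng):
        with pytest.raises(ValueError, match="empty overlap"):
            align_and_trim(rng.standard_normal((6, 10)), np.zeros((6, 0)))


def _trial(subject, movement, rep, strain, kin=None):
    return ProcessedTrial(
        subject_id=subject, movement=movement, repetition=rep, strain=strain, kinematics=kin
    )


class TestMinMax:
    def test_linear_map_endpoints_and_midpoint(self):
        strain = np.tile(np.array([2.0, 6.0, 4.0]), (6, 1))
        out = minmax_normalize_per_movement_trial([_trial("s", "flexion", 0, strain)])
        np.testing.assert_allclose(out[0].strain, np.tile([-1.0, 1.0, 0.0], (6, 1)))

    def test_constant_channel_maps_to_zero(self):
        strain = np.vstack([np.full(10, 7.0), np.random.default_rng(0).normal(size=(5, 10))])
        out = minmax_normalize_per_movement_trial([_trial("s", "flexion", 0, strain)])
        np.testing.assert_array_equal(out[0].strain[0], np.zeros(10))

    def test_group_extrema_hit_exactly(self, tiny_processed):
        groups = {}
        for t in tiny_processed:
            groups.setdefault((t.subject_id, t.movement), []).append(t)
        for members in groups.values():
            stacked = np.concatenate([m.strain for m in members], axis=1)
            np.testing.assert_allclose(stacked.min(axis=1), -1.0)
            np.testing.assert_allclose(stacked.max(axis=1), 1.0)

    def test_group_is_subject_times_movement(self, rng):
        # two subjects with very different amplitudes both span [-1, 1]
        t1 = _trial("a", "flexion", 0, rng.uniform(-0.1, 0.1, (6, 20)))
        t2 = _trial("b", "flexion", 0, rng.uniform(-10, 10, (6, 20)))
        out = minmax_normalize_per_movement_trial([t1, t2])
        for o in out:
            assert o.strain.min() == pytest.approx(-1.0)
            assert o.strain.max() == pytest.approx(1.0)

    def test_kinematics_normalized_with_own_extrema(self, rng):
        kin = rng.uniform(-90, 90, (6, 20))
        out = minmax_normalize_per_movement_trial(
            [_trial("s", "flexion", 0, rng.uniform(-1, 1, (6, 20)), kin)]
        )
        assert out[0].kinematics.min() == pytest.approx(-1.0)
        assert out[0].kinematics.max() == pytest.approx(1.0)


class TestProcessCohort:
    def test_bounds_and_provenance(self, tiny_processed):
        for t in tiny_processed:
            assert t.strain.min() >= -1.0 - 1e-12
            assert t.strain.max() <= 1.0 + 1e-12
            assert t.kinematics is not None
            steps = " -> ".join(t.provenance)
            assert "baseline_normalize" in steps
            assert "hampel" in steps
            assert "minmax" in steps

    def test_exclusion_order_flag(self, tiny_cohort):
        for flag in (True, False):
            cfg = PreprocessConfig(exclude_before_hampel=flag)
            processed, _ = process_cohort(tiny_cohort, cfg)
            assert len(processed) == len(tiny_cohort)

    def test_spiked_cohort_drops_only_spiked(self):
        cfg = CohortConfig(n_subjects=2, duration=6.0, noise_sd=0.02, spike_rate=0.5, seed=17)
        pairs = make_cohort(cfg)
        processed, reasons = process_cohort(pairs)
        assert 0 < len(reasons) < len(pairs)
        assert len(processed) == len(pairs) - len(reasons)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            process_cohort([])
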