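"""Metric oracles: brute-force Fréchet coupling enumeration, scipy W1
cross-check, and distance-axiom property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wasserstein_distance

from motiontape.metrics import (
    SeriesSet,
    discrete_frechet,
    ftsd_sets,
    series_frechet,
    wasserstein_1d,
    wasserstein_sets,
)


def brute_force_frechet(p: np.ndarray, q: np.ndarray) -> float:
    """Enumerate every monotone coupling of the index sequences."""
    n, m = len(p), len(q)

    def couplings(i, j):
        if i == n - 1 and j == m - 1:
            yield [(i, j)]
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                for rest in couplings(i + di, j + dj):
                    yield [(i, j)] + rest

    best = np.inf
    for path in couplings(0, 0):
        width = max(np.linalg.norm(p[i] - q[j]) for i, j in path)
        best = min(best, width)
    return best


class TestWasserstein1D:
    def test_identity(self, rng):
        a = rng.standard_normal(20)
        assert wasserstein_1d(a, a) == 0.0

    def test_two_point_masses(self):
        assert wasserstein_1d(np.array([0.0]), np.array([3.0])) == pytest.approx(3.0)

    def test_derived_small_case(self):
        # sorted-difference oracle: mean(|0-0|, |1-2|) = 0.5
        assert wasserstein_1d(np.array([0.0, 1.0]), np.array([0.0, 2.0])) == pytest.approx(0.5)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy(self, a, b):
        a, b = np.array(a), np.array(b)
        assert wasserstein_1d(a, b) == pytest.approx(wasserstein_distance(a, b), abs=1e-9)

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        a, b, c = np.array(a), np.array(b), np.array(c)
        assert wasserstein_1d(a, c) <= wasserstein_1d(a, b) + wasserstein_1d(b, c) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wasserstein_1d(np.array([]), np.array([1.0]))


def _set(samples, labels=None, role="real"):
    labels = labels or ["flexion"] * len(samples)
    return SeriesSet(samples=samples, labels=labels, role=role)


class TestWassersteinSets:
    def test_identical_sets_zero(self, rng):
        s = [rng.standard_normal((6, 10)) for _ in range(3)]
        assert wasserstein_sets(_set(s), _set(list(s))) == pytest.approx(0.0)

    def test_translation_property(self, rng):
        s = [rng.standard_normal((6, 10)) for _ in range(3)]
        shifted = [x + 2.5 for x in s]
        assert wasserstein_sets(_set(s), _set(shifted)) == pytest.approx(2.5)

    def test_symmetric(self, rng):
        a = _set([rng.standard_normal((6, 10)) for _ in range(3)])
        b = _set([rng.standard_normal((6, 10)) for _ in range(4)])
        assert wasserstein_sets(a, b) == pytest.approx(wasserstein_sets(b, a))

    def test_channel_mismatch_rejected(self, rng):
        a = _set([rng.standard_normal((6, 10))])
        b = _set([rng.standard_normal((5, 10))])
        with pytest.raises(ValueError, match="channel"):
            wasserstein_sets(a, b)

    def test_sample_order_invariant(self, rng):
        s = [rng.standard_normal((3, 8)) for _ in range(4)]
        a = _set(list(s))
        b = _set(s[::-1])
        ref = _set([rng.standard_normal((3, 8)) for _ in range(2)])
        assert wasserstein_sets(a, ref) == pytest.approx(wasserstein_sets(b, ref))


class TestDiscreteFrechet:
    def test_identical_sequences_zero(self, rng):
        p = rng.standard_normal((5, 2))
        assert discrete_frechet(p, p) == 0.0

    def test_derived_scalar_case(self):
        # brute-force enumeration over monotone couplings gives 4
        p = np.array([[0.0], [1.0]])
        q = np.array([[0.0], [1.0], [5.0]])
        assert brute_force_frechet(p, q) == pytest.approx(4.0)
        assert discrete_frechet(p, q) == pytest.approx(4.0)

    def test_matches_bruteforce_200_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n, m = rng.integers(1, 6), rng.integers(1, 6)
            c = rng.integers(1, 4)
            p = rng.uniform(-5, 5, size=(n, c))
            q = rng.uniform(-5, 5, size=(m, c))
            assert discrete_frechet(p, q) == pytest.approx(brute_force_frechet(p, q))

    def test_endpoint_lower_bound(self, rng):
        p = rng.standard_normal((7, 3))
        q = rng.standard_normal((9, 3))
        lower = max(np.linalg.norm(p[0] - q[0]), np.linalg.norm(p[-1] - q[-1]))
        assert discrete_frechet(p, q) >= lower - 1e-12

    def test_symmetry_and_nonnegativity(self, rng):
        p = rng.standard_normal((6, 2))
        q = rng.standard_normal((8, 2))
        d = discrete_frechet(p, q)
        assert d >= 0
        assert d == pytest.approx(discrete_frechet(q, p))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            discrete_frechet(rng.standard_normal((3, 2)), rng.standard_normal((3, 3)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discrete_frechet(np.zeros((0, 2)), np.zeros((3, 2)))


class TestFtsdSets:
    def test_subset_scores_zero(self, rng):
        real = [rng.standard_normal((6, 12)) for _ in range(4)]
        labels = ["flexion", "flexion", "extension", "extension"]
        a = SeriesSet(real, labels, role="real")
        b = SeriesSet(real[:2], labels[:2], role="synthetic")
        assert ftsd_sets(a, b) == pytest.approx(0.0)

    def test_homogeneity_under_scaling(self, rng):
        real = [rng.standard_normal((6, 12)) for _ in range(3)]
        synth = [rng.standard_normal((6, 12)) for _ in range(3)]
        a = _set(real)
        b = _set(synth, role="synthetic")
        base = ftsd_sets(a, b)
        scaled = ftsd_sets(_set([3.0 * r for r in real]), _set([3.0 * s for s in synth]))
        assert scaled == pytest.approx(3.0 * base)

    def test_single_pair_equals_frechet(self, rng):
        r = rng.standard_normal((6, 12))
        s = rng.standard_normal((6, 12))
        assert ftsd_sets(_set([r]), _set([s], role="synthetic")) == pytest.approx(
            series_frechet(s, r)
        )

    def test_missing_class_rejected(self, rng):
        a = _set([rng.standard_normal((6, 12))], labels=["flexion"])
        b = _set([rng.standard_normal((6, 12))], labels=["extension"], role="synthetic")
        with pytest.raises(ValueError, match="absent"):
            ftsd_sets(a, b)

    def test_nearest_real_is_used(self, rng):
        near = rng.standard_normal((6, 12))
        far = near + 100.0
        synth = near + 0.01
        score = ftsd_sets(_set([near, far]), _set([synth], role="synthetic"))
        assert score < 1.0  # matched against the near sample, not the far one
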