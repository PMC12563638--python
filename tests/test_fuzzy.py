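"""Fuzzy entropy: definitions, brute-force oracle equivalence, invariances."""

import numpy as np
import pytest

from fuzzent.fuzzy import (
    FuzzyEntropyConfig,
    ShortSeriesError,
    chebyshev_distance,
    embed_vectors,
    fuzzy_entropy,
    membership,
    phi,
)
from tests.helpers import naive_fuzzy_entropy, naive_phi


class TestEmbedding:
    def test_windows_are_overlapping_shifts(self):
        windows = embed_vectors([1, 2, 3, 4], 2)
        np.testing.assert_array_equal(windows, [[1, 2], [2, 3], [3, 4]])

    def test_window_count_is_n_minus_m_plus_1(self, rng):
        assert embed_vectors(rng.standard_normal(384), 2).shape == (383, 2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            embed_vectors([1, 2, 3], 2)


class TestChebyshev:
    @pytest.mark.parametrize(
        "u, v, expected", [((1, 2), (1, 2), 0.0), ((1, 5), (2, 2), 3.0)]
    )
    def test_known_pairs(self, u, v, expected):
        assert chebyshev_distance(u, v) == expected

    def test_matches_coordinate_loop_on_random_pairs(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 8))
            u, v = rng.standard_normal((2, m))
            brute = max(abs(u[k] - v[k]) for k in range(m))
            assert chebyshev_distance(u, v) == pytest.approx(brute, abs=0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chebyshev_distance([1, 2], [1, 2, 3])


class TestMembership:
    def test_zero_distance_is_full_similarity(self):
        assert membership(0.0, r=0.3, n=2) == 1.0

    def test_value_at_d_equal_r_root(self):
        # d = r**(1/n)  =>  exp(-d**n / r) = exp(-1)
        assert membership(0.5**0.5, r=0.5, n=2) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_strictly_decreasing_in_distance(self):
        assert membership(2.0, 0.5, 2) < membership(1.0, 0.5, 2)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            membership(1.0, r=0.0, n=2)


class TestPhi:
    def test_constant_series_has_full_matching(self):
        assert phi(np.full(10, 3.0), m=2, r=1.0, n=2) == pytest.approx(1.0)

    def test_matches_triple_loop(self):
        x = [1, 2, 1, 2, 1, 2]
        assert phi(np.array(x, float), m=2, r=0.5, n=2) == pytest.approx(
            naive_phi(x, m=2, r=0.5, n=2), abs=1e-12
        )

    def test_nondecreasing_in_tolerance_and_bounded(self, rng):
        x = rng.standard_normal(60)
        values = [phi(x, 2, r, 2) for r in (0.05, 0.1, 0.2, 0.5, 1.0)]
        assert all(0 < v <= 1 for v in values)
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestFuzzyEntropy:
    def test_matches_bruteforce_on_fixed_series(self):
        x = np.array([1, 2, 3, 2, 1, 2, 3, 2], float)
        res = fuzzy_entropy(x)
        assert res.fe == pytest.approx(naive_fuzzy_entropy(x), abs=1e-12)
        assert res.fe == pytest.approx(np.log(res.phi_m) - np.log(res.phi_m1))

    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(10):
            x = rng.standard_normal(int(rng.integers(10, 101)))
            assert fuzzy_entropy(x).fe == pytest.approx(
                naive_fuzzy_entropy(x), abs=1e-12
            )

    def test_constant_series_is_degenerate_zero(self):
        res = fuzzy_entropy(np.full(50, 7.0))
        assert res.fe == 0.0 and res.degenerate

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(120)
        assert fuzzy_entropy(x + 17.3).fe == pytest.approx(
            fuzzy_entropy(x).fe, abs=1e-10
        )

    def test_scale_invariance_for_linear_fuzzy_factor(self, rng):
        # with n = 1 the exponent is d/r, a degree-0 homogeneous ratio,
        # so rescaling the amplitude leaves the estimate unchanged
        x = rng.standard_normal(120)
        cfg = FuzzyEntropyConfig(n=1.0)
        for c in (0.01, 5.0, 300.0):
            assert fuzzy_entropy(c * x, cfg).fe == pytest.approx(
                fuzzy_entropy(x, cfg).fe, abs=1e-10
            )

    def test_white_noise_more_complex_than_sine(self):
        t = np.arange(384) / 128.0
        sine = np.sin(2 * np.pi * 10 * t)
        fe_sine = fuzzy_entropy(sine).fe
        wins = sum(
            fuzzy_entropy(np.random.default_rng(seed).standard_normal(384)).fe > fe_sine
            for seed in range(20)
        )
        assert wins >= 19

    def test_absolute_tolerance_overrides_relative(self, rng):
        x = rng.standard_normal(60)
        res = fuzzy_entropy(x, FuzzyEntropyConfig(r_abs=0.4))
        assert res.r == 0.4
        assert res.fe == pytest.approx(naive_fuzzy_entropy(x, r_abs=0.4), abs=1e-12)

    def test_baseline_removal_variant_differs_and_is_finite(self, rng):
        x = rng.standard_normal(80)
        plain = fuzzy_entropy(x).fe
        demeaned = fuzzy_entropy(x, FuzzyEntropyConfig(baseline_removal=True)).fe
        assert np.isfinite(demeaned) and demeaned != plain

    def test_membership_underflow_is_degenerate_zero(self):
        # an extreme outlier in a minimal series drives every pair
        # membership at dimension m+1 below the double floor; the
        # log-ratio is undefined and reported as a degenerate zero
        res = fuzzy_entropy(np.array([0.0, 0.0, 0.0, 100.0]))
        assert res.fe == 0.0 and res.degenerate
        assert res.phi_m1 == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            fuzzy_entropy(np.array([1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("bad", [dict(m=0), dict(n=0.0), dict(r_coef=-1.0)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            FuzzyEntropyConfig(**bad)
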