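import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfatigue.constants import FEATURE_NAMES
from eegfatigue.errors import AggregationError
from eegfatigue.features import (
    DEFAULT_PARAMS,
    FeatureParams,
    aggregate_event_features,
    compute_distribution_entropies,
    compute_feature_vector,
    compute_moments,
    compute_regularity_entropies,
    compute_spectral,
    compute_symbolic_entropies,
)
from oracles import (
    naive_fuzzy_entropy,
    naive_moments,
    naive_permutation_entropy,
    naive_sample_entropy,
    naive_sample_entropy_counts,
)

# Frozen 12-point series (printed here so the oracle values are stable).
PRINTED_12 = np.array([0.3, -1.2, 0.8, 0.1, -0.4, 1.5, -0.9, 0.2, 0.7, -1.1, 0.5, -0.2])


class TestMoments:
    def test_constant_segment_sentinel(self):
        mean, sd, kur, sk = compute_moments(np.full(100, 3.7))
        assert mean == pytest.approx(3.7)
        assert sd == 0.0
        assert kur == 0.0 and sk == 0.0  # flagged sentinel

    def test_alternating_plus_minus_one(self):
        x = np.tile([1.0, -1.0], 50)
        mean, sd, kur, sk = compute_moments(x)
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(1.0)
        assert sk == pytest.approx(0.0)
        assert kur == pytest.approx(1.0)

    def test_matches_oracle(self, rng):
        x = rng.normal(size=20)
        got = compute_moments(x)
        expected = naive_moments(x)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40), st.integers(0, 2**32 - 1))
    def test_oracle_property(self, values, _seed):
        got = compute_moments(np.array(values))
        expected = naive_moments(values)
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-9)


class TestRegularityEntropies:
    def test_printed_series_matches_oracle_exactly(self):
        x = PRINTED_12
        r_tol = 0.2 * float(np.std(x))
        se, fe = compute_regularity_entropies(x, DEFAULT_PARAMS)
        assert se == pytest.approx(naive_sample_entropy(x, 2, r_tol), rel=1e-12)
        assert fe == pytest.approx(naive_fuzzy_entropy(x, 2, r_tol), rel=1e-12)

    @pytest.mark.parametrize("n", [20, 35, 50])
    def test_random_series_match_oracle(self, n, rng):
        x = rng.normal(size=n)
        r_tol = 0.2 * float(np.std(x))
        se, fe = compute_regularity_entropies(x, DEFAULT_PARAMS)
        assert se == pytest.approx(naive_sample_entropy(x, 2, r_tol), rel=1e-12)
        assert fe == pytest.approx(naive_fuzzy_entropy(x, 2, r_tol), rel=1e-12)

    def test_undefined_capped(self):
        # evenly spaced ramp: template distances (>= 10) all exceed the
        # tolerance (0.2 * SD ~ 6.9), so no matches exist at either length
        x = 10.0 * np.arange(12)
        se, _ = compute_regularity_entropies(x, DEFAULT_PARAMS)
        n, m = len(x), 2
        assert se == pytest.approx(-math.log(2.0 / ((n - m - 1) * (n - m))))
        B, A = naive_sample_entropy_counts(x, 2, 0.2 * float(np.std(x)))
        assert B == 0 and A == 0  # the oracle agrees the ratio is undefined

    def test_periodic_below_noise(self):
        period = np.tile([0.0, 1.0, -1.0, 0.5], 25)
        wins = 0
        gen = np.random.default_rng(7)
        for _ in range(100):
            noise = gen.uniform(-1, 1, size=100)
            se_p, _ = compute_regularity_entropies(period + 1e-6 * gen.normal(size=100))
            se_n, _ = compute_regularity_entropies(noise)
            wins += se_p < se_n
        assert wins >= 95

    def test_constant_segment(self):
        se, fe = compute_regularity_entropies(np.full(64, 2.0))
        assert se == 0.0 and fe == 0.0


class TestSymbolicEntropies:
    def test_ramp_has_zero_pe(self):
        pe, _ = compute_symbolic_entropies(np.arange(300, dtype=float))
        assert pe == 0.0

    def test_pe_matches_oracle(self, rng):
        x = rng.normal(size=50)
        pe, _ = compute_symbolic_entropies(x, DEFAULT_PARAMS)
        assert pe == pytest.approx(naive_permutation_entropy(x, 3, 1), rel=1e-12)

    def test_pe_with_ties_matches_oracle(self, rng):
        x = rng.integers(0, 3, size=50).astype(float)  # many ties
        pe, _ = compute_symbolic_entropies(x, DEFAULT_PARAMS)
        assert pe == pytest.approx(naive_permutation_entropy(x, 3, 1), rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(min_value=30, max_value=120))
    def test_pe_bound(self, seed, n):
        x = np.random.default_rng(seed).normal(size=n)
        pe, svde = compute_symbolic_entropies(x, DEFAULT_PARAMS)
        assert 0.0 <= pe <= math.log2(math.factorial(3)) + 1e-12
        assert 0.0 <= svde <= math.log2(DEFAULT_PARAMS.svd_embed_dim) + 1e-12

    def test_pe_approaches_bound_for_long_noise(self, rng):
        x = rng.normal(size=20_000)
        pe, _ = compute_symbolic_entropies(x, DEFAULT_PARAMS)
        assert pe > 0.99 * math.log2(6)

    def test_rank_one_trajectory_zero_svde(self):
        # geometric sequence: every delay vector is a multiple of one vector
        x = 1.01 ** np.arange(100)
        _, svde = compute_symbolic_entropies(x, DEFAULT_PARAMS)
        assert svde == pytest.approx(0.0, abs=1e-8)


class TestDistributionEntropies:
    def test_uniform_over_k_bins(self):
        k = 8
        x = np.repeat(np.arange(k, dtype=float), 10)
        params = DEFAULT_PARAMS.with_(histogram_bins=k)
        sne, re, de = compute_distribution_entropies(x, params)
        assert sne == pytest.approx(math.log(k), rel=1e-12)
        assert de == pytest.approx(math.log2(k), rel=1e-12)
        assert re == pytest.approx(math.log(k), rel=1e-12)  # Renyi of uniform

    def test_renyi_to_shannon_limit(self, rng):
        x = rng.normal(size=2560)
        sne, _, _ = compute_distribution_entropies(x, DEFAULT_PARAMS)
        for alpha in (1 + 1e-4, 1 - 1e-4):
            _, re, _ = compute_distribution_entropies(
                x, DEFAULT_PARAMS.with_(renyi_alpha=alpha)
            )
            assert re == pytest.approx(sne, abs=1e-3)

    def test_constant_segment_all_zero(self):
        assert compute_distribution_entropies(np.full(100, 5.0)) == (0.0, 0.0, 0.0)


class TestSpectral:
    def test_pure_alpha_tone(self):
        t = np.arange(2560) / 256
        x = np.sin(2 * np.pi * 10.0 * t)
        delta, theta, alpha, beta, _ = compute_spectral(x, DEFAULT_PARAMS)
        assert alpha > 0.95 * (delta + theta + alpha + beta)

    def test_white_noise_near_max_spectral_entropy(self):
        gen = np.random.default_rng(11)
        # 29 one-hertz bins inside [0.4, 30) at 1 Hz Welch resolution
        max_spe = math.log(29)
        values = [compute_spectral(gen.normal(size=2560), DEFAULT_PARAMS)[4] for _ in range(20)]
        assert np.mean(values) > 0.95 * max_spe

    def test_dc_segment_zero_band_power(self):
        delta, theta, alpha, beta, spe = compute_spectral(np.full(2560, 7.0))
        assert max(delta, theta, alpha, beta) == pytest.approx(0.0, abs=1e-20)
        assert spe == 0.0

    def test_band_powers_nonnegative(self, rng):
        out = compute_spectral(rng.normal(size=2560), DEFAULT_PARAMS)
        assert min(out[:4]) >= 0.0


class TestFeatureVector:
    def test_length_16(self, rng):
        vec = compute_feature_vector(rng.normal(size=2560))
        assert vec.shape == (16,)
        assert len(FEATURE_NAMES) == 16

    def test_equals_concatenated_subops(self, rng):
        x = rng.normal(size=2560)
        vec = compute_feature_vector(x, DEFAULT_PARAMS)
        sne, re, de = compute_distribution_entropies(x, DEFAULT_PARAMS)
        pe, svde = compute_symbolic_entropies(x, DEFAULT_PARAMS)
        parts = (
            compute_moments(x)
            + compute_regularity_entropies(x, DEFAULT_PARAMS)
            + (sne, re, pe, de, svde)
            + compute_spectral(x, DEFAULT_PARAMS)
        )
        np.testing.assert_allclose(vec, np.array(parts), rtol=1e-14)

    def test_constant_segment_no_nan(self):
        vec = compute_feature_vector(np.full(2560, 1.0))
        assert np.all(np.isfinite(vec))

    def test_entropies_nonnegative(self, rng):
        vec = dict(zip(FEATURE_NAMES, compute_feature_vector(rng.normal(size=2560))))
        for name in ("SE", "FE", "SnE", "RE", "PE", "DE", "SVDE", "SpE"):
            assert vec[name] >= 0.0

    @pytest.mark.parametrize("c", [0.5, 3.0, 100.0])
    def test_scale_behaviour(self, c, rng):
        x = rng.normal(size=600)
        base = dict(zip(FEATURE_NAMES, compute_feature_vector(x)))
        scaled = dict(zip(FEATURE_NAMES, compute_feature_vector(c * x)))
        assert scaled["SD"] == pytest.approx(c * base["SD"], rel=1e-9)
        for name in ("SK", "Kur", "PE", "SE", "FE", "SnE", "DE"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-6), name


class TestAggregation:
    def test_single_vector_identity(self, rng):
        v = rng.normal(size=16)
        np.testing.assert_array_equal(aggregate_event_features([v]), v)

    def test_k_copies(self, rng):
        v = rng.normal(size=16)
        np.testing.assert_allclose(aggregate_event_features([v] * 5), v, rtol=1e-15)

    def test_matches_numpy_mean(self, rng):
        vs = [rng.normal(size=16) for _ in range(7)]
        np.testing.assert_allclose(
            aggregate_event_features(vs), np.mean(vs, axis=0), rtol=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_event_features([])


class TestParams:
    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            FeatureParams(renyi_alpha=1.0)

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            FeatureParams(histogram_bins=1)

    def test_metadata_records_log_bases(self):
        meta = DEFAULT_PARAMS.to_metadata()
        assert meta["log_bases"]["PE"] == "2"
        assert meta["log_bases"]["SnE"] == "e"


class TestFeatureTableShape:
    def test_cohort_table_shape(self, small_cohort, small_feature_table):
        # S subjects x 3 sessions x 4 channels x 6 events
        assert len(small_feature_table) == 5 * 3 * 4 * 6
        assert set(FEATURE_NAMES) <= set(small_feature_table.columns)

    def test_event_filter(self, small_cohort):
        from eegfatigue.features import extract_feature_table

        sub = extract_feature_table(
            [next(iter(small_cohort.iter_recordings()))], events=("s1",)
        )
        assert set(sub["event"]) == {"s1"}
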