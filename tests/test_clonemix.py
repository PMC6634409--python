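import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hetmix.clonemix import (
    MixParams,
    mix_expression_profile,
    mix_mutation_profile,
    sample_clone_count,
    sample_clone_weights,
    sample_purity,
    simulate_cohort,
)


class TestCloneCount:
    def test_draws_are_strictly_positive(self, rng):
        draws = sample_clone_count(rng, 6.0, size=10_000)
        assert draws.min() >= 1

    def test_mean_matches_zero_truncated_poisson(self, rng):
        # E[N | N >= 1] = lambda / (1 - exp(-lambda)) for Poisson(lambda)
        lam = 6.0
        draws = sample_clone_count(rng, lam, size=10_000)
        expected = lam / (1 - np.exp(-lam))
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se
        # and the truncation barely moves the nominal rate of 6
        assert abs(draws.mean() - 6.0) < 0.1

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_clone_count(rng, 0.0)


class TestPurity:
    def test_moments_recovered(self, rng):
        draws = sample_purity(rng, 70.0, 100.0, size=10_000)
        se_mean = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 70.0) < 3 * se_mean
        # SE of the sample variance of a Gaussian: sigma^2 * sqrt(2/(n-1))
        se_var = 100.0 * np.sqrt(2 / (draws.size - 1))
        assert abs(draws.var(ddof=1) - 100.0) < 3 * se_var
        assert draws.min() > 0 and draws.max() <= 100

    def test_zero_variance_is_degenerate(self, rng):
        assert np.all(sample_purity(rng, 70.0, 0.0, size=50) == 70.0)

    def test_negative_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_purity(rng, 70.0, -1.0)


class TestCloneWeights:
    def test_single_clone_gets_full_weight(self, rng):
        assert sample_clone_weights(rng, 1).tolist() == [1.0]

    def test_hand_normalization(self):
        class StubRng:
            def integers(self, low, high, n):
                return np.array([20, 80])

        weights = sample_clone_weights(StubRng(), 2)
        assert np.allclose(weights, [0.2, 0.8])

    def test_sizes_within_bounds_and_weights_normalized(self, rng):
        for _ in range(200):
            w, sizes = sample_clone_weights(rng, 5, return_sizes=True)
            assert sizes.min() >= 20 and sizes.max() <= 100
            assert abs(w.sum() - 1.0) < 1e-12

    def test_invalid_count_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_clone_weights(rng, 0)


class TestMixing:
    def test_pure_single_clone_is_identity(self):
        calls, mixed = mix_mutation_profile(np.array([[0.5]]), np.array([1.0]), 100.0)
        assert mixed[0] == 0.5 and calls[0] == 1

    def test_hand_mixed_vaf_above_cutoff(self):
        calls, mixed = mix_mutation_profile(
            np.array([[0.5, 0.0]]), np.array([0.2, 0.8]), 70.0
        )
        assert np.isclose(mixed[0], 0.07)
        assert calls[0] == 1

    def test_hand_mixed_vaf_below_cutoff(self):
        calls, mixed = mix_mutation_profile(np.array([[0.1]]), np.array([1.0]), 50.0, 0.03)
        # weight 0.2 via a two-clone setup gives the same arithmetic
        calls2, mixed2 = mix_mutation_profile(
            np.array([[0.1, 0.0]]), np.array([0.2, 0.8]), 50.0
        )
        assert np.isclose(mixed2[0], 0.01) and calls2[0] == 0

    def test_cutoff_is_inclusive(self):
        calls, mixed = mix_mutation_profile(np.array([[0.03]]), np.array([1.0]), 100.0)
        assert np.isclose(mixed[0], 0.03) and calls[0] == 1

    def test_hand_expression_mixture(self):
        out = mix_expression_profile(
            np.array([[100.0, 200.0]]), np.array([0.5, 0.5]), 70.0, np.array([50.0])
        )
        assert np.isclose(out[0], 120.0)

    def test_full_purity_has_no_normal_contribution(self):
        clone_expr = np.array([[10.0, 30.0], [5.0, 1.0]])
        w = np.array([0.25, 0.75])
        out = mix_expression_profile(clone_expr, w, 100.0, np.array([999.0, 999.0]))
        assert np.allclose(out, clone_expr @ w)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mix_mutation_profile(np.ones((3, 2)) * 0.5, np.array([1.0]), 70.0)
        with pytest.raises(ValueError):
            mix_expression_profile(np.ones((3, 2)), np.array([0.5, 0.5]), 70.0, np.ones(4))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_vectorized_mixing_matches_elementwise_loop(self, seed):
        g = np.random.default_rng(seed)
        n_feat, n_clones = int(g.integers(1, 50)), int(g.integers(1, 6))
        vafs = g.random((n_feat, n_clones))
        w = sample_clone_weights(g, n_clones)
        purity = float(g.uniform(1, 100))
        _, mixed = mix_mutation_profile(vafs, w, purity)
        for v in range(n_feat):
            manual = (purity / 100) * sum(w[j] * vafs[v, j] for j in range(n_clones))
            assert abs(mixed[v] - manual) <= 1e-10

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_lower_purity_never_creates_calls(self, seed):
        g = np.random.default_rng(seed)
        vafs = g.random((20, 3))
        w = sample_clone_weights(g, 3)
        hi, lo = sorted(g.uniform(1, 100, 2), reverse=True)
        calls_hi, _ = mix_mutation_profile(vafs, w, float(hi))
        calls_lo, _ = mix_mutation_profile(vafs, w, float(lo))
        assert not np.any(calls_lo > calls_hi)


class TestCohort:
    def test_cohort_size_and_truth_invariants(self, small_panel):
        cohort = simulate_cohort(small_panel, MixParams(seed=3, n_samples=40))
        assert len(cohort) == 40
        for s in cohort:
            assert s.truth_n_clones >= 1
            assert abs(s.truth_clone_weights.sum() - 1.0) < 1e-12
            assert len(s.truth_clone_lines) == s.truth_n_clones

    def test_same_seed_reproduces_cohort_exactly(self, small_panel):
        a = simulate_cohort(small_panel, MixParams(seed=5, n_samples=10))
        b = simulate_cohort(small_panel, MixParams(seed=5, n_samples=10))
        for x, y in zip(a, b):
            assert np.array_equal(x.mutation_calls, y.mutation_calls)
            assert np.array_equal(x.expression, y.expression)
            assert x.truth_purity == y.truth_purity
            assert x.truth_clone_lines == y.truth_clone_lines

    def test_empty_cohort_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate_cohort(small_panel, MixParams(seed=1, n_samples=0))

    def test_supersets_of_clones_carry_superset_variant_unions(self, small_panel, rng):
        """Before the cutoff, adding a clone can only grow the mixed-VAF support."""
        vaf = small_panel.tumor_vaf.to_numpy()
        for _ in range(50):
            k = int(rng.integers(2, 6))
            lines = rng.choice(small_panel.n_tumor_lines, size=k, replace=False)
            w_small = sample_clone_weights(rng, k - 1)
            w_big = sample_clone_weights(rng, k)
            _, mixed_small = mix_mutation_profile(vaf[:, lines[:-1]], w_small, 70.0)
            _, mixed_big = mix_mutation_profile(vaf[:, lines], w_big, 70.0)
            assert set(np.flatnonzero(mixed_small > 0)) <= set(np.flatnonzero(mixed_big > 0))

    def test_clone_count_drives_premix_support(self, small_panel):
        """The pre-cutoff support size rises with the true clone number."""
        cohort = simulate_cohort(small_panel, MixParams(seed=9, n_samples=500))
        n_clones = np.array([s.truth_n_clones for s in cohort])
        support = np.array([(s.mixed_vaf > 0).sum() for s in cohort])
        rho, p = stats.spearmanr(n_clones, support)
        assert rho > 0 and p < 1e-6
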