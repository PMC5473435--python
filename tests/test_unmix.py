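import numpy as np
import pytest
from scipy.optimize import nnls

import specfrac as sf


def _pixel_stack(grid, spectrum_values):
    """1x1 stack holding a single pixel spectrum."""
    return sf.LambdaStack(np.asarray(spectrum_values, dtype=float).reshape(-1, 1, 1),
                          grid)


NO_BG = dict(background_threshold=0.0, background_spectrum_mode="none")


class TestKLDivergence:
    def test_zero_at_agreement(self):
        obs = np.array([1.0, 5.0, 0.0])
        assert sf.kl_divergence(obs, obs.copy() + (obs == 0) * 2.0) >= 0
        assert sf.kl_divergence(obs, obs + (obs == 0) * 0.0) == pytest.approx(0.0)

    def test_zero_observed_limit(self):
        assert sf.kl_divergence([0.0], [3.5]) == pytest.approx(3.5)

    def test_direct_formula(self):
        assert sf.kl_divergence([2.0], [1.0]) == pytest.approx(2 * np.log(2) - 1)

    def test_model_zero_where_observed_positive(self):
        with pytest.raises(ValueError):
            sf.kl_divergence([1.0], [0.0])

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            o = rng.uniform(0, 10, 30)
            m = rng.uniform(0.1, 10, 30)
            assert sf.kl_divergence(o, m) >= 0


class TestPixelMasks:
    def test_boundary_conventions(self, grid17):
        counts = np.zeros((17, 1, 3))
        counts[3, 0, 1] = 50.0               # channel sum exactly 50
        counts[0, 0, 2] = 4000.0             # one channel at the threshold
        counts[1, 0, 2] = 100.0
        stack = sf.LambdaStack(counts, grid17)
        bg, sat = sf.pixel_masks(stack, sf.UnmixParams())
        assert bg[0, 0]                       # all-zero pixel is background
        assert not bg[0, 1]                   # sum == threshold is kept
        assert sat[0, 2]                      # channel >= 4000 is saturated
        assert not sat[0, 1]

    def test_masks_are_independent(self, grid17):
        counts = np.zeros((17, 1, 1))
        counts[0, 0, 0] = 5000.0
        stack = sf.LambdaStack(counts, grid17)
        bg, sat = sf.pixel_masks(stack)
        assert sat[0, 0] and not bg[0, 0]


class TestUnmixFixed:
    def test_pure_component_recovery(self, grid17, refs2):
        stack = _pixel_stack(grid17, 12.0 * refs2.matrix()[:, 0])
        maps = sf.unmix_fixed(stack, refs2,
                              sf.UnmixParams(n_iterations=200, **NO_BG))
        assert maps.values[0, 0, 0] == pytest.approx(12.0, rel=1e-3)
        assert maps.values[1, 0, 0] == pytest.approx(0.0, abs=1e-3 * 12)

    def test_two_component_mixture_against_linear_solve(self, grid17, refs2):
        S = refs2.matrix()
        y = 0.3 * S[:, 0] + 0.7 * S[:, 1]
        maps = sf.unmix_fixed(_pixel_stack(grid17, y), refs2,
                              sf.UnmixParams(n_iterations=500, **NO_BG))
        a_direct, _ = nnls(S, y)
        assert np.allclose(a_direct, [0.3, 0.7], atol=1e-9)
        assert np.allclose(maps.values[:, 0, 0], a_direct, rtol=1e-3)

    def test_below_background_threshold_zeroed_and_flagged(self, grid17, refs2):
        counts = np.zeros((17, 1, 2))
        counts[:, 0, 0] = 10.0   # sum 170 > 50 -> fit
        counts[:, 0, 1] = 1.0    # sum 17 < 50 -> background
        stack = sf.LambdaStack(counts, grid17)
        maps = sf.unmix_fixed(stack, refs2, sf.UnmixParams(n_iterations=50))
        assert maps.background_mask[0, 1]
        assert np.all(maps.values[:, 0, 1] == 0)
        assert maps.values[:, 0, 0].sum() > 0

    def test_all_background_warns_and_returns_zeros(self, grid17, refs2):
        stack = sf.LambdaStack(np.zeros((17, 4, 4)), grid17)
        with pytest.warns(UserWarning):
            maps = sf.unmix_fixed(stack, refs2)
        assert np.all(maps.values == 0)

    def test_refs_must_match_grid(self, grid29, refs2, small_cell_scene):
        stack, _ = small_cell_scene
        with pytest.raises(ValueError):
            sf.unmix_fixed(stack, refs2.resampled(grid29))

    def test_too_many_components_rejected(self):
        grid = sf.ChannelGrid(418, 9.8, 2)
        refs = sf.ReferenceSet(tuple(
            sf.gaussian_emission(430 + 5 * k, 30, grid, name=f"c{k}")
            for k in range(3)))
        stack = sf.LambdaStack(np.full((2, 2, 2), 100.0), grid)
        with pytest.raises(ValueError):
            sf.unmix_fixed(stack, refs, sf.UnmixParams(**NO_BG))

    def test_objective_monotone_on_random_stacks(self, grid17, refs2):
        rng = np.random.default_rng(5)
        for seed in range(3):
            counts = rng.poisson(rng.uniform(5, 40, (17, 12, 12))).astype(float)
            stack = sf.LambdaStack(counts, grid17)
            maps = sf.unmix_fixed(stack, refs2,
                                  sf.UnmixParams(n_iterations=40, **NO_BG),
                                  record_objective=True)
            h = np.array(maps.objective_history)
            assert np.all(np.diff(h) <= 1e-9 * np.abs(h[:-1]) + 1e-9), seed

    def test_determinism(self, small_cell_scene, refs2):
        stack, _ = small_cell_scene
        noisy = sf.add_poisson_noise(stack, seed=1)
        a = sf.unmix_fixed(noisy, refs2, sf.UnmixParams(n_iterations=20))
        b = sf.unmix_fixed(noisy, refs2, sf.UnmixParams(n_iterations=20))
        assert np.array_equal(a.values, b.values)


class TestUnmixBlind:
    def test_disjoint_pure_regions_recovered(self, grid17, refs2):
        stack, _ = sf.make_mlv_scene(grid17, 4, refs2, intensity_scale=800,
                                     seed=7, shape=(64, 64))
        noisy = sf.add_poisson_noise(stack, seed=8)
        disc, maps = sf.unmix_blind(noisy, 2, sf.UnmixParams(n_iterations=100, seed=9))
        S_true = refs2.matrix()
        S_est = disc.matrix()
        # best permutation matching by brute force
        best = -1.0
        for perm in ([0, 1], [1, 0]):
            cos = min(
                float(S_true[:, perm[k]] @ S_est[:, k]
                      / (np.linalg.norm(S_true[:, perm[k]]) * np.linalg.norm(S_est[:, k])))
                for k in range(2))
            best = max(best, cos)
        assert best >= 0.99

    def test_rank_one_identity_on_uniform_stack(self, grid17, refs2):
        spec = refs2.matrix()[:, 0] * 400.0
        counts = np.tile(spec[:, None, None], (1, 8, 8))
        stack = sf.LambdaStack(counts, grid17)
        disc, _ = sf.unmix_blind(stack, 1, sf.UnmixParams(n_iterations=60, seed=0))
        est = disc.matrix()[:, 0]
        truth = spec / spec.sum()
        assert float(est @ truth / (np.linalg.norm(est) * np.linalg.norm(truth))) > 0.9999

    def test_objective_non_increasing(self, grid17, refs2):
        rng = np.random.default_rng(11)
        for seed in range(3):
            expected = np.einsum("ck,khw->chw", refs2.matrix(),
                                 rng.uniform(50, 400, (2, 16, 16)))
            noisy = sf.add_poisson_noise(sf.LambdaStack(expected, grid17), seed=seed)
            _, maps = sf.unmix_blind(noisy, 2,
                                     sf.UnmixParams(n_iterations=50, seed=seed))
            h = np.array(maps.objective_history)
            assert np.all(np.diff(h) <= 1e-9 * np.abs(h[:-1]) + 1e-9), seed

    def test_determinism_given_seed(self, grid17, refs2):
        stack, _ = sf.make_mlv_scene(grid17, 3, refs2, seed=2, shape=(48, 48))
        noisy = sf.add_poisson_noise(stack, seed=3)
        p = sf.UnmixParams(n_iterations=30, seed=5)
        d1, m1 = sf.unmix_blind(noisy, 2, p)
        d2, m2 = sf.unmix_blind(noisy, 2, p)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(d1.matrix(), d2.matrix())

    def test_too_few_usable_pixels(self, grid17):
        stack = sf.LambdaStack(np.zeros((17, 4, 4)), grid17)
        with pytest.raises(ValueError):
            sf.unmix_blind(stack, 2, sf.UnmixParams())

    def test_component_count_bounds(self, small_cell_scene):
        stack, _ = small_cell_scene
        with pytest.raises(ValueError):
            sf.unmix_blind(stack, 0)
        with pytest.raises(ValueError):
            sf.unmix_blind(stack, 18)


class TestBackgroundSpectrum:
    def test_minimal_values_component(self, grid17, refs2):
        # constant additive background everywhere: the per-channel minimum
        # recovers it and the probe abundances stay unbiased
        stack, phantom = sf.make_mlv_scene(grid17, 2, refs2, intensity_scale=600,
                                           seed=1, shape=(48, 48),
                                           background_level=3.0)
        bspec = sf.background_spectrum(stack, np.zeros((48, 48), dtype=bool))
        assert bspec is not None and np.allclose(bspec, 3.0)
        maps = sf.unmix_fixed(stack, refs2, sf.UnmixParams(n_iterations=300))
        k = 0
        roi = phantom.true_abundances[k] > 0
        assert np.nanmedian(maps.values[k][roi]) == pytest.approx(600.0, rel=0.02)

    def test_zero_minimum_skipped(self, small_cell_scene):
        stack, _ = small_cell_scene
        assert sf.background_spectrum(stack, np.zeros(stack.counts.shape[1:],
                                                      dtype=bool)) is None


class TestSegregationBias:
    def test_zero_bias_is_inert(self, grid17, refs2, small_cell_scene):
        stack, _ = small_cell_scene
        noisy = sf.add_poisson_noise(stack, seed=2)
        base = sf.unmix_fixed(noisy, refs2, sf.UnmixParams(n_iterations=30))
        explicit = sf.unmix_fixed(noisy, refs2,
                                  sf.UnmixParams(n_iterations=30, segregation_bias=0.0))
        assert np.array_equal(base.values, explicit.values)

    def test_positive_bias_reduces_overlap(self, grid17, refs2, small_cell_scene):
        stack, _ = small_cell_scene
        noisy = sf.add_poisson_noise(stack, seed=2)
        base = sf.unmix_fixed(noisy, refs2, sf.UnmixParams(n_iterations=60))
        biased = sf.unmix_fixed(noisy, refs2,
                                sf.UnmixParams(n_iterations=60, segregation_bias=5.0))

        def overlap(m):
            a = m.values
            tot = a.sum(axis=0)
            ok = tot > 0
            f = a[:, ok] / tot[ok]
            return float((f[0] * f[1]).sum())

        assert overlap(biased) < overlap(base)
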