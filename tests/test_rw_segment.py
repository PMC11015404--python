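"""Random-walker solver: hand-solved chains, Monte-Carlo oracle, maximum
principle, weight-scheme reductions, post-processing and seeding contracts."""

import numpy as np
import pytest

from nodulewalk.errors import FormatError, SeedError
from nodulewalk.phantom import PhantomSpec, generate_phantom
from nodulewalk.rw_segment import (
    BACKGROUND,
    FOREGROUND,
    RWParams,
    auto_seeds,
    build_weights,
    build_weights_improved,
    postprocess,
    segment,
    solve_rw,
)
from nodulewalk.texture_lbp import lbp_map

from oracles import harmonic_residual, mc_absorption


def chain_seeds(n):
    seeds = np.zeros((1, n), dtype=np.int8)
    seeds[0, 0] = FOREGROUND
    seeds[0, -1] = BACKGROUND
    return seeds


class TestWeights:
    def test_constant_image_gives_uniform_weights(self):
        params = RWParams(epsilon=1e-6)
        w = build_weights(np.full((5, 5), 0.4), params)
        np.testing.assert_allclose(w.horizontal, 1 + 1e-6)
        np.testing.assert_allclose(w.vertical, 1 + 1e-6)

    def test_unit_contrast_closed_form(self):
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        w = build_weights(img, RWParams(beta=90, epsilon=1e-6))
        np.testing.assert_allclose(w.horizontal, np.exp(-90.0) + 1e-6)

    def test_pure_function(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        a = build_weights(img)
        b = build_weights(img)
        np.testing.assert_array_equal(a.horizontal, b.horizontal)

    def test_gamma_zero_reduces_to_plain_rw(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        params = RWParams(gamma=0.0)
        plain = build_weights(img, params)
        improved = build_weights_improved(img, params=params)
        np.testing.assert_array_equal(plain.horizontal, improved.horizontal)
        np.testing.assert_array_equal(plain.vertical, improved.vertical)

    def test_identical_codes_no_texture_penalty(self, rng):
        img = rng.uniform(0, 1, (6, 6))
        codes = np.full((6, 6), 37, dtype=np.uint8)
        params = RWParams(gamma=5.0)
        w = build_weights_improved(img, codes, params)
        ref = build_weights(img, params)
        np.testing.assert_allclose(w.horizontal, ref.horizontal)

    def test_opposite_codes_full_texture_penalty(self):
        """Codes 0 vs 255 have Hamming distance 1: factor exp(-gamma)."""
        img = np.full((2, 3), 0.5)
        codes = np.array([[0, 255, 0], [0, 255, 0]], dtype=np.uint8)
        params = RWParams(gamma=8.0, epsilon=1e-12)
        w = build_weights_improved(img, codes, params)
        np.testing.assert_allclose(w.horizontal, np.exp(-8.0) + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FormatError):
            build_weights_improved(np.zeros((4, 4)),
                                   np.zeros((5, 5), dtype=np.uint8))


class TestSolveRW:
    def test_three_chain_midpoint_half(self):
        w = build_weights(np.full((1, 3), 0.5))
        p = solve_rw(w, chain_seeds(3))
        np.testing.assert_allclose(p, [[1.0, 0.5, 0.0]], atol=1e-12)

    def test_four_chain_interior_thirds(self):
        """Equal-weight 1x4 chain: hand-solved 2x2 system gives 2/3, 1/3."""
        w = build_weights(np.full((1, 4), 0.5))
        p = solve_rw(w, chain_seeds(4))
        np.testing.assert_allclose(p, [[1.0, 2 / 3, 1 / 3, 0.0]], atol=1e-12)

    def test_monte_carlo_oracle_small_grid(self, rng):
        img = rng.uniform(0, 1, (6, 6))
        w = build_weights(img, RWParams(beta=10))
        seeds = np.zeros((6, 6), dtype=np.int8)
        seeds[1, 1] = FOREGROUND
        seeds[4, 4] = BACKGROUND
        p = solve_rw(w, seeds)
        p_mc = mc_absorption(w, seeds, walks_per_pixel=4000, rng=rng)
        assert np.abs(p - p_mc).max() < 0.03

    def test_harmonic_property_on_phantom(self):
        s = generate_phantom(PhantomSpec(noise_sigma=0.05, rng_seed=2))
        w = build_weights(s.image)
        seeds = auto_seeds(s.mask)
        p = solve_rw(w, seeds)
        assert harmonic_residual(p, w, seeds) < 1e-6

    def test_maximum_principle(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        seeds = np.zeros((16, 16), dtype=np.int8)
        seeds[2, 3] = FOREGROUND
        seeds[12, 13] = BACKGROUND
        p = solve_rw(build_weights(img), seeds)
        assert p.min() >= 0.0 and p.max() <= 1.0
        assert p[2, 3] == 1.0 and p[12, 13] == 0.0

    def test_label_symmetry(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        seeds = np.zeros((10, 10), dtype=np.int8)
        seeds[1, 1] = FOREGROUND
        seeds[8, 8] = BACKGROUND
        swapped = np.zeros_like(seeds)
        swapped[1, 1] = BACKGROUND
        swapped[8, 8] = FOREGROUND
        w = build_weights(img)
        np.testing.assert_allclose(solve_rw(w, seeds), 1.0 - solve_rw(w, swapped),
                                   atol=1e-9)

    def test_agrees_with_reference_random_walker(self, rng):
        """Cross-check against scikit-image's independent random-walker.

        scikit-image weights edges as exp(-beta_sk * dg^2 / (10 * std(img)))
        + 1e-10, so our Gaussian kernel reproduces it exactly with
        beta = beta_sk / (10 * std) and epsilon = 1e-10.
        """
        from skimage.segmentation import random_walker

        img = rng.uniform(0, 1, (12, 12))
        seeds = np.zeros((12, 12), dtype=np.int8)
        seeds[3, 3] = FOREGROUND
        seeds[9, 9] = BACKGROUND
        beta_sk = 130.0
        params = RWParams(beta=beta_sk / (10.0 * img.std()), epsilon=1e-10)
        p = solve_rw(build_weights(img, params), seeds)
        ref = random_walker(img, seeds.astype(int), beta=beta_sk, mode="bf",
                            return_full_prob=True)[0]
        assert np.abs(p - ref).max() < 1e-6

    def test_missing_seed_class_rejected(self):
        w = build_weights(np.zeros((4, 4)))
        seeds = np.zeros((4, 4), dtype=np.int8)
        seeds[0, 0] = FOREGROUND
        with pytest.raises(SeedError):
            solve_rw(w, seeds)


class TestPostprocess:
    def test_clean_disc_unchanged(self):
        from skimage.morphology import disk

        p = np.zeros((32, 32))
        d = disk(8).astype(bool)
        p[8:25, 8:25] = d
        seg = postprocess(p)
        np.testing.assert_array_equal(seg.mask[8:25, 8:25], d)
        assert seg.mask.sum() == d.sum()

    def test_interior_hole_filled(self):
        p = np.zeros((20, 20))
        p[5:15, 5:15] = 1.0
        p[9, 9] = 0.0
        seg = postprocess(p)
        assert seg.mask[9, 9]

    def test_largest_component_kept(self):
        p = np.zeros((30, 30))
        p[2:12, 2:12] = 1.0   # area 100
        p[20:22, 20:22] = 1.0  # area 4, far away
        seg = postprocess(p, RWParams(closing_radius=0))
        assert seg.mask[5, 5] and not seg.mask[20, 20]
        assert seg.mask.sum() == 100

    def test_empty_field_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty segmentation"):
            seg = postprocess(np.zeros((10, 10)))
        assert not seg.mask.any()


class TestAutoSeeds:
    def test_centered_disc(self, smooth_phantom):
        seeds = auto_seeds(smooth_phantom.mask, margin=12)
        r, c = np.argwhere(seeds == FOREGROUND)[0]
        assert smooth_phantom.mask[r, c]
        bg = np.argwhere(seeds == BACKGROUND)
        assert len(bg) > 0
        assert all(r0 in (0, 127) or c0 in (0, 127) for r0, c0 in bg)

    def test_crescent_centroid_fallback(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = np.mgrid[0:40, 0:40]
        outer = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        inner = (rr - 20) ** 2 + (cc - 14) ** 2 <= 11**2
        mask = outer & ~inner  # centroid falls in the bite
        seeds = auto_seeds(mask, margin=2)
        r, c = np.argwhere(seeds == FOREGROUND)[0]
        assert mask[r, c]

    def test_both_classes_always_present(self, spiculated_phantom):
        seeds = auto_seeds(spiculated_phantom.mask)
        assert (seeds == FOREGROUND).any() and (seeds == BACKGROUND).any()

    def test_foreground_disc_stays_inside_mask(self, spiculated_phantom):
        seeds = auto_seeds(spiculated_phantom.mask, fg_radius=3)
        fg = seeds == FOREGROUND
        assert fg.sum() > 1  # a disc, not a lone pixel
        assert np.all(spiculated_phantom.mask[fg])


class TestSegmentEndToEnd:
    def test_rw_equals_rwi_with_zero_gamma(self, noisy_phantom):
        seeds = auto_seeds(noisy_phantom.mask)
        params = RWParams(gamma=0.0)
        _, seg_rw = segment(noisy_phantom.image, seeds, params, method="rw")
        _, seg_rwi = segment(noisy_phantom.image, seeds, params, method="rwi")
        np.testing.assert_array_equal(seg_rw.mask, seg_rwi.mask)

    def test_rwi_median_dice_not_below_rw_on_spiculated(self):
        """Paired one-sided comparison on 50 noisy spiculated phantoms:
        the texture-fused weights must not degrade the median Dice."""
        from nodulewalk.phantom import SpecRanges, generate_dataset
        from nodulewalk.pipeline import PipelineConfig, segment_samples

        config = PipelineConfig(rng_seed=7)
        ranges = SpecRanges(noise_sigma=(0.1, 0.1),
                            benign_amplitude=(0.25, 0.45))  # all spiculated
        samples = generate_dataset(50, spec_ranges=ranges, rng_seed=7)
        rw, _ = segment_samples(samples, config, method="rw")
        rwi, _ = segment_samples(samples, config, method="rwi")
        diffs = np.array([b.dice - a.dice for a, b in zip(rw, rwi)])
        assert np.median(diffs) >= 0.0

    def test_noisy_phantom_segmented_accurately(self, noisy_phantom):
        from nodulewalk.metrics import dice
        from nodulewalk.preprocess import anisotropic_diffusion

        den = anisotropic_diffusion(noisy_phantom.image)
        seeds = auto_seeds(noisy_phantom.mask)
        _, seg = segment(den, seeds, method="rwi", lbp_codes=lbp_map(den))
        assert dice(seg.mask, noisy_phantom.mask) > 0.85
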