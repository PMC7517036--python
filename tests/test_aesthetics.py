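import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazechannel import (
    SyntheticImageSpec,
    color_region_mi,
    jensen_shannon_q,
    kolmogorov_redundancy,
    make_synthetic_image,
    ms_inverse,
    ordinal_pattern_distribution,
    palette_redundancy,
    permutation_entropy,
    q_max,
    statistical_complexity,
    to_luminance,
)
from gazechannel.aesthetics import OrdinalDistribution


class TestPaletteRedundancy:
    def test_single_color_image_has_unit_redundancy(self):
        for mode in ("luminance", "rgb"):
            img = np.full((8, 8, 3), 77, dtype=np.uint8)
            dist, mb = palette_redundancy(img, mode)
            assert dist.H == 0.0
            assert mb == 1.0

    def test_full_uniform_luminance_palette_has_zero_redundancy(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        dist, mb = palette_redundancy(img, "luminance")
        assert dist.H == pytest.approx(8.0)
        assert mb == pytest.approx(0.0)

    def test_maximum_entropy_is_24_rgb_and_8_luminance(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        assert palette_redundancy(img, "rgb")[0].Hmax == 24.0
        assert palette_redundancy(img, "luminance")[0].Hmax == 8.0

    def test_bt601_luminance_weights(self):
        rgb = np.array([[[255, 0, 0], [0, 255, 0], [0, 0, 255]]], dtype=np.uint8)
        assert to_luminance(rgb).tolist() == [[76, 150, 29]]


class TestKolmogorovRedundancy:
    def test_constant_image_compresses_almost_entirely(self):
        img = make_synthetic_image(SyntheticImageSpec("constant", 64, 64))
        assert kolmogorov_redundancy(img, mode="luminance").Mk > 0.95

    def test_iid_noise_is_nearly_incompressible(self):
        img = make_synthetic_image(SyntheticImageSpec("iid_noise", 64, 64, seed=11))
        assert kolmogorov_redundancy(img, mode="luminance").Mk < 0.10

    def test_compression_is_deterministic(self):
        img = make_synthetic_image(SyntheticImageSpec("iid_noise", 32, 32, seed=2))
        a = kolmogorov_redundancy(img, mode="luminance")
        b = kolmogorov_redundancy(img, mode="luminance")
        assert a.Mk == b.Mk and a.K_bits == b.K_bits

    def test_alternative_compressors_and_bad_name(self):
        img = make_synthetic_image(SyntheticImageSpec("gradient", 32, 32))
        for comp in ("deflate", "bz2", "lzma"):
            assert 0.0 <= kolmogorov_redundancy(img, comp, "luminance").Mk <= 1.0
        with pytest.raises(ValueError, match="unknown compressor"):
            kolmogorov_redundancy(img, "middle-out", "luminance")


class TestColorRegionChannel:
    def test_single_region_carries_no_information(self):
        img = make_synthetic_image(SyntheticImageSpec("iid_noise", 8, 8, seed=3))
        assert color_region_mi(img, [(0, 0, 8, 8)]) == pytest.approx(0.0, abs=1e-12)

    def test_pixel_level_partition_recovers_palette_entropy(self):
        img = make_synthetic_image(SyntheticImageSpec("iid_noise", 4, 4, seed=4))
        regions = [(x, y, x + 1, y + 1) for x in range(4) for y in range(4)]
        dist, _ = palette_redundancy(img, "luminance")
        assert color_region_mi(img, regions) == pytest.approx(dist.H, abs=1e-12)

    def test_two_by_two_black_white_split(self):
        img = np.array([[0, 255], [0, 255]], dtype=np.uint8)
        assert color_region_mi(img, [(0, 0, 1, 2), (1, 0, 2, 2)]) == pytest.approx(1.0)

    def test_partition_must_tile(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="tile"):
            color_region_mi(img, [(0, 0, 2, 4)])

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_refinement_never_decreases_mutual_information(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 5, size=(4, 4)).astype(np.uint8)
        coarse = [(0, 0, 2, 4), (2, 0, 4, 4)]
        fine = [(0, 0, 2, 2), (0, 2, 2, 4), (2, 0, 4, 2), (2, 2, 4, 4)]
        assert (color_region_mi(img, fine)
                >= color_region_mi(img, coarse) - 1e-12)


class TestMsInverse:
    def test_zero_ratio_returns_single_region(self):
        img = make_synthetic_image(SyntheticImageSpec("two_tone_blocks", 4, 4))
        assert ms_inverse(img, 0.0).n == 1

    def test_two_tone_image_needs_two_regions(self):
        img = make_synthetic_image(SyntheticImageSpec("two_tone_blocks", 4, 4))
        res = ms_inverse(img, 0.25)
        assert res.n == 2 and res.reached and res.ratio == pytest.approx(1.0)

    def test_constant_image_has_undefined_ratio(self):
        img = make_synthetic_image(SyntheticImageSpec("constant", 4, 4))
        with pytest.raises(ValueError, match="zero palette entropy"):
            ms_inverse(img, 0.5)

    def test_unreachable_ratio_is_flagged(self):
        img = make_synthetic_image(SyntheticImageSpec("iid_noise", 8, 8, seed=5))
        res = ms_inverse(img, 1.0, max_regions=3)
        assert not res.reached and res.n == 3 and res.ratio < 1.0

    @settings(derandomize=True, max_examples=10)
    @given(st.integers(0, 10_000))
    def test_greedy_ms_curve_is_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 6, size=(4, 4)).astype(np.uint8)
        res = ms_inverse(img, 1.0, max_regions=16)
        assert all(b >= a - 1e-12 for a, b in zip(res.curve, res.curve[1:]))
        assert res.reached  # pixel-level refinement always captures H(C)


class TestOrdinalPatterns:
    def test_constant_image_gives_identity_point_mass(self):
        img = make_synthetic_image(SyntheticImageSpec("constant", 8, 8))
        dist = ordinal_pattern_distribution(img, 2, 2)
        assert dist.n == 24
        assert dist.pattern_index.tolist() == [0]  # ties -> identity pattern
        assert dist.probs.tolist() == [1.0]
        assert dist.windows == 49

    def test_single_window_increasing_values(self):
        img = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        dist = ordinal_pattern_distribution(img, 2, 2)
        assert dist.pattern_index.tolist() == [0] and dist.windows == 1

    def test_all_24_patterns_enumerable_against_permutation_oracle(self):
        # oracle: the lexicographic list of all 4! permutations
        lex = {perm: rank for rank, perm in enumerate(permutations(range(4)))}
        seen = set()
        for vals in permutations([10, 20, 30, 40]):
            img = np.array(vals, dtype=np.uint8).reshape(2, 2)
            dist = ordinal_pattern_distribution(img, 2, 2)
            expected = lex[tuple(np.argsort(vals, kind="stable"))]
            assert dist.pattern_index.tolist() == [expected]
            seen.add(expected)
        assert seen == set(range(24))

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="smaller than the embedding"):
            ordinal_pattern_distribution(np.zeros((1, 4), dtype=np.uint8), 2, 2)

    def test_pattern_cap_enforced(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError, match="pattern cap"):
            ordinal_pattern_distribution(img, 3, 3, max_patterns=1000)


def point_mass(n=24):
    return OrdinalDistribution(2, 2, n, np.array([0]), np.array([1.0]), 1)


def uniform_dist(n=24):
    return OrdinalDistribution(2, 2, n, np.arange(n), np.full(n, 1 / n), n)


class TestEntropyComplexityPlane:
    def test_point_mass_has_zero_entropy_and_complexity(self):
        assert permutation_entropy(point_mass()) == 0.0
        assert statistical_complexity(point_mass()) == 0.0

    def test_uniform_distribution_has_unit_entropy_zero_complexity(self):
        assert permutation_entropy(uniform_dist()) == pytest.approx(1.0)
        assert statistical_complexity(uniform_dist()) == pytest.approx(0.0, abs=1e-12)

    def test_two_pattern_split_entropy(self):
        dist = OrdinalDistribution(2, 2, 24, np.array([0, 1]), np.array([0.5, 0.5]), 2)
        assert permutation_entropy(dist) == pytest.approx(math.log(2) / math.log(24))

    def test_qmax_closed_form_for_two_patterns(self):
        expected = -0.5 * (1.5 * math.log(3) + math.log(2) - 2 * math.log(4))
        assert q_max(2) == pytest.approx(expected)
        assert q_max(2) == pytest.approx(0.2158, abs=5e-5)

    def test_pe_and_complexity_are_log_base_invariant(self):
        img = make_synthetic_image(SyntheticImageSpec("iid_noise", 32, 32, seed=6))
        dist = ordinal_pattern_distribution(img)
        assert permutation_entropy(dist, base=2) == pytest.approx(
            permutation_entropy(dist, base=math.e), abs=1e-12)
        assert statistical_complexity(dist, base=2) == pytest.approx(
            statistical_complexity(dist, base=math.e), abs=1e-12)

    def test_large_noise_image_approaches_unit_entropy(self):
        img = make_synthetic_image(SyntheticImageSpec("iid_noise", 256, 256, seed=12))
        dist = ordinal_pattern_distribution(img)
        assert permutation_entropy(dist) == pytest.approx(1.0, abs=0.01)

    def test_complexity_follows_one_minus_pe_times_pe_near_order(self):
        # families mixing the uniform pattern distribution with a point
        # mass keep Q(P,U) close to (1-PE)*Qmax, so C tracks (1-PE)*PE
        n = 24
        for eps in (0.02, 0.05, 0.1, 0.15, 0.2):
            probs = np.full(n, (1 - eps) / n)
            probs[0] += eps
            dist = OrdinalDistribution(2, 2, n, np.arange(n), probs, 1)
            pe = permutation_entropy(dist)
            c = statistical_complexity(dist)
            assert c == pytest.approx((1 - pe) * pe, abs=0.005)
            assert jensen_shannon_q(dist) / q_max(n) == pytest.approx(1 - pe, abs=0.01)
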