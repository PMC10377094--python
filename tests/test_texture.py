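"""Handcrafted block: weighted-LBP histograms, Haar subband descriptors and
the 236 + 180 = 416 concatenation contract."""

from collections import Counter

import numpy as np
import pytest

from oralfuse import (
    dwt_block,
    dwt_decompose,
    handcrafted_vector,
    lbp_block,
    subband_descriptor,
    to_grayscale,
    weighted_lbp,
)
from oralfuse.texture import LBP_BINS, SUBBAND_ORDER


def _brute_uniform_pattern_sizes(gray):
    """Oracle: enumerate 8-neighbour comparison codes over interior pixels
    and return (sorted class sizes, catch-all count), where each uniform
    pattern (<= 2 circular bit transitions) is its own class.

    Valid only for images where neighbour-vs-centre comparisons are
    insensitive to the bilinear interpolation of diagonal samples (e.g.
    bright pixels on an exactly-zero background).
    """
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    H, W = gray.shape
    classes = []
    for y in range(1, H - 1):
        for x in range(1, W - 1):
            bits = tuple(int(gray[y + dy, x + dx] >= gray[y, x]) for dy, dx in offs)
            trans = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
            classes.append(bits if trans <= 2 else "catch-all")
    counts = Counter(classes)
    return sorted(counts.values(), reverse=True), counts.get("catch-all", 0)


class TestWeightedLBP:
    def test_histogram_has_59_bins_summing_to_one(self, small_image_set):
        for w in (1, 2, 3, 4):
            h = weighted_lbp(small_image_set.images[0], w)
            assert h.shape == (LBP_BINS,)
            assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_flat_texture_concentrates_in_one_bin(self):
        for w in (1, 2, 3, 4):
            h = weighted_lbp(np.full((24, 24, 3), 100, dtype=np.uint8), w)
            assert h.max() == pytest.approx(1.0)

    def test_single_bright_centre_matches_hand_enumeration(self):
        """5x5 image with one bright centre pixel: the 9 interior pattern
        counts must equal the brute-force enumeration."""
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 200
        h = weighted_lbp(img, 1)
        counts = sorted((h * 9).round().astype(int), reverse=True)
        brute_sizes, brute_catchall = _brute_uniform_pattern_sizes(img.astype(float))
        assert [c for c in counts if c > 0] == brute_sizes
        assert int(round(h[LBP_BINS - 1] * 9)) == brute_catchall

    def test_sparse_binary_image_matches_hand_enumeration(self, rng):
        """Random sparse bright-on-zero images: the multiset of per-pattern
        counts from the histogram equals the brute-force enumeration."""
        for _ in range(5):
            img = np.zeros((11, 11), dtype=np.uint8)
            # isolated bright pixels (Chebyshev distance >= 3) keep the
            # comparisons insensitive to diagonal-sample interpolation
            cells = [(r, c) for r in (1, 4, 7) for c in (1, 4, 7)]
            picks = rng.choice(len(cells), size=int(rng.integers(2, 5)), replace=False)
            for p in picks:
                img[cells[p]] = 200
            n_interior = 81
            h = weighted_lbp(img, 1)
            counts = sorted((h * n_interior).round().astype(int), reverse=True)
            brute_sizes, _ = _brute_uniform_pattern_sizes(img.astype(float))
            assert [c for c in counts if c > 0] == brute_sizes

    def test_offset_invariance(self, rng):
        base = rng.integers(30, 200, size=(40, 40, 3)).astype(np.uint8)
        shifted = (base.astype(int) + 20).astype(np.uint8)
        assert np.allclose(weighted_lbp(base, 1), weighted_lbp(shifted, 1))

    def test_invalid_weight_rejected(self, small_image_set):
        for w in (0, 5, -1):
            with pytest.raises(ValueError, match="weight"):
                weighted_lbp(small_image_set.images[0], w)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            weighted_lbp(np.zeros((2, 5, 3), dtype=np.uint8), 1)


class TestLBPBlock:
    def test_length_236_and_order(self, small_image_set):
        img = small_image_set.images[0]
        block = lbp_block(img)
        assert block.shape == (236,)
        assert np.allclose(block[:59], weighted_lbp(img, 1))
        assert np.allclose(block[59:118], weighted_lbp(img, 2))

    def test_weight_order_matters(self, small_image_set):
        img = small_image_set.images[0]
        block = lbp_block(img)
        permuted = np.concatenate([weighted_lbp(img, w) for w in (4, 3, 2, 1)])
        assert not np.allclose(block, permuted)


class TestDWT:
    def test_one_level_subbands_are_half_resolution(self, small_image_set):
        bands = dwt_decompose(small_image_set.images[0])
        assert set(bands) == set(SUBBAND_ORDER)
        for b in bands.values():
            assert b.shape == (48, 48)

    def test_224_input_gives_112_subbands(self):
        img = np.zeros((224, 224, 3), dtype=np.uint8)
        for b in dwt_decompose(img).values():
            assert b.shape == (112, 112)

    def test_constant_image_has_zero_detail_subbands(self):
        bands = dwt_decompose(np.full((32, 32, 3), 77, dtype=np.uint8))
        for name in ("vertical", "horizontal", "diagonal"):
            assert np.allclose(bands[name], 0.0)

    def test_energy_conservation(self, small_image_set):
        """Orthonormal one-level transform: total subband energy equals the
        squared norm of the grayscale input."""
        img = small_image_set.images[0]
        gray = to_grayscale(img)
        bands = dwt_decompose(img)
        total = sum(np.sum(b**2) for b in bands.values())
        assert total == pytest.approx(np.sum(gray**2), rel=1e-6)

    def test_constant_approximate_descriptor_closed_form(self):
        """Haar approximation of a constant image at level 1 is 2c, so every
        block mean of |coefficients| is exactly 2c."""
        c = 5.0
        bands = dwt_decompose(np.full((36, 20), c))
        desc = subband_descriptor(bands["approximate"])
        assert desc.shape == (45,)
        assert np.allclose(desc, 2 * c)

    def test_block_length_180_and_zero_details_for_flat_input(self):
        block = dwt_block(np.full((64, 64, 3), 10, dtype=np.uint8))
        assert block.shape == (180,)
        assert np.allclose(block[45:], 0.0)  # vertical/horizontal/diagonal

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            dwt_decompose(np.zeros((1, 10)))
        with pytest.raises(ValueError, match="block grid"):
            dwt_block(np.zeros((8, 8), dtype=np.uint8))


class TestHandcraftedVector:
    def test_length_416_with_block_boundaries(self, small_image_set):
        hv = handcrafted_vector(small_image_set.images[0])
        assert hv.values.shape == (416,)
        assert hv.block_map == [("lbp", 0, 236), ("dwt", 236, 180)]

    def test_prefix_equals_lbp_block(self, small_image_set):
        img = small_image_set.images[1]
        hv = handcrafted_vector(img)
        assert np.allclose(hv.values[:236], lbp_block(img))
        assert np.allclose(hv.values[236:], dwt_block(img))

    def test_grayscale_conversion_is_luma_weighted(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 0] = 100  # pure red
        assert np.allclose(to_grayscale(img), 29.9)
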