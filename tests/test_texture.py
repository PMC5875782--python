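"""Texture-feature extraction: oracle equivalence and invariants."""

import numpy as np
import pytest

from omentex import (
    compute_glcm,
    extract_features,
    first_order_stats,
    glcm_contrast,
    glcm_correlation,
    histogram_entropy,
    rasterize_polygon,
)
from omentex.texture import CANONICAL_DIRECTIONS

from conftest import brute_glcm, point_in_polygon_even_odd


def checkerboard(n=4):
    return (np.indices((n, n)).sum(axis=0) % 2).astype(np.uint16)


# -------------------------------------------------------------------------
# polygon rasterization
# -------------------------------------------------------------------------


class TestRasterizePolygon:
    def test_axis_aligned_square(self):
        mask = rasterize_polygon([(0, 0), (2, 0), (2, 2), (0, 2)], (4, 4))
        expected = np.zeros((4, 4), bool)
        expected[:2, :2] = True
        assert (mask == expected).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pointwise_even_odd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # star-shaped polygons are simple by construction
        n_vert = int(rng.integers(3, 10))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        rad = rng.uniform(1.5, 5.5, n_vert)
        verts = np.column_stack([6 + rad * np.cos(ang), 6 + rad * np.sin(ang)])
        mask = rasterize_polygon(verts, (12, 12))
        for r in range(12):
            for c in range(12):
                assert mask[r, c] == point_in_polygon_even_odd(c + 0.5, r + 0.5, verts)

    def test_rejects_bad_polygons(self):
        with pytest.raises(ValueError):
            rasterize_polygon([(0, 0), (1, 1)], (4, 4))
        # bow-tie self-intersection
        with pytest.raises(ValueError):
            rasterize_polygon([(0, 0), (2, 2), (2, 0), (0, 2)], (4, 4))
        # polygon entirely between pixel centers
        with pytest.raises(ValueError):
            rasterize_polygon([(0.6, 0.6), (0.9, 0.6), (0.9, 0.9), (0.6, 0.9)], (4, 4))


# -------------------------------------------------------------------------
# first-order statistics and entropy
# -------------------------------------------------------------------------


class TestFirstOrder:
    def test_hand_computed_example(self):
        img = np.array([[1, 1], [2, 3]])
        mask = np.ones((2, 2), bool)
        avg, sd, skew, kurt = first_order_stats(img, mask)
        assert avg == pytest.approx(1.75)
        assert sd == pytest.approx(np.sqrt(2.75 / 3))  # sample SD, divisor n-1

    def test_symmetric_values_have_zero_skewness(self):
        img = np.array([[1, 2, 3, 4, 5, 3]], dtype=np.uint16)
        mask = np.ones_like(img, bool)
        _, _, skew, _ = first_order_stats(img, mask)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_excess_kurtosis_near_zero(self, rng):
        vals = np.clip(np.round(rng.normal(500, 50, 200_000)), 0, 65535).astype(np.uint16)
        img = vals.reshape(400, 500)
        mask = np.ones_like(img, bool)
        _, _, skew, kurt = first_order_stats(img, mask)
        assert abs(skew) < 0.05
        assert abs(kurt) < 0.08

    def test_constant_roi_degenerate_markers(self):
        img = np.full((3, 3), 7, dtype=np.uint16)
        mask = np.ones((3, 3), bool)
        avg, sd, skew, kurt = first_order_stats(img, mask)
        assert avg == 7 and sd == 0
        assert np.isnan(skew) and np.isnan(kurt)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            first_order_stats(np.ones((2, 2), dtype=np.uint16), np.zeros((2, 2), bool))


class TestHistogramEntropy:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 5, 5, 5], 0.0),  # single bin
            ([1, 1, 2, 3], 1.5),  # -(1/2 log 1/2 + 2 * 1/4 log 1/4)
            ([1, 2, 3, 4, 5, 6, 7, 8], 3.0),  # all distinct -> log2(n)
        ],
    )
    def test_known_histograms(self, values, expected):
        img = np.asarray(values, dtype=np.uint16).reshape(1, -1)
        assert histogram_entropy(img, np.ones_like(img, bool)) == pytest.approx(expected)

    def test_entropy_bounds(self, rng):
        for _ in range(20):
            img = rng.integers(0, 30, (6, 6)).astype(np.uint16)
            mask = rng.random((6, 6)) < 0.7
            if not mask.any():
                continue
            h = histogram_entropy(img, mask)
            n = int(mask.sum())
            k = len(np.unique(img[mask]))
            assert 0.0 <= h <= np.log2(n) + 1e-12
            assert h <= np.log2(k) + 1e-12


# -------------------------------------------------------------------------
# GLCM and its functionals
# -------------------------------------------------------------------------


class TestGLCM:
    def test_constant_roi_single_cell(self):
        img = np.full((3, 3), 9, dtype=np.uint16)
        g = compute_glcm(img, np.ones((3, 3), bool))
        assert g.matrix.shape == (1, 1)
        assert g.matrix[0, 0] == pytest.approx(1.0)
        assert glcm_contrast(g) == 0.0
        assert np.isnan(glcm_correlation(g))

    def test_two_level_horizontal_example(self):
        img = np.array([[0, 0], [1, 1]], dtype=np.uint16)
        g = compute_glcm(img, np.ones((2, 2), bool), directions=[(0, 1)])
        assert g.matrix[0, 0] == pytest.approx(0.5)
        assert g.matrix[1, 1] == pytest.approx(0.5)
        assert g.matrix[0, 1] == 0 and g.matrix[1, 0] == 0

    def test_checkerboard_functionals(self):
        g = compute_glcm(checkerboard(4), np.ones((4, 4), bool), directions=[(0, 1)])
        assert glcm_contrast(g) == pytest.approx(1.0)
        assert glcm_correlation(g, "standard") == pytest.approx(-1.0)
        assert glcm_correlation(g, "paper_scale") == pytest.approx(-4.0)

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_pair_enumeration(self, seed, symmetric):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 9, 2))
        img = rng.integers(0, 5, shape).astype(np.uint16)
        mask = rng.random(shape) < 0.8
        distance = int(rng.integers(1, 3))
        try:
            g = compute_glcm(img, mask, distance=distance, symmetric=symmetric)
        except ValueError:
            # no valid pairs: the oracle must agree that none exist
            assert not brute_glcm(img, mask, distance, CANONICAL_DIRECTIONS, symmetric)
            return
        oracle = brute_glcm(img, mask, distance, CANONICAL_DIRECTIONS, symmetric)
        total = sum(oracle.values())
        for i, li in enumerate(g.levels):
            for j, lj in enumerate(g.levels):
                expected = oracle.get((int(li), int(lj)), 0) / total
                assert g.matrix[i, j] == pytest.approx(expected, abs=1e-10)
        # contrast / correlation against direct enumeration over pairs
        pairs = np.array([[a, b] for (a, b), k in oracle.items() for _ in range(k)], dtype=float)
        assert glcm_contrast(g) == pytest.approx(np.mean((pairs[:, 0] - pairs[:, 1]) ** 2), abs=1e-10)
        if pairs[:, 0].std() > 0 and pairs[:, 1].std() > 0:
            r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
            assert glcm_correlation(g, "standard") == pytest.approx(r, abs=1e-10)

    def test_probabilities_sum_to_one_and_symmetry(self, rng):
        img = rng.integers(0, 10, (8, 8)).astype(np.uint16)
        g = compute_glcm(img, np.ones((8, 8), bool), symmetric=True)
        assert g.matrix.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(g.matrix, g.matrix.T)

    def test_scattered_single_pixels_raise(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[4, 4] = True
        with pytest.raises(ValueError):
            compute_glcm(np.ones((5, 5), dtype=np.uint16), mask)


class TestIntensityInvariance:
    """Contrast/entropy shift-invariant; standard correlation affine-invariant."""

    def test_constant_shift(self, rng):
        img = rng.integers(10, 40, (7, 7)).astype(np.int64)
        mask = np.ones((7, 7), bool)
        g1 = compute_glcm(img, mask)
        g2 = compute_glcm(img + 100, mask)
        assert glcm_contrast(g1) == pytest.approx(glcm_contrast(g2), abs=1e-10)
        assert histogram_entropy(img, mask) == pytest.approx(histogram_entropy(img + 100, mask))
        assert glcm_correlation(g1, "standard") == pytest.approx(
            glcm_correlation(g2, "standard"), abs=1e-10
        )
        # the variance-product variant is *not* scale-invariant
        g3 = compute_glcm(img * 3, mask)
        assert glcm_correlation(g1, "standard") == pytest.approx(
            glcm_correlation(g3, "standard"), abs=1e-10
        )
        assert glcm_correlation(g3, "paper_scale") != pytest.approx(
            glcm_correlation(g1, "paper_scale"), rel=0.01
        )


class TestExtractFeatures:
    def test_constant_image_degenerate_features(self):
        img = np.full((20, 20), 920, dtype=np.uint16)
        verts = [(2, 2), (15, 2), (15, 15), (2, 15)]
        fs = extract_features(img, verts)
        assert fs.average == 920 and fs.std_dev == 0
        assert fs.entropy == 0 and fs.contrast == 0
        assert np.isnan(fs.skewness) and np.isnan(fs.kurtosis)
        assert np.isnan(fs.correlation_standard)

    def test_deterministic_for_fixed_inputs(self, rng):
        img = rng.integers(800, 1100, (32, 32)).astype(np.uint16)
        verts = [(3, 3), (28, 5), (25, 28), (4, 25)]
        a = extract_features(img, verts)
        b = extract_features(img, verts)
        assert a == b

    def test_mask_input_equivalent_to_polygon(self, rng):
        img = rng.integers(800, 1100, (32, 32)).astype(np.uint16)
        verts = [(3, 3), (28, 5), (25, 28), (4, 25)]
        mask = rasterize_polygon(verts, img.shape)
        assert extract_features(img, verts).as_dict() == extract_features(img, mask).as_dict()
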