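"""DOG ganglion layer: kernels, responses, thresholding, binarization."""
import numpy as np
import pytest

from v1colmap.ganglion import (DOGParams, binarize, compute_threshold,
                               gc_response, image_to_gc, make_dog_kernel,
                               pathway_kernel)
from v1colmap.stimuli import bar_image, rotate90
from v1colmap.tiling import build_tiling, generate_index_matrices


def brute_force_gc(field_2d, sigma_cen, sigma_sur, kernel_side=3):
    """Independent oracle: direct double-loop centre-surround summation.

    For every cell, average photoreceptor values under the two discrete
    Gaussians, each renormalized over the cells that actually fall inside
    the field, and subtract.
    """
    half = kernel_side // 2
    ax = np.arange(-half, half + 1)

    def gauss_weights(sigma):
        w = np.array([[np.exp(-(x * x + y * y) / (2 * sigma * sigma))
                       for x in ax] for y in ax])
        return w / w.sum()

    wc, ws = gauss_weights(sigma_cen), gauss_weights(sigma_sur)
    h, w = field_2d.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc_c = acc_s = mass_c = mass_s = 0.0
            for dy in range(-half, half + 1):
                for dx in range(-half, half + 1):
                    rr, cc = r + dy, c + dx
                    if 0 <= rr < h and 0 <= cc < w:
                        p = field_2d[rr, cc]
                        acc_c += p * wc[dy + half, dx + half]
                        acc_s += p * ws[dy + half, dx + half]
                        mass_c += wc[dy + half, dx + half]
                        mass_s += ws[dy + half, dx + half]
            out[r, c] = acc_c / mass_c - acc_s / mass_s
    return out


class TestKernel:
    def test_kernel_sums_to_zero(self):
        k = make_dog_kernel(0.5, 1.0, 3)
        assert abs(k.sum()) < 1e-12
        k5 = make_dog_kernel(0.8, 2.0, 5)
        assert abs(k5.sum()) < 1e-12

    def test_tiny_centre_sigma_approaches_delta_minus_surround(self):
        k = make_dog_kernel(1e-3, 1.0, 3)
        g = np.exp(-(np.arange(-1, 2)[:, None] ** 2 +
                     np.arange(-1, 2)[None, :] ** 2) / 2.0)
        g /= g.sum()
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        np.testing.assert_allclose(k, delta - g, atol=1e-9)

    def test_centre_entry_matches_direct_evaluation(self):
        k = make_dog_kernel(0.5, 1.0, 3)
        ax = np.arange(-1, 2)
        r2 = ax[:, None] ** 2 + ax[None, :] ** 2
        gc = np.exp(-r2 / (2 * 0.25))
        gs = np.exp(-r2 / 2.0)
        expected = gc[1, 1] / gc.sum() - gs[1, 1] / gs.sum()
        assert k[1, 1] == pytest.approx(expected, abs=1e-15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_dog_kernel(1.0, 0.5, 3)
        with pytest.raises(ValueError):
            make_dog_kernel(0.5, 1.0, 4)

    def test_off_kernel_uses_off_sigma_pair(self):
        p = DOGParams(sigma_cen_off=0.4, sigma_sur_off=1.3)
        np.testing.assert_allclose(pathway_kernel(p, "off"),
                                   make_dog_kernel(0.4, 1.3, 3))


class TestResponse:
    def test_constant_field_gives_zero_response(self, dog_params):
        rf = np.full(81, 200, dtype=np.uint8)
        np.testing.assert_allclose(gc_response(rf, dog_params), 0.0, atol=1e-12)

    def test_impulse_response_is_kernel(self, dog_params):
        rf = np.zeros(81)
        rf[4 * 9 + 4] = 255.0
        resp = gc_response(rf, dog_params).reshape(9, 9)
        k = pathway_kernel(dog_params)
        np.testing.assert_allclose(resp[3:6, 3:6], k, atol=1e-12)
        assert abs(resp[0, 0]) < 1e-15

    def test_step_edge_matches_brute_force_summation(self, dog_params):
        field = np.zeros((9, 9))
        field[:, 5:] = 255.0
        resp = gc_response(field.ravel(), dog_params).reshape(9, 9)
        oracle = brute_force_gc(field / 255.0, dog_params.sigma_cen_on,
                                dog_params.sigma_sur_on)
        np.testing.assert_allclose(resp, oracle, atol=1e-10)

    def test_linearity_of_graded_path(self, dog_params, rng):
        a = rng.uniform(0, 255, 81)
        b = rng.uniform(0, 255, 81)
        lhs = gc_response(0.3 * a + 0.6 * b, dog_params)
        rhs = 0.3 * gc_response(a, dog_params) + 0.6 * gc_response(b, dog_params)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_rotating_field_rotates_response(self, dog_params, rng):
        field = rng.integers(0, 256, (9, 9)).astype(float)
        r1 = gc_response(field.ravel(), dog_params).reshape(9, 9)
        r2 = gc_response(rotate90(field, 1).ravel(), dog_params).reshape(9, 9)
        np.testing.assert_allclose(r2, np.rot90(r1), atol=1e-12)

    def test_non_square_length_rejected(self, dog_params):
        with pytest.raises(ValueError):
            gc_response(np.zeros(80), dog_params)


class TestThreshold:
    def test_unit_span_at_alpha_0p2(self):
        assert compute_threshold(np.array([0.0, 0.3, 1.0]), 0.2) == pytest.approx(0.2)

    def test_constant_responses_give_zero(self):
        assert compute_threshold(np.full(10, 0.7), 0.2) == 0.0

    def test_mixed_sign_span(self):
        assert compute_threshold(np.array([-0.3, 0.1, 0.5]), 0.2) == \
            pytest.approx(0.16)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(np.array([]), 0.2)


class TestBinarize:
    def test_strict_inequality_at_threshold(self):
        assert (binarize(np.zeros(5), 0.0) == 0).all()

    def test_direct_comparison(self):
        np.testing.assert_array_equal(binarize(np.array([0.3, 0.1]), 0.2), [1, 0])

    def test_off_pathway_fires_on_negative_response(self):
        g = np.array([0.5, -0.5, 0.0])
        np.testing.assert_array_equal(binarize(g, 0.2, "off"), [0, 1, 0])

    def test_impulse_fired_support_is_positive_kernel_support(self, dog_params):
        rf = np.zeros(81)
        rf[4 * 9 + 4] = 255.0
        graded = gc_response(rf, dog_params)
        fired = binarize(graded, 0.1)
        k = pathway_kernel(dog_params)
        expected = np.zeros((9, 9), dtype=np.uint8)
        expected[3:6, 3:6] = (k > 0.1).astype(np.uint8)
        np.testing.assert_array_equal(fired.reshape(9, 9), expected)


class TestImagePipeline:
    def test_uniform_image_never_fires(self, small_tiling, dog_params):
        img = np.full((33, 33), 77, dtype=np.uint8)
        gc = image_to_gc(img, small_tiling, dog_params)
        assert gc.fired.sum() == 0

    def test_convolution_path_equals_brute_force_on_all_fields(self, rng,
                                                               dog_params):
        t = build_tiling(33, 33)
        idx = generate_index_matrices(t)
        img = rng.integers(0, 256, (33, 33), dtype=np.uint8)
        gc = image_to_gc(img, t, dog_params, idx)
        for f in range(t.n_fields):
            r0, c0 = t.field_origin(f)
            patch = img[r0:r0 + 9, c0:c0 + 9].astype(float) / 255.0
            oracle = brute_force_gc(patch, dog_params.sigma_cen_on,
                                    dog_params.sigma_sur_on)
            np.testing.assert_allclose(gc.graded[f].reshape(9, 9), oracle,
                                       atol=1e-10)

    def test_field_scope_threshold_is_per_field(self, small_tiling):
        params = DOGParams(threshold_scope="field")
        img = bar_image(33, 33, 0.0)
        gc = image_to_gc(img, small_tiling, params)
        assert np.ndim(gc.threshold) == 1
        assert gc.threshold.shape == (small_tiling.n_fields,)
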