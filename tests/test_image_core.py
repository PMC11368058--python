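"""Core image/mask operations: normalization, flips, dilation,
compositing and patch bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudohealthy import (GraySlice, LesionMask, ValidationError, composite,
                           dilate_mask, extract_patches, horizontal_flip,
                           normalize_intensity, scatter_patches)
from pseudohealthy.image import disk_structure, downsample_mask


class TestNormalize:
    def test_linear_map_endpoints_and_midpoint(self):
        raw = np.array([[0.0, 127.5], [255.0, 64.0]])
        out = normalize_intensity(raw).pixels
        assert out[0, 0] == pytest.approx(-1.0)
        assert out[1, 0] == pytest.approx(1.0)
        assert out[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_constant_image_maps_to_background(self):
        out = normalize_intensity(np.full((5, 5), 7.3)).pixels
        assert np.all(out == -1.0)

    def test_two_point_map(self):
        out = normalize_intensity(np.array([[-3.0, 1.0]])).pixels
        assert out[0, 0] == -1.0 and out[0, 1] == 1.0

    def test_idempotent_and_order_preserving(self, rng):
        raw = rng.normal(size=(16, 16)) * 40 + 10
        once = normalize_intensity(raw).pixels
        twice = normalize_intensity(once).pixels
        np.testing.assert_allclose(twice, once, atol=1e-6)
        flat_r, flat_o = raw.ravel(), once.ravel()
        order = np.argsort(flat_r)
        assert np.all(np.diff(flat_o[order]) >= -1e-7)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            normalize_intensity(np.array([[0.0, np.nan]]))


class TestFlip:
    def test_involution(self, rng):
        img = GraySlice(rng.uniform(-1, 1, size=(8, 10)).astype(np.float32))
        np.testing.assert_array_equal(horizontal_flip(horizontal_flip(img)).pixels, img.pixels)

    def test_symmetric_phantom_is_fixed_point(self):
        from pseudohealthy import PhantomSpec, make_healthy_phantom

        img = make_healthy_phantom(PhantomSpec(size=32, noise_sigma=0.0, seed=4))
        np.testing.assert_array_equal(horizontal_flip(img).pixels, img.pixels)

    def test_two_by_two_definition(self):
        img = GraySlice(np.array([[0.1, 0.2], [0.3, 0.4]], dtype=np.float32))
        np.testing.assert_allclose(horizontal_flip(img).pixels,
                                   [[0.2, 0.1], [0.4, 0.3]])


class TestDilate:
    def test_radius_zero_is_identity(self, mask64):
        out = dilate_mask(mask64, 0.0)
        np.testing.assert_array_equal(out.pixels, mask64.pixels)

    def test_single_pixel_matches_lattice_count(self):
        # oracle: brute-force count of lattice points with dx^2+dy^2 <= r^2
        r = 5.0
        expected = sum(1 for dy in range(-6, 7) for dx in range(-6, 7)
                       if dx * dx + dy * dy <= r * r)
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[10, 10] = 1
        out = dilate_mask(LesionMask(mask, spacing=1.0), 5.0)
        assert int(out.pixels.sum()) == expected == 81

    def test_saturated_mask_is_idempotent(self):
        full = LesionMask(np.ones((9, 9), dtype=np.uint8))
        np.testing.assert_array_equal(dilate_mask(full, 3.0).pixels, full.pixels)

    def test_monotone_and_extensive(self, rng):
        for _ in range(5):
            a = (rng.random((20, 20)) < 0.1).astype(np.uint8)
            b = np.clip(a + (rng.random((20, 20)) < 0.1), 0, 1).astype(np.uint8)
            da = dilate_mask(LesionMask(a), 2.0).pixels
            db = dilate_mask(LesionMask(b), 2.0).pixels
            assert np.all(da >= a)            # extensive
            assert np.all(db >= da * (b >= a))  # monotone on supersets

    def test_negative_radius_rejected(self, mask64):
        with pytest.raises(ValidationError):
            dilate_mask(mask64, -1.0)


class TestComposite:
    def test_empty_mask_returns_original(self, phantom64, rng):
        gen = GraySlice(rng.uniform(-1, 1, (64, 64)).astype(np.float32))
        empty = LesionMask(np.zeros((64, 64), dtype=np.uint8))
        np.testing.assert_array_equal(
            composite(phantom64, gen, empty).pixels, phantom64.pixels)

    def test_full_mask_returns_generated(self, phantom64, rng):
        gen = GraySlice(rng.uniform(-1, 1, (64, 64)).astype(np.float32))
        full = LesionMask(np.ones((64, 64), dtype=np.uint8))
        np.testing.assert_array_equal(composite(phantom64, gen, full).pixels, gen.pixels)

    def test_original_preserved_outside_mask_bit_exact(self, phantom64, mask64, rng):
        gen = GraySlice(rng.uniform(-1, 1, (64, 64)).astype(np.float32))
        out = composite(phantom64, gen, mask64)
        keep = ~mask64.pixels.astype(bool)
        np.testing.assert_array_equal(out.pixels[keep], phantom64.pixels[keep])

    def test_shape_mismatch_rejected(self, phantom64):
        with pytest.raises(ValidationError):
            composite(phantom64, GraySlice(np.zeros((8, 8), dtype=np.float32)),
                      LesionMask(np.zeros((64, 64), dtype=np.uint8)))


class TestPatches:
    def test_default_resolution_gives_256_patches(self):
        mask = LesionMask(np.zeros((256, 256), dtype=np.uint8))
        ps = extract_patches(np.zeros((256, 256), dtype=np.float32), 16, mask)
        assert ps.n_patches == 256

    def test_small_map_patch_count(self):
        mask = LesionMask(np.zeros((32, 32), dtype=np.uint8))
        assert extract_patches(np.zeros((32, 32)), 16, mask).n_patches == 4

    def test_nondivisible_dims_rejected(self):
        mask = LesionMask(np.zeros((250, 250), dtype=np.uint8))
        with pytest.raises(ValidationError):
            extract_patches(np.zeros((250, 250)), 16, mask)

    def test_scatter_roundtrip(self, rng):
        feat = rng.normal(size=(3, 32, 32)).astype(np.float32)
        mask = LesionMask((rng.random((32, 32)) < 0.3).astype(np.uint8))
        ps = extract_patches(feat, 8, mask)
        np.testing.assert_array_equal(scatter_patches(ps), feat)

    def test_inside_label_rule_any_pixel(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[0, 0] = 1  # single pixel marks its whole patch inside
        ps = extract_patches(np.zeros((32, 32)), 16, LesionMask(mask))
        assert list(ps.inside) == [True, False, False, False]
        assert ps.n_outside == 3

    @given(st.integers(0, 2 ** 20))
    @settings(max_examples=20, deadline=None)
    def test_downsample_mask_is_block_any(self, seed):
        r = np.random.default_rng(seed)
        m = (r.random((16, 16)) < 0.2).astype(np.uint8)
        coarse = downsample_mask(LesionMask(m), 4).pixels
        expected = m.reshape(4, 4, 4, 4).max(axis=(1, 3))
        np.testing.assert_array_equal(coarse, expected)


def test_disk_structure_is_symmetric():
    s = disk_structure(3.5)
    np.testing.assert_array_equal(s, s[::-1])
    np.testing.assert_array_equal(s, s[:, ::-1])
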