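"""ROI stage: dilation, cropping, restoration, warping, registration."""

import warnings

import numpy as np
import pytest

from hipposeg import (PhantomSpec, RoiConfig, SpatialTransform, Volume,
                      binarize_and_dilate, extract_roi, generate_phantom,
                      normalize_intensity, register_affine, register_nonlinear,
                      resample_through, restore_to_full, warp_probability_map)
from hipposeg.atlas import RoiCrop
from hipposeg.phantom import _draw_subject_affine, _rasterize


def brute_force_dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Independent oracle: per-voxel max over the 3x3x3 neighbourhood."""
    out = mask.astype(bool).copy()
    for _ in range(iterations):
        prev = out
        out = np.zeros_like(prev)
        idx = np.argwhere(prev)
        for x, y, z in idx:
            xs = slice(max(x - 1, 0), min(x + 2, prev.shape[0]))
            ys = slice(max(y - 1, 0), min(y + 2, prev.shape[1]))
            zs = slice(max(z - 1, 0), min(z + 2, prev.shape[2]))
            out[xs, ys, zs] = True
    return out


class TestBinarizeAndDilate:
    def test_single_voxel_two_dilations_gives_5_cube(self):
        prob = np.zeros((9, 9, 9))
        prob[4, 4, 4] = 0.7
        out = binarize_and_dilate(Volume(prob), RoiConfig(dilation_voxels=2))
        assert out.data.sum() == 125
        assert np.array_equal(out.data.astype(bool),
                              brute_force_dilate(prob > 0, 2))

    def test_all_ones_is_fixed_point(self):
        out = binarize_and_dilate(Volume(np.ones((6, 6, 6))), RoiConfig())
        assert np.all(out.data == 1)

    def test_zero_dilations_is_binarization(self, rng):
        prob = rng.random((8, 8, 8)) * (rng.random((8, 8, 8)) > 0.7)
        out = binarize_and_dilate(Volume(prob), RoiConfig(dilation_voxels=0))
        assert np.array_equal(out.data.astype(bool), prob > 1e-6)

    def test_empty_support_errors(self):
        with pytest.raises(ValueError, match="empty"):
            binarize_and_dilate(Volume(np.zeros((5, 5, 5))), RoiConfig())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        prob = (rng.random((20, 20, 20)) > 0.95).astype(float)
        if not prob.any():
            prob[10, 10, 10] = 1.0
        for it in (1, 2):
            out = binarize_and_dilate(Volume(prob), RoiConfig(dilation_voxels=it))
            assert np.array_equal(out.data.astype(bool),
                                  brute_force_dilate(prob > 0, it))

    def test_dilation_monotone_in_iterations(self, rng):
        prob = (rng.random((15, 15, 15)) > 0.97).astype(float)
        prob[7, 7, 7] = 1.0
        prev = binarize_and_dilate(Volume(prob), RoiConfig(dilation_voxels=0)).data
        for k in (1, 2, 3):
            cur = binarize_and_dilate(Volume(prob), RoiConfig(dilation_voxels=k)).data
            assert np.all(cur[prev > 0] == 1)
            prev = cur


class TestExtractRestore:
    def _mask(self, shape, lo, hi):
        m = np.zeros(shape, dtype=bool)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return m

    def test_margin_arithmetic(self, rng):
        img = Volume(rng.normal(size=(64, 64, 64)))
        mask = self._mask((64, 64, 64), (10, 10, 10), (20, 20, 20))
        crop = extract_roi(img, mask, RoiConfig(margin_voxels=2), "left")
        assert crop.bbox_lo == (8, 8, 8)
        assert crop.image.shape == (14, 14, 14)
        assert np.array_equal(crop.image.data, img.data[8:22, 8:22, 8:22])

    def test_mask_touching_edge_clips(self, rng):
        img = Volume(rng.normal(size=(32, 32, 32)))
        mask = self._mask((32, 32, 32), (0, 0, 0), (5, 5, 5))
        crop = extract_roi(img, mask, RoiConfig(margin_voxels=2), "right")
        assert crop.bbox_lo == (0, 0, 0)
        assert crop.image.shape == (7, 7, 7)

    def test_zero_margin_is_tight_bbox(self, rng):
        img = Volume(rng.normal(size=(32, 32, 32)))
        mask = self._mask((32, 32, 32), (5, 6, 7), (9, 11, 13))
        crop = extract_roi(img, mask, RoiConfig(margin_voxels=0), "left")
        assert crop.bbox_lo == (5, 6, 7)
        assert crop.image.shape == (4, 5, 6)

    def test_empty_mask_errors(self, rng):
        img = Volume(rng.normal(size=(16, 16, 16)))
        with pytest.raises(ValueError, match="empty"):
            extract_roi(img, np.zeros((16, 16, 16), bool), RoiConfig(), "left")

    def test_extract_then_restore_round_trip(self, rng):
        img = Volume(rng.normal(size=(40, 40, 40)))
        mask = self._mask((40, 40, 40), (12, 14, 16), (22, 26, 30))
        crop = extract_roi(img, mask, RoiConfig(), "left")
        restored = restore_to_full(crop.dilated_mask, crop)
        assert np.array_equal(restored > 0, mask)
        assert set(np.unique(restored)) <= {0, 1}

    def test_restore_right_uses_label_2(self, rng):
        img = Volume(rng.normal(size=(30, 30, 30)))
        mask = self._mask((30, 30, 30), (10, 10, 10), (15, 15, 15))
        crop = extract_roi(img, mask, RoiConfig(), "right")
        restored = restore_to_full(crop.dilated_mask, crop)
        assert set(np.unique(restored)) == {0, 2}

    def test_restore_all_zero(self, rng):
        img = Volume(rng.normal(size=(30, 30, 30)))
        mask = self._mask((30, 30, 30), (10, 10, 10), (15, 15, 15))
        crop = extract_roi(img, mask, RoiConfig(), "left")
        assert restore_to_full(np.zeros(crop.image.shape), crop).sum() == 0

    def test_restore_shape_mismatch_errors(self, rng):
        img = Volume(rng.normal(size=(30, 30, 30)))
        mask = self._mask((30, 30, 30), (10, 10, 10), (15, 15, 15))
        crop = extract_roi(img, mask, RoiConfig(), "left")
        with pytest.raises(ValueError, match="shape"):
            restore_to_full(np.zeros((3, 3, 3)), crop)


class TestWarpProbabilityMap:
    def test_identity_same_grid_is_identity(self, rng):
        prob = np.clip(rng.random((16, 16, 16)), 0, 1)
        prob[prob < 0.5] = 0.0
        v = Volume(prob)
        out = warp_probability_map(v, SpatialTransform(np.eye(4)), v)
        assert np.allclose(out.data, np.where(prob < 1e-6, 0, prob), atol=1e-6)

    def test_zero_map_stays_zero(self):
        v = Volume(np.zeros((12, 12, 12)))
        t = SpatialTransform(np.diag([1.0, 1.0, 1.0, 1.0]))
        out = warp_probability_map(v, t, v)
        assert np.all(out.data == 0)

    def test_integer_translation_matches_array_shift(self):
        prob = np.zeros((20, 20, 20))
        prob[8:12, 8:12, 8:12] = 1.0
        v = Volume(prob)
        t = np.eye(4)
        t[:3, 3] = [3.0, -2.0, 1.0]  # resampling map: out(x) = in(x + t)
        out = warp_probability_map(v, SpatialTransform(t), v)
        expected = np.zeros_like(prob)
        expected[5:9, 10:14, 7:11] = 1.0
        interior = np.zeros_like(prob, dtype=bool)
        interior[2:-2, 2:-2, 2:-2] = True
        assert np.allclose(out.data[interior], expected[interior], atol=1e-3)

    def test_values_clamped_to_unit_interval(self, rng):
        prob = np.clip(rng.random((14, 14, 14)), 0, 1)
        v = Volume(prob)
        t = np.eye(4)
        t[:3, 3] = [0.4, 0.2, -0.3]
        out = warp_probability_map(v, SpatialTransform(t), v)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0


SMALL_SPEC = PhantomSpec(shape=(56, 56, 56))


def _make_subject(seed):
    r = np.random.default_rng(seed)
    A = _draw_subject_affine(SMALL_SPEC, r)
    img, _ = _rasterize(SMALL_SPEC, A, r.normal(size=9), r)
    return A, normalize_intensity(Volume(img, SMALL_SPEC.grid_affine()))


class TestRegistration:
    def test_constant_image_errors(self):
        v = Volume(np.zeros((8, 8, 8)))
        w = Volume(np.ones((8, 8, 8)))
        with pytest.raises(ValueError, match="constant"):
            register_affine(v, w)

    def test_self_registration_is_identity(self):
        img, _ = _rasterize(SMALL_SPEC, np.eye(4), None, None)
        v = normalize_intensity(Volume(img, SMALL_SPEC.grid_affine()))
        t = register_affine(v, v)
        assert np.abs(t.affine[:3, 3]).max() < 0.1
        assert np.abs(t.affine[:3, :3] - np.eye(3)).max() < 0.01

    def test_known_translation_recovered(self):
        img0, _ = _rasterize(SMALL_SPEC, np.eye(4), None, None)
        atlas_ref = normalize_intensity(Volume(img0, SMALL_SPEC.grid_affine()))
        A = np.eye(4)
        A[:3, 3] = [5.0, -3.0, 2.0]
        rng = np.random.default_rng(0)
        img, _ = _rasterize(SMALL_SPEC, A, None, rng)
        subj = normalize_intensity(Volume(img, SMALL_SPEC.grid_affine()))
        t = register_affine(atlas_ref, subj)
        assert np.abs(t.affine[:3, 3] - np.linalg.inv(A)[:3, 3]).max() < 0.5

    def test_known_scale_recovered(self):
        img0, _ = _rasterize(SMALL_SPEC, np.eye(4), None, None)
        atlas_ref = normalize_intensity(Volume(img0, SMALL_SPEC.grid_affine()))
        A = np.diag([1.1, 1.1, 1.1, 1.0])
        rng = np.random.default_rng(1)
        img, _ = _rasterize(SMALL_SPEC, A, None, rng)
        subj = normalize_intensity(Volume(img, SMALL_SPEC.grid_affine()))
        t = register_affine(atlas_ref, subj)
        sv = np.linalg.svd(t.affine[:3, :3], compute_uv=False)
        assert np.abs(sv * 1.1 - 1.0).max() < 0.02  # recovered scale ~ 1/1.1

    def test_nonlinear_zero_deformation_case(self):
        A, subj = _make_subject(77)
        img0, _ = _rasterize(SMALL_SPEC, np.eye(4), None, None)
        atlas_ref = normalize_intensity(Volume(img0, SMALL_SPEC.grid_affine()))
        aff = register_affine(atlas_ref, subj)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nl = register_nonlinear(atlas_ref, subj, aff)
        if nl.deformation is not None:
            mag = np.linalg.norm(nl.deformation, axis=-1)
            assert mag[subj.data != 0].mean() < 0.5

    def test_nonlinear_noise_only_stays_small(self):
        img0, _ = _rasterize(SMALL_SPEC, np.eye(4), None, None)
        ref = normalize_intensity(Volume(img0, SMALL_SPEC.grid_affine()))
        rng = np.random.default_rng(3)
        img1, _ = _rasterize(SMALL_SPEC, np.eye(4), None, rng)
        noisy = normalize_intensity(Volume(img1, SMALL_SPEC.grid_affine()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nl = register_nonlinear(ref, noisy, SpatialTransform(np.eye(4)))
        if nl.deformation is not None:
            mag = np.linalg.norm(nl.deformation, axis=-1)
            assert np.percentile(mag, 95) < 1.5

    def test_self_registration_leaves_probe_map_unchanged(self):
        img0, _ = _rasterize(SMALL_SPEC, np.eye(4), None, None)
        v = normalize_intensity(Volume(img0, SMALL_SPEC.grid_affine()))
        t = register_affine(v, v)
        probe = np.zeros(v.shape)
        probe[20:30, 22:34, 20:30] = 1.0
        out = warp_probability_map(Volume(probe, v.affine), t, v)
        interior = np.zeros_like(probe, dtype=bool)
        interior[3:-3, 3:-3, 3:-3] = True
        # away from the step edges the probe is preserved
        core = probe == 1.0
        core[20:30, 22, :] = False  # exclude 1-voxel boundary shells
        assert np.abs(out.data[interior & core] - 1.0).max() < 1e-2


class TestTransformSerialization:
    def test_affine_round_trip(self, tmp_path, rng):
        from hipposeg import save_transform, load_transform

        a = np.eye(4)
        a[:3, :3] += rng.normal(0, 0.05, (3, 3))
        a[:3, 3] = rng.normal(0, 3, 3)
        t = SpatialTransform(a)
        save_transform(t, tmp_path / "t")
        back = load_transform(tmp_path / "t")
        assert np.allclose(back.affine, a, atol=1e-9)
        assert back.deformation is None

    def test_dense_round_trip(self, tmp_path, rng):
        from hipposeg import save_transform, load_transform

        a = np.eye(4)
        field = rng.normal(0, 1, (6, 7, 8, 3)).astype(np.float32)
        grid = np.diag([1.0, 1.0, 1.0, 1.0])
        t = SpatialTransform(a, field, grid)
        save_transform(t, tmp_path / "t")
        back = load_transform(tmp_path / "t")
        assert np.allclose(back.deformation, field, atol=1e-6)
        assert np.allclose(back.fixed_grid_affine, grid)
        # serialized transform resamples identically
        v = Volume(rng.normal(size=(6, 7, 8)))
        out1 = resample_through(v, t, v)
        out2 = resample_through(v, back, v)
        assert np.allclose(out1.data, out2.data, atol=1e-5)
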