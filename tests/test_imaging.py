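"""Volume preprocessing and peritumoral ring geometry."""

import numpy as np
import pytest

from habitomics.imaging import (
    GridError,
    RegionMask,
    Volume,
    correct_bias,
    load_mask,
    load_volume,
    normalize_intensity,
    peritumoral_ring,
    peritumoral_rings,
    resample_isotropic,
    save_mask,
    save_volume,
)


class TestResampling:
    def test_isotropic_input_unchanged(self):
        vol = Volume(np.random.default_rng(0).normal(size=(10, 10, 10)))
        out, _ = resample_isotropic(vol, [], 1.0)
        assert out is vol

    def test_constant_value_preserved_and_voxel_count_scales(self):
        vol = Volume(np.full((8, 8, 8), 7.0), spacing_mm=(2.0, 2.0, 2.0))
        out, _ = resample_isotropic(vol, [], 1.0)
        assert np.allclose(out.array, 7.0)
        assert out.spacing_mm == (1.0, 1.0, 1.0)
        # 2 mm -> 1 mm: 8x voxels up to boundary effects
        assert abs(out.array.size - 8 * vol.array.size) <= 0.1 * 8 * vol.array.size

    def test_sphere_mask_volume_preserved_within_5pc(self):
        shape = (24, 24, 24)
        zz, yy, xx = np.meshgrid(*[np.arange(n) * 2.0 for n in shape], indexing="ij")
        mask = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2 <= 16.0**2
        m = RegionMask(mask, spacing_mm=(2.0, 2.0, 2.0))
        vol = Volume(np.zeros(shape), spacing_mm=(2.0, 2.0, 2.0))
        _, [out] = resample_isotropic(vol, [m], 1.0)
        vol_before = m.voxel_count * 8.0
        vol_after = out.voxel_count * 1.0
        analytic = 4.0 / 3.0 * np.pi * 16.0**3
        assert abs(vol_after - vol_before) / vol_before < 0.05
        assert abs(vol_after - analytic) / analytic < 0.05
        assert set(np.unique(out.array.astype(int))) <= {0, 1}

    def test_mask_grid_mismatch_rejected(self):
        vol = Volume(np.zeros((5, 5, 5)))
        bad = RegionMask(np.zeros((6, 6, 6), dtype=bool))
        with pytest.raises(GridError):
            resample_isotropic(vol, [bad], 1.0)


class TestBiasCorrection:
    def test_bias_free_input_is_near_identity(self, rng):
        img = np.full((16, 16, 16), 100.0) + rng.normal(0, 1e-6, (16, 16, 16))
        vol = Volume(img)
        mask = RegionMask(np.ones((16, 16, 16), dtype=bool))
        out = correct_bias(vol, mask)
        assert np.max(np.abs(out.array - img) / img) < 0.01

    def test_planted_quadratic_field_recovered(self, rng):
        shape = (20, 20, 20)
        ax = np.linspace(-1, 1, 20)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        field = np.exp(0.4 * X**2 - 0.3 * Y * Z + 0.2 * X)
        clean = np.full(shape, 100.0)
        vol = Volume(clean * field)
        mask = RegionMask(np.ones(shape, dtype=bool))
        out = correct_bias(vol, mask, degree=2)
        cv_before = vol.array[mask.array].std() / vol.array[mask.array].mean()
        cv_after = out.array[mask.array].std() / out.array[mask.array].mean()
        assert cv_before / max(cv_after, 1e-12) >= 5.0

    def test_constant_image_unchanged(self):
        vol = Volume(np.full((12, 12, 12), 50.0))
        mask = RegionMask(np.ones((12, 12, 12), dtype=bool))
        out = correct_bias(vol, mask)
        assert np.allclose(out.array, 50.0, rtol=1e-6)

    def test_nonpositive_intensities_warn_then_succeed(self, rng):
        arr = rng.normal(0.0, 1.0, (12, 12, 12))
        vol = Volume(arr)
        mask = RegionMask(np.ones((12, 12, 12), dtype=bool))
        with pytest.warns(UserWarning, match="non-positive"):
            out = correct_bias(vol, mask)
        assert np.all(np.isfinite(out.array))


class TestNormalization:
    def test_zero_mean_unit_sd_over_region(self, sphere_volume):
        vol, mask = sphere_volume
        out = normalize_intensity(vol, mask)
        vals = out.array[mask.array]
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std() - 1.0) < 1e-9

    def test_affine_invariance(self, sphere_volume):
        vol, mask = sphere_volume
        scaled = Volume(3.5 * vol.array + 12.0, vol.spacing_mm, vol.origin_mm)
        a = normalize_intensity(vol, mask)
        b = normalize_intensity(scaled, mask)
        assert np.allclose(a.array, b.array, atol=1e-9)

    def test_constant_region_errors(self):
        vol = Volume(np.zeros((6, 6, 6)))
        mask = RegionMask(np.ones((6, 6, 6), dtype=bool), role="body")
        with pytest.raises(GridError, match="body"):
            normalize_intensity(vol, mask)


class TestPeritumoralRings:
    def test_single_voxel_2mm_ring_has_32_voxels(self):
        # integer offsets v with 0 < |v|^2 <= 4: 6 + 12 + 8 + 6 = 32
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        ring = peritumoral_ring(RegionMask(mask), 2.0)
        assert ring.voxel_count == 32
        assert not (ring.array & mask).any()

    def test_tiny_distance_gives_empty_ring(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        ring = peritumoral_ring(RegionMask(mask), 0.4)
        assert ring.voxel_count == 0

    def test_nesting_and_disjointness_on_random_masks(self, rng):
        for _ in range(3):
            mask = np.zeros((20, 20, 20), dtype=bool)
            mask[tuple(rng.integers(6, 14, size=(3, 8)))] = True
            tumor = RegionMask(mask)
            rings = peritumoral_rings(tumor, (1.0, 2.0, 3.0, 4.0, 5.0))
            prev = np.zeros_like(mask)
            for d in (1.0, 2.0, 3.0, 4.0, 5.0):
                cur = rings[d].array
                assert not (cur & mask).any()
                assert (prev & ~cur).sum() == 0  # monotone nesting
                prev = cur

    def test_anisotropic_spacing_matches_physical_geometry(self):
        # one voxel at 0.5 mm in-plane: a 1 mm ring reaches 2 voxels in-plane
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        ring = peritumoral_ring(RegionMask(mask, spacing_mm=(0.5, 0.5, 1.0)), 1.0)
        # offsets (di,dj,dk) with (0.5di)^2+(0.5dj)^2+dk^2 <= 1: in-plane radius 2
        expected = sum(
            1
            for di in range(-2, 3)
            for dj in range(-2, 3)
            for dk in range(-1, 2)
            if 0 < (0.5 * di) ** 2 + (0.5 * dj) ** 2 + dk**2 <= 1.0 + 1e-12
        )
        assert ring.voxel_count == expected

    def test_invalid_distance_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError):
            peritumoral_ring(RegionMask(mask), 0.0)


class TestNiftiRoundTrip:
    def test_volume_and_mask_round_trip(self, tmp_path, sphere_volume):
        vol, mask = sphere_volume
        save_volume(vol, tmp_path / "v.nii.gz")
        save_mask(mask, tmp_path / "m.nii.gz")
        v2 = load_volume(tmp_path / "v.nii.gz")
        m2 = load_mask(tmp_path / "m.nii.gz")
        assert np.allclose(v2.array, vol.array, atol=1e-4)
        assert v2.spacing_mm == vol.spacing_mm
        assert (m2.array == mask.array).all()
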