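import numpy as np
import nibabel as nib
import pytest

from renoquant.grids import (
    FormatError,
    LabeledMask,
    Unit,
    VolumeGrid,
    crop_to_window,
    read_volume,
    resample,
    smooth_mask,
    uncrop,
    write_volume,
)


def _grid(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), unit=Unit.HU):
    return VolumeGrid(values, spacing, origin, unit)


def _ellipsoid_mask(shape, semi, spacing=(1.0, 1.0, 1.0)):
    ax = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    m = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1
    return m.astype(np.uint8)


class TestIO:
    @pytest.mark.parametrize("spacing", [(0.977, 0.977, 2.5), (1.726, 1.726, 1.726)])
    def test_roundtrip_preserves_values_and_geometry(self, tmp_path, rng, spacing):
        v = _grid(
            rng.normal(size=(12, 10, 8)).astype(np.float32),
            spacing=spacing,
            origin=(-5.0, 3.5, 10.0),
            unit=Unit.BQ_PER_ML,
        )
        p = tmp_path / "vol.nii.gz"
        write_volume(v, p)
        back = read_volume(p)
        np.testing.assert_array_equal(back.values, v.values)
        np.testing.assert_allclose(back.spacing_mm, v.spacing_mm, atol=1e-6)
        np.testing.assert_allclose(back.origin_mm, v.origin_mm, atol=1e-6)
        assert back.unit is Unit.BQ_PER_ML  # from the sidecar

    def test_binary_mask_roundtrip(self, tmp_path, rng):
        m = _grid((rng.random((6, 6, 6)) > 0.5).astype(np.uint8), unit=Unit.BINARY)
        p = tmp_path / "mask.nii"
        write_volume(m, p)
        np.testing.assert_array_equal(read_volume(p).values, m.values)

    def test_non_3d_image_rejected(self, tmp_path):
        p = tmp_path / "flat.nii"
        nib.save(nib.Nifti1Image(np.zeros((4, 4), dtype=np.float32), np.eye(4)), str(p))
        with pytest.raises(FormatError):
            read_volume(p)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(FormatError):
            VolumeGrid(np.zeros((2, 2, 2)), spacing_mm=(1.0, 0.0, 1.0))


class TestResample:
    def test_identity_grid_is_identity(self, rng):
        v = _grid(rng.normal(size=(8, 8, 8)).astype(np.float32))
        out = resample(v, v.spacing_mm, v.shape)
        np.testing.assert_allclose(out.values, v.values, atol=1e-5)

    def test_constant_field_is_exact_and_nonnegative(self):
        v = _grid(np.full((10, 10, 10), 7.25, dtype=np.float32), spacing=(2.0, 2.0, 2.0))
        out = resample(v, (1.3, 1.3, 1.3), (12, 12, 12))
        np.testing.assert_allclose(out.values, 7.25, atol=1e-5)
        assert (out.values >= 0).all()

    def test_centered_fov_trim(self):
        # coarse analogue of the 512 @ 0.977 -> 256 @ 1.726 in-plane trim:
        # the target grid center must coincide with the source center and
        # the extents follow shape * spacing
        v = _grid(np.zeros((64, 64, 20), dtype=np.float32), spacing=(0.977, 0.977, 2.5))
        out = resample(v, (1.726, 1.726, 1.726), (32, 32, 29))
        np.testing.assert_allclose(out.center_mm, v.center_mm, atol=1e-9)
        extent = np.asarray(out.shape) * np.asarray(out.spacing_mm)
        np.testing.assert_allclose(extent, [55.232, 55.232, 50.054])

    def test_mask_mode_stays_binary_and_requires_binary_tag(self):
        m = _grid(_ellipsoid_mask((16, 16, 16), (5, 5, 5)), unit=Unit.BINARY)
        out = resample(m, (0.8, 0.8, 0.8), (20, 20, 20), mode="mask")
        assert set(np.unique(out.values)) <= {0, 1}
        hu = _grid(np.zeros((4, 4, 4), dtype=np.float32), unit=Unit.HU)
        with pytest.raises(ValueError):
            resample(hu, (1, 1, 1), (4, 4, 4), mode="mask")

    def test_total_activity_conserved_for_smooth_volume(self, clean_phantom):
        sp = clean_phantom.spect
        blurred = sp.with_values(
            __import__("scipy.ndimage", fromlist=["gaussian_filter"]).gaussian_filter(
                np.asarray(sp.values, dtype=np.float64), 1.0
            )
        )
        total = blurred.values.sum() * blurred.voxel_volume_ml
        out = resample(blurred, (2.5, 2.5, 2.5), (80, 60, 60))
        total2 = out.values.sum() * out.voxel_volume_ml
        assert abs(total2 - total) / total < 0.02


class TestCrop:
    def test_crop_shape_and_uncrop_identity(self, rng):
        v = _grid(rng.normal(size=(32, 32, 29)).astype(np.float32))
        w = crop_to_window(v, (24, 16, 12))
        assert w.shape == (24, 16, 12)
        # world coordinates preserved
        start = w.meta["crop"]["start"]
        np.testing.assert_allclose(
            w.origin_mm, [v.origin_mm[a] + start[a] * v.spacing_mm[a] for a in range(3)]
        )
        back = uncrop(w)
        assert back.shape == v.shape
        sl = tuple(slice(start[a], start[a] + w.shape[a]) for a in range(3))
        np.testing.assert_array_equal(back.values[sl], v.values[sl])

    def test_mask_crop_uncrop_zero_outside(self):
        m = _grid(_ellipsoid_mask((20, 20, 20), (4, 4, 4)), unit=Unit.BINARY)
        w = crop_to_window(m, (12, 12, 12))
        back = uncrop(w)
        np.testing.assert_array_equal(back.values[4:16, 4:16, 4:16], m.values[4:16, 4:16, 4:16])
        outside = np.ones((20, 20, 20), dtype=bool)
        outside[4:16, 4:16, 4:16] = False
        assert back.values[outside].sum() == 0

    def test_window_equal_to_volume_is_identity(self, rng):
        v = _grid(rng.normal(size=(10, 8, 6)).astype(np.float32))
        w = crop_to_window(v, v.shape)
        np.testing.assert_array_equal(w.values, v.values)
        np.testing.assert_allclose(w.origin_mm, v.origin_mm)

    def test_padding_handles_oversized_window(self, rng):
        v = _grid(rng.normal(size=(6, 6, 6)).astype(np.float32))
        w = crop_to_window(v, (10, 10, 10))
        assert w.shape == (10, 10, 10)
        np.testing.assert_array_equal(w.values[2:8, 2:8, 2:8], v.values)


class TestSmoothMask:
    def test_smooth_ellipsoid_nearly_unchanged(self):
        m = LabeledMask.from_binary(
            _grid(_ellipsoid_mask((30, 30, 30), (10, 8, 7)), unit=Unit.BINARY)
        )
        out = smooth_mask(m)
        a = m.grid.values.astype(bool)
        b = out.grid.values.astype(bool)
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice > 0.99

    def test_striped_mask_becomes_continuous(self):
        full = _ellipsoid_mask((24, 24, 24), (8, 8, 8))
        striped = full.copy()
        striped[:, 1::2, :] = 0  # drop every other coronal slice
        out = smooth_mask(
            LabeledMask.from_binary(_grid(striped, unit=Unit.BINARY)), sigma_mm=1.0
        )
        vals = out.grid.values
        js = np.where(vals.any(axis=(0, 2)))[0]
        # every coronal slice between the first and last occupied one is occupied
        assert len(js) == js[-1] - js[0] + 1, "empty coronal slice inside kidney span"
        assert len(js) >= 10  # the smoothed kidney still spans most of the stripes

    def test_empty_mask_returned_unchanged(self):
        m = LabeledMask.from_binary(_grid(np.zeros((8, 8, 8), np.uint8), unit=Unit.BINARY))
        out = smooth_mask(m)
        assert out.grid.values.sum() == 0

    def test_idempotent_to_dice_099(self):
        m = LabeledMask.from_binary(
            _grid(_ellipsoid_mask((26, 26, 26), (9, 7, 6)), unit=Unit.BINARY)
        )
        once = smooth_mask(m)
        twice = smooth_mask(once)
        a = once.grid.values.astype(bool)
        b = twice.grid.values.astype(bool)
        assert 2 * (a & b).sum() / (a.sum() + b.sum()) >= 0.99


class TestLaterality:
    def test_two_components_get_left_and_right(self):
        vals = np.zeros((20, 10, 10), dtype=np.uint8)
        vals[2:6, 4:7, 4:7] = 1  # low index -> right
        vals[14:18, 4:7, 4:7] = 1  # high index -> left
        m = LabeledMask.from_binary(_grid(vals, unit=Unit.BINARY))
        assert m.side_mask("right")[3, 5, 5]
        assert m.side_mask("left")[15, 5, 5]
        assert not (m.side_mask("left") & m.side_mask("right")).any()

    def test_single_kidney_leaves_other_side_empty(self):
        vals = np.zeros((20, 10, 10), dtype=np.uint8)
        vals[2:6, 4:7, 4:7] = 1
        m = LabeledMask.from_binary(_grid(vals, unit=Unit.BINARY))
        assert m.sides_present == ["right"]

    def test_nonbinary_values_rejected(self):
        with pytest.raises(ValueError):
            LabeledMask(
                grid=_grid(np.full((3, 3, 3), 2.0), unit=Unit.BINARY),
                labels={"left": np.zeros((3, 3, 3), bool), "right": np.zeros((3, 3, 3), bool)},
            )
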