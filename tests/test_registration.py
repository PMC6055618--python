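"""Flip, demons registration, Jacobian modulation, symmetric template."""

import numpy as np
import pytest

from vbasym.io_core import GreyMatterVolume, make_affine
from vbasym.registration import (
    DisplacementField,
    RegistrationParams,
    build_symmetric_template,
    flip_lr,
    identity_field,
    jacobian_determinant,
    read_field,
    register,
    warp_and_modulate,
    write_field,
)
from vbasym.synthetic import default_anatomy, make_base_anatomy


class TestFlip:
    def test_involution_bit_exact(self, small_volume):
        assert np.array_equal(flip_lr(flip_lr(small_volume)).data, small_volume.data)

    def test_symmetric_anatomy_is_fixed_point(self):
        base = make_base_anatomy(default_anatomy())
        assert np.array_equal(flip_lr(base).data, base.data)

    def test_impulse_reflects_about_midline(self):
        shape = (17, 16, 16)
        aff = make_affine(shape, 3.0)
        data = np.zeros(shape)
        data[11, 4, 4] = 1.0  # world x = (11-8)*3 = +9 mm
        flipped = flip_lr(GreyMatterVolume(data, aff))
        assert flipped.data[5, 4, 4] == 1.0  # world x = -9 mm
        assert flipped.data.sum() == 1.0

    def test_even_x_rejected(self):
        vol = GreyMatterVolume(np.ones((8, 8, 8)), np.eye(4))
        with pytest.raises(ValueError, match="odd"):
            flip_lr(vol)


class TestJacobian:
    def test_zero_field_gives_unit_determinant(self, small_affine):
        f = identity_field((17, 16, 16), small_affine)
        np.testing.assert_allclose(jacobian_determinant(f), 1.0)

    def test_uniform_linear_expansion(self, small_affine):
        # u(x) = 0.1 x  =>  det(d(x+u)/dx) = 1.1^3 = 1.331 (exact for linear fields)
        shape = (17, 16, 16)
        disp = np.zeros(shape + (3,))
        for ax in range(3):
            coord = small_affine[ax, ax] * np.arange(shape[ax]) + small_affine[ax, 3]
            sl = [None, None, None]
            sl[ax] = slice(None)
            disp[..., ax] = 0.1 * coord[tuple(sl)]
        det = jacobian_determinant(DisplacementField(disp, small_affine))
        np.testing.assert_allclose(det, 1.1**3, rtol=1e-10)

    def test_pure_translation_is_volume_preserving(self, small_affine):
        disp = np.ones((17, 16, 16, 3)) * 4.2
        det = jacobian_determinant(DisplacementField(disp, small_affine))
        np.testing.assert_allclose(det, 1.0)


class TestWarpAndModulate:
    def test_identity_field_is_identity(self, small_volume, small_affine):
        f = identity_field(small_volume.shape, small_affine)
        out = warp_and_modulate(small_volume, f)
        np.testing.assert_allclose(out.data, small_volume.data, atol=1e-12)

    def test_integer_translation_preserves_mass_and_shifts(self, gaussian_blob):
        # shift by exactly one voxel (3 mm) along y: permutation with unit Jacobian
        disp = np.zeros(gaussian_blob.shape + (3,))
        disp[..., 1] = 3.0
        f = DisplacementField(disp, gaussian_blob.affine)
        out = warp_and_modulate(gaussian_blob, f)
        np.testing.assert_allclose(out.data[:, :-1, :], gaussian_blob.data[:, 1:, :], atol=1e-12)
        assert abs(out.data.sum() - gaussian_blob.data.sum()) / gaussian_blob.data.sum() < 1e-6

    def test_modulation_restores_mass_under_expansion(self, gaussian_blob):
        # the map x -> 1.08 x samples a shrunken blob (unmodulated mass drops by
        # ~1/1.08^3); multiplying by the Jacobian determinant restores it
        from vbasym.registration import warp_only

        shape = gaussian_blob.shape
        aff = gaussian_blob.affine
        disp = np.zeros(shape + (3,))
        for ax in range(3):
            coord = aff[ax, ax] * np.arange(shape[ax]) + aff[ax, 3]
            sl = [None, None, None]
            sl[ax] = slice(None)
            disp[..., ax] = 0.08 * coord[tuple(sl)]
        f = DisplacementField(disp, aff)
        mass0 = gaussian_blob.data.sum()
        plain = warp_only(gaussian_blob, f).data.sum()
        modulated = warp_and_modulate(gaussian_blob, f).data.sum()
        np.testing.assert_allclose(plain / mass0, 1.08**-3, rtol=0.01)
        assert abs(modulated - mass0) / mass0 < 0.005

    def test_grid_mismatch_rejected(self, small_volume, gaussian_blob):
        f = identity_field(gaussian_blob.shape, gaussian_blob.affine)
        with pytest.raises(ValueError, match="grid"):
            warp_and_modulate(small_volume, f)


class TestRegister:
    def test_self_registration_yields_tiny_displacement(self, gaussian_blob):
        f = register(gaussian_blob, gaussian_blob)
        assert np.abs(f.disp).max() < 0.1 * 3.0  # < 0.1 voxel

    def test_known_translation_recovered(self, gaussian_blob):
        moving = gaussian_blob.with_data(np.roll(gaussian_blob.data, 2, axis=1))
        f = register(moving, gaussian_blob)
        support = gaussian_blob.data > 0.1
        mean_dy = f.disp[..., 1][support].mean()
        assert abs(mean_dy - 6.0) < 1.5  # within 0.5 voxel of the +2 voxel shift
        assert jacobian_determinant(f).min() > 0

    def test_zero_iterations_gives_identity_field(self, gaussian_blob):
        params = RegistrationParams(levels=(2, 1), iterations=(0, 0))
        moving = gaussian_blob.with_data(np.roll(gaussian_blob.data, 2, axis=1))
        f = register(moving, gaussian_blob, params)
        assert np.abs(f.disp).max() == 0.0
        np.testing.assert_allclose(jacobian_determinant(f), 1.0)

    def test_registration_reduces_ssd(self, gaussian_blob):
        moving = gaussian_blob.with_data(np.roll(gaussian_blob.data, 2, axis=1))
        f = register(moving, gaussian_blob)
        warped = warp_and_modulate(moving, f)
        ssd0 = ((moving.data - gaussian_blob.data) ** 2).sum()
        ssd1 = ((warped.data - gaussian_blob.data) ** 2).sum()
        assert ssd1 < 0.25 * ssd0


class TestSymmetricTemplate:
    def test_identical_symmetric_inputs_are_fixed_point(self):
        base = make_base_anatomy(default_anatomy(grid_shape=(33, 32, 32)))
        tmpl, pairs = build_symmetric_template([base, base], n_iter=1)
        assert tmpl.symmetry_residual <= 1e-6
        np.testing.assert_allclose(tmpl.template.data, base.data, atol=0.02)
        for fo, ff in pairs:
            assert np.abs(fo.disp).max() < 1.5  # ~identity (mm)
            assert np.abs(ff.disp).max() < 1.5

    def test_zero_iterations_gives_symmetrized_grand_mean(self, gaussian_blob):
        shifted = gaussian_blob.with_data(np.roll(gaussian_blob.data, 1, axis=0))
        tmpl, pairs = build_symmetric_template([gaussian_blob, shifted], n_iter=0)
        pool = np.mean(
            [gaussian_blob.data, shifted.data, gaussian_blob.data[::-1], shifted.data[::-1]], axis=0
        )
        expected = 0.5 * (pool + pool[::-1])
        np.testing.assert_allclose(tmpl.template.data, expected, atol=1e-12)
        for fo, ff in pairs:
            assert np.abs(fo.disp).max() == 0.0 and np.abs(ff.disp).max() == 0.0

    def test_one_asymmetric_blob_template_averages_sides(self):
        # a subject with a brighter left blob: the symmetric template's blob mass
        # approximates the mean of left and right blob masses
        shape = (49, 48, 48)
        aff = make_affine(shape, 3.0)
        idx = np.indices(shape, dtype=float)
        right = np.exp(-(((idx[0] - 34) ** 2 + (idx[1] - 24) ** 2 + (idx[2] - 24) ** 2)) / (2 * 3.0**2))
        left = np.exp(-(((idx[0] - 14) ** 2 + (idx[1] - 24) ** 2 + (idx[2] - 24) ** 2)) / (2 * 3.0**2))
        vol = GreyMatterVolume(0.9 * left + 0.5 * right, aff)
        tmpl, _ = build_symmetric_template([vol], n_iter=1)
        assert tmpl.symmetry_residual <= 1e-6
        half = tmpl.template.data[25:, :, :].sum()
        expected = 0.5 * (0.9 + 0.5) * left.sum()
        assert abs(half - expected) / expected < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_symmetric_template([])


def test_field_nifti_roundtrip(tmp_path, small_affine):
    rng = np.random.default_rng(3)
    disp = rng.normal(0, 1, (17, 16, 16, 3)).astype(np.float32).astype(np.float64)
    f = DisplacementField(disp, small_affine)
    write_field(f, tmp_path / "f.nii.gz")
    back = read_field(tmp_path / "f.nii.gz")
    np.testing.assert_array_equal(back.disp, f.disp)
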