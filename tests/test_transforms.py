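"""Warping, field composition/upsampling, Jacobians and landmark mapping."""

import numpy as np
import pytest

from tumorbedreg.transforms import (affine_to_field, apply_affine,
                                    compose_fields, identity_coords,
                                    jacobian_determinant,
                                    transform_landmarks, upsample_field,
                                    warp_image, warp_mask)
from tumorbedreg.volumes_io import (AffineTransform, DisplacementField,
                                    Image3D, LandmarkSet, SegmentationMask)

from oracles import compose_brute, warp_brute


def _field(arr, img):
    return DisplacementField(arr, img.spacing.copy(), img.origin.copy())


def test_zero_field_is_identity_warp(smooth_volume):
    u = DisplacementField.zeros_like(smooth_volume)
    out = warp_image(smooth_volume, u)
    np.testing.assert_array_equal(out.data, smooth_volume.data)


def test_constant_shift_of_linear_ramp(smooth_volume):
    ramp = Image3D(identity_coords(smooth_volume.shape)[0].astype(float),
                   smooth_volume.spacing)
    u = np.zeros((3,) + smooth_volume.shape)
    u[0] = 1.0
    out = warp_image(ramp, _field(u, ramp))
    np.testing.assert_allclose(out.data[:-1], ramp.data[:-1] + 1.0,
                               atol=1e-12)


def test_warp_matches_brute_force_oracle(rng):
    vol = Image3D(rng.random((3, 3, 3)))
    u = rng.normal(scale=0.4, size=(3, 3, 3, 3))
    out = warp_image(vol, _field(u, vol))
    np.testing.assert_allclose(out.data, warp_brute(vol.data, u), atol=1e-12)


def test_warp_respects_input_range(rng):
    vol = Image3D(rng.random((6, 6, 6)))
    u = rng.normal(scale=2.0, size=(3, 6, 6, 6))
    out = warp_image(vol, _field(u, vol))
    assert out.data.min() >= vol.data.min() - 1e-12
    assert out.data.max() <= vol.data.max() + 1e-12


def test_warp_nearest_mode(rng):
    vol = Image3D(rng.random((5, 5, 5)))
    u = np.full((3, 5, 5, 5), 0.4)
    out = warp_image(vol, _field(u, vol), mode="nearest")
    np.testing.assert_array_equal(out.data[:-1, :-1, :-1],
                                  vol.data[:-1, :-1, :-1])
    with pytest.raises(ValueError):
        warp_image(vol, _field(u, vol), mode="cubic")


def test_warp_grid_mismatch_raises(rng):
    vol = Image3D(rng.random((5, 5, 5)))
    u = DisplacementField(np.zeros((3, 4, 4, 4)))
    with pytest.raises(ValueError):
        warp_image(vol, u)


def test_warp_mask_fraction_and_oracle(rng):
    mask = SegmentationMask((rng.random((4, 4, 4)) > 0.5).astype(float))
    u = rng.normal(scale=0.5, size=(3, 4, 4, 4))
    out = warp_mask(mask, _field(u, mask))
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
    np.testing.assert_allclose(out.data, warp_brute(mask.data, u), atol=1e-12)


def test_apply_affine_identity(smooth_volume):
    out = apply_affine(smooth_volume, AffineTransform.identity())
    np.testing.assert_allclose(out.data, smooth_volume.data, atol=1e-12)


def test_affine_translation_equals_constant_field(smooth_volume):
    A = AffineTransform(np.eye(3), smooth_volume.spacing.copy())  # 1 voxel
    via_affine = apply_affine(smooth_volume, A)
    u = np.ones((3,) + smooth_volume.shape)
    via_field = warp_image(smooth_volume, _field(u, smooth_volume))
    np.testing.assert_allclose(via_affine.data, via_field.data, atol=1e-10)


def test_affine_rotation_preserves_symmetric_blob():
    shape = (17, 17, 17)
    xw = identity_coords(shape) - 8.0
    blob = np.exp(-(xw ** 2).sum(axis=0) / 18.0)
    img = Image3D(blob, np.ones(3))
    R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    c = np.full(3, 8.0)
    out = apply_affine(img, AffineTransform(R, c - R @ c))
    np.testing.assert_allclose(out.data, img.data, atol=1e-10)


def test_affine_to_field_equivalence(smooth_volume, rng):
    A = AffineTransform(np.eye(3) + 0.02 * rng.normal(size=(3, 3)),
                        rng.normal(scale=1.0, size=3))
    u = affine_to_field(A, smooth_volume)
    via_field = warp_image(smooth_volume, u)
    via_affine = apply_affine(smooth_volume, A)
    rms = np.sqrt(((via_field.data - via_affine.data) ** 2).mean())
    assert rms < 1e-4
    uz = affine_to_field(AffineTransform.identity(), smooth_volume)
    np.testing.assert_allclose(uz.data, 0.0, atol=1e-12)


def test_compose_identity_and_inverse_translation():
    grid = Image3D(np.zeros((6, 6, 6)))
    z = DisplacementField.zeros_like(grid)
    u = _field(np.tile(np.array([1.5, -0.5, 0.25]).reshape(3, 1, 1, 1),
                       (1, 6, 6, 6)), grid)
    np.testing.assert_allclose(compose_fields(u, z).data, u.data)
    np.testing.assert_allclose(compose_fields(z, u).data, u.data)
    minus = _field(-u.data, grid)
    comp = compose_fields(u, minus)
    interior = comp.data[:, 2:-2, 2:-2, 2:-2]
    np.testing.assert_allclose(interior, 0.0, atol=1e-12)


def test_compose_matches_brute_force(rng):
    grid = Image3D(np.zeros((5, 5, 5)))
    u1 = rng.normal(scale=0.4, size=(3, 5, 5, 5))
    u2 = rng.normal(scale=0.4, size=(3, 5, 5, 5))
    comp = compose_fields(_field(u1, grid), _field(u2, grid))
    np.testing.assert_allclose(comp.data, compose_brute(u1, u2), atol=1e-12)


def test_upsample_unit_conversion_and_linear_exactness():
    coarse_grid = Image3D(np.zeros((8, 8, 8)), np.full(3, 4.0))
    fine_grid = Image3D(np.zeros((16, 16, 16)), np.full(3, 2.0))
    const = _field(np.tile(np.array([1.0, 0, 0]).reshape(3, 1, 1, 1),
                           (1, 8, 8, 8)), coarse_grid)
    up = upsample_field(const, fine_grid)
    np.testing.assert_allclose(up.data[0], 2.0, atol=1e-12)
    np.testing.assert_allclose(up.data[1:], 0.0, atol=1e-12)

    zero = DisplacementField.zeros_like(coarse_grid)
    zero = _field(zero.data, coarse_grid)
    np.testing.assert_allclose(upsample_field(zero, fine_grid).data, 0.0)

    lin = 0.1 * identity_coords((8, 8, 8)) + 0.3
    up2 = upsample_field(_field(lin, coarse_grid), fine_grid)
    # linear displacement (voxel units doubled, coordinates halved)
    expected = 2.0 * (0.1 * identity_coords((16, 16, 16)) / 2.0 + 0.3)
    interior = np.s_[:, :-2, :-2, :-2]  # inside the coarse extent
    np.testing.assert_allclose(up2.data[interior], expected[interior],
                               atol=1e-10)

    with pytest.raises(ValueError):
        upsample_field(upsample_field(const, fine_grid), coarse_grid)


def test_jacobian_closed_forms():
    grid = Image3D(np.zeros((9, 9, 9)))
    zero = DisplacementField.zeros_like(grid)
    np.testing.assert_allclose(jacobian_determinant(zero).data, 1.0)
    const = _field(np.tile(np.array([0.7, -1.2, 0.1]).reshape(3, 1, 1, 1),
                           (1, 9, 9, 9)), grid)
    np.testing.assert_allclose(jacobian_determinant(const).data, 1.0,
                               atol=1e-12)
    s = 1.1
    u = (s - 1.0) * (identity_coords((9, 9, 9)) - 4.0)
    det = jacobian_determinant(_field(u, grid)).data
    np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], s ** 3, atol=1e-6)


def test_transform_landmarks_conventions(phantom_small):
    grid = Image3D(np.zeros((8, 8, 8)), np.full(3, 2.0))
    pts = LandmarkSet(np.array([[2.0, 4.0, 6.0], [8.0, 8.0, 8.0]]))
    zero = DisplacementField.zeros_like(grid)
    np.testing.assert_allclose(transform_landmarks(pts, zero).points,
                               pts.points)
    const = _field(np.tile(np.array([1.0, 0, 0]).reshape(3, 1, 1, 1),
                           (1, 8, 8, 8)), grid)
    mapped = transform_landmarks(pts, const)
    np.testing.assert_allclose(mapped.points - pts.points,
                               [[2.0, 0, 0], [2.0, 0, 0]])
    # phantom ground truth maps fixed landmarks onto moving landmarks
    mapped = transform_landmarks(phantom_small.target_landmarks,
                                 phantom_small.gt_field)
    err = np.linalg.norm(mapped.points - phantom_small.source_landmarks.points,
                         axis=1)
    assert err.max() < 0.5 * phantom_small.gt_field.spacing[0]


def test_transform_landmarks_excludes_outside_points():
    grid = Image3D(np.zeros((6, 6, 6)), np.full(3, 2.0))
    u = DisplacementField.zeros_like(grid)
    pts = LandmarkSet(np.array([[2.0, 2.0, 2.0], [100.0, 0.0, 0.0]]))
    with pytest.warns(UserWarning, match="outside"):
        mapped, keep = transform_landmarks(pts, u, return_mask=True)
    assert len(mapped) == 1 and keep.tolist() == [True, False]


def test_jacobian_of_composition_with_zero_matches(rng):
    grid = Image3D(np.zeros((6, 6, 6)))
    u = _field(rng.normal(scale=0.3, size=(3, 6, 6, 6)), grid)
    z = DisplacementField.zeros_like(grid)
    np.testing.assert_allclose(
        jacobian_determinant(compose_fields(u, z)).data,
        jacobian_determinant(u).data, atol=1e-12)
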