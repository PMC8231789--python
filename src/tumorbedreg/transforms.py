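"""Applying and manipulating affine transforms and displacement fields.

All warping is backward: ``out(x) = img(x + u(x))`` with the field ``u``
defined on the fixed/target grid and pointing into the moving/source
domain, in voxel units. Out-of-bounds samples take the border (clamped)
value, so homogeneous background does not leak spurious similarity
gradients across the body outline.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import autodiff as ad
from .volumes_io import (AffineTransform, DisplacementField, Image3D,
                         LandmarkSet, SegmentationMask)

__all__ = [
    "identity_coords", "warp_image", "warp_mask", "apply_affine",
    "affine_to_field", "compose_fields", "upsample_field",
    "jacobian_determinant", "transform_landmarks", "warp_tensor",
    "affine_coords_tensor",
]


def identity_coords(shape, dtype=float) -> np.ndarray:
    """Voxel-index coordinate grid, shape ``(3, X, Y, Z)``."""
    axes = [np.arange(s, dtype=dtype) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


def _sample_channels(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear sampling of (C, X, Y, Z) values at voxel coords (3, ...)."""
    return ad.grid_sample(ad.Tensor(values), ad.Tensor(coords)).data


def warp_tensor(values, u, grid_shape=None):
    """Differentiable backward warp of channel-first values by field ``u``.

    ``values`` has shape (C, X, Y, Z) and ``u`` shape (3, X, Y, Z) in voxel
    units of the same grid; either may be a Tensor or ndarray.
    """
    ut = ad.as_tensor(u)
    shape = ut.shape[1:] if grid_shape is None else grid_shape
    ident = ad.Tensor(identity_coords(shape, dtype=ut.dtype))
    return ad.grid_sample(ad.as_tensor(values), ident + ut)


def warp_image(img: Image3D, u: DisplacementField,
               mode: str = "trilinear") -> Image3D:
    """Backward-warp ``img`` by ``u``: ``out(x) = img(x + u(x))``."""
    if not u.same_grid(img):
        raise ValueError("displacement field grid does not match image grid")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    coords = identity_coords(img.shape) + u.data
    if mode == "nearest":
        hi = np.array(img.shape).reshape(3, 1, 1, 1) - 1
        idx = np.clip(np.rint(coords), 0, hi).astype(np.int64)
        out = img.data[idx[0], idx[1], idx[2]]
    else:
        out = _sample_channels(img.data[None].astype(float), coords)[0]
    return img.copy_with(out)


def warp_mask(mask: SegmentationMask, u: DisplacementField) -> SegmentationMask:
    """Trilinear (differentiable-compatible) warp of a mask; values in [0,1]."""
    if not u.same_grid(mask):
        raise ValueError("displacement field grid does not match mask grid")
    coords = identity_coords(mask.shape) + u.data
    out = _sample_channels(mask.data[None].astype(float), coords)[0]
    return mask.copy_with(out)


def affine_coords_tensor(img: Image3D, matrix, translation):
    """Sampling coordinates of ``apply_affine`` as a (3,X,Y,Z) Tensor.

    ``matrix`` (3,3) and ``translation`` (3,) may be Tensors; the result is
    then differentiable with respect to them (used by the affine instance
    optimization).
    """
    shape = img.shape
    xw = (identity_coords(shape).reshape(3, -1)
          * img.spacing[:, None] + img.origin[:, None])
    m = ad.as_tensor(matrix)
    t = ad.as_tensor(translation)
    y = m @ ad.Tensor(xw) + t.reshape(3, 1)
    vox = (y - ad.Tensor(img.origin[:, None])) / ad.Tensor(img.spacing[:, None])
    return vox.reshape((3,) + tuple(shape))


def apply_affine(img: Image3D, A: AffineTransform) -> Image3D:
    """Backward-resample ``img`` through the world-coordinate map ``A``."""
    vox = affine_coords_tensor(img, A.matrix, A.translation).data
    out = _sample_channels(img.data[None].astype(float), vox)[0]
    return img.copy_with(out)


def affine_to_field(A: AffineTransform, grid_of: Image3D) -> DisplacementField:
    """Displacement field equivalent to ``apply_affine`` on ``grid_of``."""
    vox = affine_coords_tensor(grid_of, A.matrix, A.translation).data
    u = vox - identity_coords(grid_of.shape)
    return DisplacementField(u, grid_of.spacing.copy(), grid_of.origin.copy())


def compose_fields(u1: DisplacementField,
                   u2: DisplacementField) -> DisplacementField:
    """Composition ``(u2 after u1)(x) = u1(x) + u2(x + u1(x))``."""
    if not u1.same_grid(u2):
        raise ValueError("fields must share a grid to be composed")
    coords = identity_coords(u1.grid_shape) + u1.data
    u2_at = _sample_channels(u2.data, coords)
    return DisplacementField(u1.data + u2_at, u1.spacing.copy(),
                             u1.origin.copy())


def upsample_field(u: DisplacementField, target_grid) -> DisplacementField:
    """Resample ``u`` onto a finer grid, rescaling voxel-unit magnitudes."""
    tsp = np.asarray(target_grid.spacing, dtype=float)
    torigin = np.asarray(target_grid.origin, dtype=float)
    tshape = tuple(target_grid.shape[1:]) if isinstance(
        target_grid, DisplacementField) else tuple(target_grid.shape)
    if np.any(tsp > u.spacing + 1e-9):
        raise ValueError("target grid must be at least as fine as the source")
    coords = (identity_coords(tshape) * tsp.reshape(3, 1, 1, 1)
              + (torigin - u.origin).reshape(3, 1, 1, 1)) \
        / u.spacing.reshape(3, 1, 1, 1)
    vals = _sample_channels(u.data, coords)
    vals = vals * (u.spacing / tsp).reshape(3, 1, 1, 1)
    return DisplacementField(vals, tsp, torigin)


def jacobian_determinant(u: DisplacementField) -> Image3D:
    """Per-voxel ``det(I + grad(u))`` (gradients in voxel units).

    Central differences in the interior, one-sided at the borders. Values
    below zero flag folding of the deformation.
    """
    shape = u.grid_shape
    if min(shape) < 2:
        raise ValueError("jacobian needs at least 2 voxels per axis")
    jac = np.empty(shape + (3, 3))
    for c in range(3):
        grads = np.gradient(u.data[c], axis=(0, 1, 2))
        for d in range(3):
            jac[..., c, d] = grads[d]
        jac[..., c, c] += 1.0
    det = np.linalg.det(jac)
    return Image3D(det, u.spacing.copy(), u.origin.copy())


def transform_landmarks(points: LandmarkSet, u: DisplacementField,
                        return_mask: bool = False):
    """Map fixed-space landmarks through ``u`` into the moving space.

    For each point ``p`` (mm): mapped = ``p + u(p) * spacing`` with the
    field interpolated at the point's voxel position. Points outside the
    field's physical extent are excluded with a warning.
    """
    vox = (points.points - u.origin) / u.spacing
    hi = np.array(u.grid_shape) - 1
    inside = np.all((vox >= -1e-9) & (vox <= hi + 1e-9), axis=1)
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} landmark(s) outside the "
                      "field extent were excluded", stacklevel=2)
    vox_in = vox[inside]
    disp = _sample_channels(u.data, vox_in.T[:, :, None, None])[:, :, 0, 0].T
    mapped = points.points[inside] + disp * u.spacing
    labels = None
    if points.labels is not None:
        labels = [l for l, k in zip(points.labels, inside) if k]
    out = LandmarkSet(mapped, labels)
    return (out, inside) if return_mask else out
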