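"""Intensity normalization, isotropic resampling, padding, pyramids.

The standard preparation for a registration pair: map intensities linearly
to [0, 1], resample both volumes to a common isotropic spacing (2 mm by
default), pad them to a shared shape, and build coarse-to-fine resolution
pyramids (8/4 mm for the affine stage, 8/4/2 mm for the nonrigid stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .transforms import identity_coords
from .volumes_io import Image3D, SegmentationMask

__all__ = ["normalize_intensity", "resample_isotropic", "pad_to_common_shape",
           "build_pyramid", "ResolutionPyramid", "preprocess_pair"]

DEFAULT_SPACING_MM = 2.0
AFFINE_PYRAMID_MM = (8.0, 4.0)
NONRIGID_PYRAMID_MM = (8.0, 4.0, 2.0)


def normalize_intensity(img: Image3D) -> Image3D:
    """Linearly map intensities to [0, 1]; constant volumes map to zeros."""
    lo = float(img.data.min())
    hi = float(img.data.max())
    if hi - lo == 0:
        return img.copy_with(np.zeros_like(img.data, dtype=float))
    return img.copy_with((img.data.astype(float) - lo) / (hi - lo))


def resample_isotropic(img: Image3D, spacing_mm: float,
                       antialias: bool = True) -> Image3D:
    """Trilinear resampling to isotropic ``spacing_mm``.

    The physical extent ``shape * spacing`` is preserved to within one
    output voxel. Axes that are downsampled are Gaussian-smoothed first
    (sigma = 0.5 * spacing ratio, in input voxels); axes resampled at or
    above their native resolution are left untouched, so a volume already
    at the target spacing passes through unchanged. Masks resample
    trilinearly too and may become fractional.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    ratios = spacing_mm / img.spacing
    data = img.data.astype(float)
    if antialias and np.any(ratios > 1 + 1e-6):
        sigma = np.where(ratios > 1 + 1e-6, 0.5 * ratios, 0.0)
        data = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")
    new_shape = tuple(max(1, int(round(s * sp / spacing_mm)))
                      for s, sp in zip(img.shape, img.spacing))
    if new_shape == img.shape and np.allclose(ratios, 1.0):
        return img.copy_with(data)
    coords = identity_coords(new_shape) * (spacing_mm / img.spacing
                                           ).reshape(3, 1, 1, 1)
    out = ad.grid_sample(ad.Tensor(data[None]), ad.Tensor(coords)).data[0]
    result = Image3D(out, np.full(3, float(spacing_mm)), img.origin.copy())
    if isinstance(img, SegmentationMask):
        return SegmentationMask(np.clip(out, 0, 1), result.spacing,
                                result.origin)
    return result


def pad_to_common_shape(a: Image3D, b: Image3D):
    """Zero-pad both volumes (at the high-index side) to the per-axis max.

    Origins are unchanged, so world coordinates of the original voxels —
    and therefore landmark positions — are preserved.
    """
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError("volumes must share spacing before padding")
    target = tuple(max(sa, sb) for sa, sb in zip(a.shape, b.shape))

    def _pad(img):
        widths = [(0, t - s) for t, s in zip(target, img.shape)]
        if all(w == (0, 0) for w in widths):
            return img
        return img.copy_with(np.pad(img.data, widths))

    return _pad(a), _pad(b)


@dataclass
class ResolutionPyramid:
    """Coarse-to-fine list of the same volume at decreasing spacings."""

    levels: list

    def __post_init__(self):
        sp = [lv.spacing[0] for lv in self.levels]
        if any(s2 >= s1 for s1, s2 in zip(sp, sp[1:])):
            raise ValueError("pyramid spacings must strictly decrease")

    @property
    def spacings(self):
        return [float(lv.spacing[0]) for lv in self.levels]

    def __len__(self):
        return len(self.levels)

    def __getitem__(self, i):
        return self.levels[i]

    def __iter__(self):
        return iter(self.levels)


def build_pyramid(img: Image3D, spacings_mm) -> ResolutionPyramid:
    """Build a coarse-to-fine pyramid at the given isotropic spacings.

    Each level is produced from the original volume with anti-aliased
    trilinear resampling; a level at the image's own (isotropic) spacing
    is the image itself. Spacings coarser than or equal to the image
    spacing are required.
    """
    spacings_mm = list(spacings_mm)
    if any(s2 >= s1 for s1, s2 in zip(spacings_mm, spacings_mm[1:])):
        raise ValueError("pyramid spacings must strictly decrease")
    if not np.allclose(img.spacing, img.spacing[0]):
        raise ValueError("build_pyramid expects an isotropic volume")
    if spacings_mm[-1] < img.spacing[0] - 1e-9:
        raise ValueError("finest pyramid spacing cannot be finer than the "
                         "image spacing")
    levels = []
    for s in spacings_mm:
        if np.isclose(s, img.spacing[0]):
            levels.append(img)
        else:
            levels.append(resample_isotropic(img, s))
    return ResolutionPyramid(levels)


def preprocess_pair(source: Image3D, target: Image3D, mask=None,
                    spacing_mm: float = DEFAULT_SPACING_MM):
    """Normalize, resample to isotropic spacing and pad a pair to one shape.

    The optional tumor mask (on the source grid) is carried through the
    same resampling/padding. Returns ``(source, target)`` or
    ``(source, target, mask)``.
    """
    src = resample_isotropic(normalize_intensity(source), spacing_mm)
    tgt = resample_isotropic(normalize_intensity(target), spacing_mm)
    src, tgt = pad_to_common_shape(src, tgt)
    if mask is None:
        return src, tgt
    msk = resample_isotropic(mask, spacing_mm)
    msk, _ = pad_to_common_shape(msk, tgt)
    return src, tgt, SegmentationMask(msk.data, msk.spacing, msk.origin)
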