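"""Spatial data types and volume/landmark I/O.

Conventions used throughout the package:

* Volumes are numpy arrays indexed ``(x, y, z)`` with per-axis physical
  spacing in mm and a world-space origin (the mm position of voxel
  ``(0, 0, 0)``). World coordinate of voxel index ``i`` is
  ``origin + i * spacing`` (0-based). Internal grids always use identity
  direction cosines; input headers with non-trivial direction matrices are
  resampled onto an axis-aligned grid at read time.
* Displacement fields store one 3-vector per voxel, component order
  ``(x, y, z)``, expressed in voxel units of their own grid. They are
  converted to mm only where results are reported.
* Landmarks are ordered lists of world-coordinate points in mm.
* Affine transforms map fixed/target world coordinates into the
  moving/source world frame (the pull-back convention used for backward
  warping): ``y = A x + t``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "Image3D", "SegmentationMask", "DisplacementField", "LandmarkSet",
    "AffineTransform", "read_volume", "write_volume", "read_mask",
    "read_landmarks", "write_landmarks", "read_field", "write_field",
]

_VOLUME_EXTS = (".nii", ".nii.gz", ".mhd", ".mha")


def _check_grid(data: np.ndarray, spacing, origin, expect_ndim: int):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing and origin must be 3-vectors")
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be positive, got {spacing}")
    if data.ndim != expect_ndim:
        raise ValueError(f"expected {expect_ndim}-D data, got {data.ndim}-D")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume data contains non-finite values")
    return spacing, origin


@dataclass(eq=False)
class Image3D:
    """A scalar 3-D volume on a regular, axis-aligned physical grid."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _check_grid(self.data, self.spacing,
                                                self.origin, 3)
        if min(self.data.shape) < 1:
            raise ValueError("all shape components must be >= 1")

    @property
    def shape(self):
        return self.data.shape

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def same_grid(self, other) -> bool:
        return (self.shape == tuple(other.shape)
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def copy_with(self, data: np.ndarray) -> "Image3D":
        return Image3D(data, self.spacing.copy(), self.origin.copy())


@dataclass(eq=False)
class SegmentationMask(Image3D):
    """A mask on the same grid contract as :class:`Image3D`.

    Values live in [0, 1]; binary on input, fractional after trilinear
    warping or resampling.
    """

    def __post_init__(self):
        super().__post_init__()
        d = self.data
        if d.min() < -1e-6 or d.max() > 1 + 1e-6:
            raise ValueError("mask values must lie in [0, 1]")
        self.data = np.clip(d, 0.0, 1.0)

    def copy_with(self, data: np.ndarray) -> "SegmentationMask":
        return SegmentationMask(np.clip(data, 0.0, 1.0), self.spacing.copy(),
                                self.origin.copy())


@dataclass(eq=False)
class DisplacementField:
    """Per-voxel displacement, shape ``(3, X, Y, Z)``, voxel units."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.spacing, self.origin = _check_grid(self.data, self.spacing,
                                                self.origin, 4)
        if self.data.shape[0] != 3:
            raise ValueError("field leading axis must hold 3 components")

    @property
    def shape(self):
        return self.data.shape

    @property
    def grid_shape(self):
        return self.data.shape[1:]

    def same_grid(self, img) -> bool:
        other_shape = img.shape[1:] if isinstance(img, DisplacementField) \
            else img.shape
        return (self.grid_shape == tuple(other_shape)
                and np.allclose(self.spacing, img.spacing)
                and np.allclose(self.origin, img.origin))

    @classmethod
    def zeros_like(cls, img: Image3D) -> "DisplacementField":
        return cls(np.zeros((3,) + tuple(img.shape)), img.spacing.copy(),
                   img.origin.copy())


@dataclass(eq=False)
class LandmarkSet:
    """Ordered 3-D world-coordinate points (mm) with optional labels."""

    points: np.ndarray
    labels: list | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("landmarks must be an (N, 3) array")
        if self.points.shape[0] < 1:
            raise ValueError("landmark set must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("label count must match point count")

    def __len__(self):
        return len(self.points)


@dataclass(eq=False)
class AffineTransform:
    """World-coordinate affine map ``y = A x + t`` (fixed -> moving frame)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-8:
            raise ValueError("affine linear part is (near-)singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: x -> self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.translation
                               + self.translation)

    def as_matrix_3x4(self) -> np.ndarray:
        return np.hstack([self.matrix, self.translation[:, None]])

    def save(self, path) -> None:
        np.savetxt(path, self.as_matrix_3x4(), fmt="%.17g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        m = np.loadtxt(path).reshape(3, 4)
        return cls(m[:, :3], m[:, 3])


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI-1 and MetaImage via SimpleITK)
# ---------------------------------------------------------------------------

def _check_ext(path: str) -> None:
    p = str(path).lower()
    if not any(p.endswith(e) for e in _VOLUME_EXTS):
        raise ValueError(f"unsupported volume format: {path} "
                         f"(expected one of {_VOLUME_EXTS})")


def _to_axis_aligned(img: sitk.Image) -> sitk.Image:
    """Resample onto an identity-direction grid if the header has rotations."""
    if np.allclose(np.reshape(img.GetDirection(), (3, 3)), np.eye(3)):
        return img
    rs = sitk.ResampleImageFilter()
    rs.SetOutputDirection(tuple(np.eye(3).ravel()))
    rs.SetOutputSpacing(img.GetSpacing())
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetSize(img.GetSize())
    rs.SetInterpolator(sitk.sitkLinear)
    rs.SetDefaultPixelValue(0.0)
    return rs.Execute(img)


def read_volume(path) -> Image3D:
    """Read a NIfTI or MetaImage scalar volume into an :class:`Image3D`."""
    _check_ext(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:  # pragma: no cover - backend specific message
        raise ValueError(f"unreadable volume file {path}: {e}") from e
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3-D volume, got {img.GetDimension()}-D")
    img = _to_axis_aligned(img)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return Image3D(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def write_volume(img: Image3D, path) -> None:
    """Write a volume; binary masks are stored 8-bit, everything else float32."""
    _check_ext(path)
    data = img.data
    binary_mask = (isinstance(img, SegmentationMask)
                   and np.isin(data, (0.0, 1.0)).all())
    if binary_mask:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    out = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    out.SetSpacing(tuple(float(s) for s in img.spacing))
    out.SetOrigin(tuple(float(o) for o in img.origin))
    sitk.WriteImage(out, str(path))


def read_mask(path) -> SegmentationMask:
    v = read_volume(path)
    return SegmentationMask(v.data.astype(float), v.spacing, v.origin)


# ---------------------------------------------------------------------------
# Displacement-field I/O (4-D NIfTI, last axis = vector component x,y,z)
# ---------------------------------------------------------------------------

def write_field(u: DisplacementField, path) -> None:
    arr = u.data.astype(np.float32).transpose(3, 2, 1, 0)  # (z,y,x,comp)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
    img.SetSpacing(tuple(float(s) for s in u.spacing))
    img.SetOrigin(tuple(float(o) for o in u.origin))
    sitk.WriteImage(img, str(path))


def read_field(path) -> DisplacementField:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, comp)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"not a 3-component displacement field: {path}")
    data = np.ascontiguousarray(arr.transpose(3, 2, 1, 0))
    return DisplacementField(data.astype(float),
                             np.array(img.GetSpacing())[:3],
                             np.array(img.GetOrigin())[:3])


# ---------------------------------------------------------------------------
# Landmark I/O (CSV: x,y,z[,label] in mm world coordinates)
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"empty landmark file: {path}") from e
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file {path} missing columns {missing}")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    if len(pts) == 0:
        raise ValueError(f"landmark file {path} contains no points")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"landmark file {path} contains NaN/inf coordinates")
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    return LandmarkSet(pts, labels)


def write_landmarks(lms: LandmarkSet, path) -> None:
    df = pd.DataFrame(lms.points, columns=["x", "y", "z"])
    if lms.labels is not None:
        df["label"] = lms.labels
    df.to_csv(path, index=False)
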