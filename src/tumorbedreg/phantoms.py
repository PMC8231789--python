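"""Synthetic pre/post-resection phantom pairs with known ground truth.

Each phantom emulates one registration case: a smooth soft-tissue body
with a breast-like protrusion and internal intensity texture; a
hyperintense spherical tumor present only in the pre-surgery (source)
volume; a smooth random ground-truth deformation built from a handful of
Gaussian displacement bumps (analytic Jacobian, guaranteed fold-free);
and a post-surgery (target) volume produced by warping the tumor-free
tissue through that deformation — the resection cavity closes over, so
the tumor region is filled with surrounding-tissue intensity — plus
acquisition noise and an optional hypointense scar streak. Landmarks sit
at texture extrema away from the tumor, paired exactly through the
analytic deformation.

The ground-truth field follows the package's backward-warping
convention: it maps the target grid into the source domain, so it is
directly comparable to registration output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import ndimage

from .transforms import identity_coords, warp_image
from .volumes_io import (DisplacementField, Image3D, LandmarkSet,
                         SegmentationMask, write_field, write_landmarks,
                         write_volume)

__all__ = ["PhantomConfig", "PhantomPair", "generate_pair",
           "generate_dataset"]


@dataclass
class PhantomConfig:
    shape: tuple = (48, 48, 48)
    spacing_mm: float = 2.0
    tumor_radius_mm: tuple = (6.0, 10.0)
    deformation_amplitude_mm: tuple = (2.0, 6.0)
    deformation_smoothness_mm: float = 18.0
    n_bumps: tuple = (3, 8)
    n_landmarks: int = 12
    landmark_min_separation_mm: float = 8.0
    noise_sigma: float = 0.02
    texture_amplitude: float = 0.15
    texture_smoothness_mm: float = 6.0
    tissue_intensity: float = 0.45
    tumor_contrast: float = 0.15
    scar: bool = False
    max_jacobian_rejections: int = 100


@dataclass(eq=False)
class PhantomPair:
    source: Image3D
    target: Image3D
    tumor_mask: SegmentationMask
    gt_field: DisplacementField
    source_landmarks: LandmarkSet
    target_landmarks: LandmarkSet
    seed: int = 0
    #: closed-form deformation (world mm), kept for analytic oracles
    analytic_field: object | None = None


def _smoothstep(x):
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


class _GaussianBumpField:
    """Sum of Gaussian displacement bumps; analytic values and Jacobian."""

    def __init__(self, centers, amplitudes, sigmas):
        self.centers = np.asarray(centers, dtype=float)      # (K, 3) mm
        self.amplitudes = np.asarray(amplitudes, dtype=float)  # (K, 3) mm
        self.sigmas = np.asarray(sigmas, dtype=float)        # (K,) mm

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        """World-mm displacement at world points ``pts`` (N, 3)."""
        pts = np.atleast_2d(pts)
        out = np.zeros_like(pts)
        for c, a, s in zip(self.centers, self.amplitudes, self.sigmas):
            d = pts - c
            w = np.exp(-(d * d).sum(axis=1) / (2 * s * s))
            out += w[:, None] * a
        return out

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """det(I + du/dx) at world points (N, 3)."""
        pts = np.atleast_2d(pts)
        J = np.tile(np.eye(3), (len(pts), 1, 1))
        for c, a, s in zip(self.centers, self.amplitudes, self.sigmas):
            d = pts - c
            w = np.exp(-(d * d).sum(axis=1) / (2 * s * s))
            # du_i/dx_j = a_i * w * (-(x_j - c_j) / s^2)
            J += (a[None, :, None] * (-d / (s * s))[:, None, :]
                  * w[:, None, None])
        return np.linalg.det(J)


def _draw_field(rng, cfg: PhantomConfig, extent):
    lo, hi = cfg.deformation_amplitude_mm
    if hi <= 0:
        return _GaussianBumpField(np.zeros((1, 3)), np.zeros((1, 3)),
                                  np.array([cfg.deformation_smoothness_mm]))
    k = int(rng.integers(cfg.n_bumps[0], cfg.n_bumps[1] + 1))
    centers = rng.uniform(0.15, 0.85, size=(k, 3)) * extent
    mags = rng.uniform(lo, hi, size=k)
    dirs = rng.normal(size=(k, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    sig = cfg.deformation_smoothness_mm * rng.uniform(0.8, 1.2, size=k)
    return _GaussianBumpField(centers, mags[:, None] * dirs, sig)


def generate_pair(cfg: PhantomConfig | None = None, seed: int = 0
                  ) -> PhantomPair:
    """Build one deterministic phantom pair from ``seed``."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    shape = tuple(cfg.shape)
    sp = float(cfg.spacing_mm)
    spacing = np.full(3, sp)
    origin = np.zeros(3)
    extent = (np.array(shape) - 1) * sp
    xw = identity_coords(shape) * sp  # world coords, origin 0

    # -- body: ellipsoid torso + breast protrusion -------------------------
    torso_c = np.array([0.42, 0.5, 0.5]) * extent
    torso_ax = np.array([0.30, 0.36, 0.36]) * extent
    q = ((xw - torso_c.reshape(3, 1, 1, 1)) /
         torso_ax.reshape(3, 1, 1, 1))
    torso = 1.0 - np.sqrt((q * q).sum(axis=0))
    breast_c = np.array([0.70, 0.5, 0.5]) * extent
    breast_r = 0.24 * extent.min()
    db = np.sqrt((((xw - breast_c.reshape(3, 1, 1, 1))) ** 2).sum(axis=0))
    breast = (breast_r - db) / breast_r
    body = _smoothstep(np.maximum(torso * 4.0, breast * 4.0) + 0.5)

    # -- texture ------------------------------------------------------------
    noise = rng.normal(size=shape)
    tex = ndimage.gaussian_filter(noise, sigma=cfg.texture_smoothness_mm / sp)
    tex *= cfg.texture_amplitude / max(tex.std(), 1e-12)
    tissue = np.clip((cfg.tissue_intensity + tex) * body, 0.0, 1.0)

    # -- tumor (source only) -------------------------------------------------
    r_t = rng.uniform(*cfg.tumor_radius_mm)
    jit = rng.uniform(-0.25, 0.25, size=3) * r_t
    tumor_c = breast_c * 0.75 + torso_c * 0.25 + jit
    dt = np.sqrt((((xw - tumor_c.reshape(3, 1, 1, 1))) ** 2).sum(axis=0))
    if np.linalg.norm(tumor_c - breast_c) + r_t > breast_r + 2 * sp:
        raise ValueError("tumor does not fit inside the breast region")
    tumor_soft = _smoothstep((r_t - dt) / sp + 0.5)
    mask = (dt <= r_t).astype(float)
    if mask.sum() == 0:
        raise ValueError("tumor radius below voxel resolution")
    source = np.clip(tissue + cfg.tumor_contrast * tumor_soft * body, 0, 1)

    # -- ground-truth deformation (fixed -> moving) --------------------------
    for attempt in range(cfg.max_jacobian_rejections + 1):
        fieldw = _draw_field(rng, cfg, extent)
        pts = xw.reshape(3, -1).T
        if fieldw.jacobian(pts).min() > 0.1:
            break
    else:
        raise RuntimeError("could not draw a fold-free deformation")
    disp_mm = fieldw.displacement(pts).T.reshape((3,) + shape)
    gt = DisplacementField(disp_mm / sp, spacing.copy(), origin.copy())

    # -- target: warp tumor-free tissue, add scar and noise ------------------
    tissue_img = Image3D(tissue, spacing.copy(), origin.copy())
    target = warp_image(tissue_img, gt).data
    if cfg.scar:
        scar_dir = rng.normal(size=3)
        scar_dir /= np.linalg.norm(scar_dir)
        rel = xw - tumor_c.reshape(3, 1, 1, 1)
        along = np.tensordot(scar_dir, rel, axes=(0, 0))
        radial = np.sqrt(np.maximum((rel * rel).sum(axis=0) - along ** 2, 0))
        streak = _smoothstep((sp - radial) / sp) \
            * _smoothstep((r_t * 1.5 - np.abs(along)) / sp)
        target = np.clip(target - 0.15 * streak * body, 0, 1)
    if cfg.noise_sigma > 0:
        target = np.clip(target + rng.normal(0, cfg.noise_sigma, size=shape),
                         0, 1)

    # -- landmarks at texture extrema, paired through the exact field --------
    src_lms, tgt_lms = _place_landmarks(cfg, rng, tex, body, dt, r_t, fieldw,
                                        shape, sp, extent)

    return PhantomPair(
        source=Image3D(source, spacing.copy(), origin.copy()),
        target=Image3D(target, spacing.copy(), origin.copy()),
        tumor_mask=SegmentationMask(mask, spacing.copy(), origin.copy()),
        gt_field=gt,
        source_landmarks=src_lms,
        target_landmarks=tgt_lms,
        seed=seed,
        analytic_field=fieldw,
    )


def _place_landmarks(cfg, rng, tex, body, dist_tumor, r_t, fieldw, shape, sp,
                     extent):
    """Texture extrema outside the tumor, mapped through the analytic field.

    A target-space landmark p and its source-space partner q satisfy
    q = p + u(p); extrema are found in the source texture, so q is known
    and p is recovered by fixed-point iteration p <- q - u(p).
    """
    score = np.abs(tex) * (body > 0.5)
    score[dist_tumor < r_t + 3 * sp] = 0
    # keep extrema away from the volume border so warped partners stay inside
    border = np.zeros(shape, dtype=bool)
    m = max(2, int(8.0 / sp))
    border[m:-m, m:-m, m:-m] = True
    score[~border] = 0
    peaks = (ndimage.maximum_filter(score, size=3) == score) & (score > 0)
    cand = np.argwhere(peaks)
    order = np.argsort(score[tuple(cand.T)])[::-1]
    cand = cand[order]
    chosen = []
    for c in cand:
        w = c * sp
        if all(np.linalg.norm(w - p) >= cfg.landmark_min_separation_mm
               for p in chosen):
            chosen.append(w)
        if len(chosen) >= cfg.n_landmarks:
            break
    if not chosen:
        raise RuntimeError("no landmark candidates found")
    q = np.array(chosen)
    p = q.copy()
    for _ in range(50):
        p = q - fieldw.displacement(p)
    inside = np.all((p >= 0) & (p <= extent), axis=1)
    q, p = q[inside], p[inside]
    return LandmarkSet(q), LandmarkSet(p)


def generate_dataset(n: int, cfg: PhantomConfig | None = None,
                     out_dir=None, base_seed: int = 0) -> pd.DataFrame:
    """Generate ``n`` phantom cases; optionally write them to disk.

    The on-disk layout per case is
    ``case_XXX/{source,target,tumor_mask,gt_field}.nii.gz`` plus
    ``landmarks_{source,target}.csv``, with a ``manifest.csv`` recording
    the per-case seeds (sufficient to regenerate every case exactly).
    """
    cfg = cfg or PhantomConfig()
    rows = []
    for i in range(n):
        seed = base_seed + i
        pair = generate_pair(cfg, seed=seed)
        row = {"case": f"case_{i:03d}", "seed": seed,
               "n_landmarks": len(pair.source_landmarks)}
        if out_dir is not None:
            cdir = os.path.join(str(out_dir), row["case"])
            os.makedirs(cdir, exist_ok=True)
            write_volume(pair.source, os.path.join(cdir, "source.nii.gz"))
            write_volume(pair.target, os.path.join(cdir, "target.nii.gz"))
            write_volume(pair.tumor_mask,
                         os.path.join(cdir, "tumor_mask.nii.gz"))
            write_field(pair.gt_field, os.path.join(cdir, "gt_field.nii.gz"))
            write_landmarks(pair.source_landmarks,
                            os.path.join(cdir, "landmarks_source.csv"))
            write_landmarks(pair.target_landmarks,
                            os.path.join(cdir, "landmarks_target.csv"))
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(str(out_dir), "manifest.csv"),
                        index=False)
    return manifest
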