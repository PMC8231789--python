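"""Multilevel affine registration by instance optimization.

Gradient-based maximization of local NCC over the 12 parameters of a
world-coordinate affine transform, on a two-level resolution pyramid
(8 mm then 4 mm by default). The transform is parameterized as
``y = L (x - c) + c + t`` about the image center ``c`` and initialized at
identity; each level warm-starts from the best transform of the preceding
level, and the transform with the largest observed NCC is returned
(identity is always in the search history, so the result is never worse
than no alignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .objectives import local_ncc
from .preprocessing import resample_isotropic
from .transforms import affine_coords_tensor
from .volumes_io import AffineTransform, Image3D

__all__ = ["AffineConfig", "register_affine"]


@dataclass
class AffineConfig:
    pyramid_spacings: tuple = (8.0, 4.0)
    learning_rate: float = 0.001
    ncc_window: int = 7
    max_iters_per_level: int = 500
    patience: int = 50
    min_improvement: float = 1e-5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        sp = list(self.pyramid_spacings)
        if any(s2 >= s1 for s1, s2 in zip(sp, sp[1:])):
            raise ValueError("pyramid spacings must strictly decrease")


def _center_to_world(L: np.ndarray, t: np.ndarray,
                     c: np.ndarray) -> AffineTransform:
    """Fold the about-center parameterization into a plain world affine."""
    return AffineTransform(L, c - L @ c + t)


def register_affine(source: Image3D, target: Image3D,
                    cfg: AffineConfig | None = None) -> AffineTransform:
    """Estimate the affine transform aligning ``source`` onto ``target``.

    Expects preprocessed inputs (normalized intensities, isotropic
    spacing, common shape). Returns the world-coordinate pull-back
    transform: resampling ``source`` through it yields the aligned volume.
    """
    cfg = cfg or AffineConfig()
    if source.shape != target.shape or not np.allclose(source.spacing,
                                                       target.spacing):
        raise ValueError("affine registration expects a same-grid pair")
    if source.data.std() < 1e-12 or target.data.std() < 1e-12:
        warnings.warn("degenerate (constant) input; returning identity")
        return AffineTransform.identity()

    extent = (np.array(source.shape) - 1) * source.spacing
    center = source.origin + extent / 2.0

    levels = []
    for s in cfg.pyramid_spacings:
        levels.append((resample_isotropic(source, s),
                       resample_isotropic(target, s)))

    # the translation parameter is expressed in half-extent units so that
    # one optimizer step moves rotations and translations comparably (the
    # linear part is dimensionless); converted to mm when applied
    half = np.maximum(extent / 2.0, 1e-6)
    L = ad.Tensor(np.eye(3), requires_grad=True)
    t = ad.Tensor(np.zeros(3), requires_grad=True)
    candidates = [(np.eye(3), np.zeros(3))]

    for src_lv, tgt_lv in levels:
        opt = ad.Adam([L, t], lr=cfg.learning_rate)
        tgt_t = ad.Tensor(tgt_lv.data)
        best_ncc = -np.inf
        best_state = (L.data.copy(), t.data.copy())
        stall = 0
        ccol = ad.Tensor(center[:, None])
        hcol = ad.Tensor(half[:, None])
        for _ in range(cfg.max_iters_per_level):
            trans = t.reshape(3, 1) * hcol + ccol - (L @ ccol)
            coords = affine_coords_tensor(src_lv, L, trans)
            warped = ad.grid_sample(ad.Tensor(src_lv.data[None]), coords)
            ncc = local_ncc(warped.reshape(src_lv.shape), tgt_t,
                            cfg.ncc_window)
            loss = -ncc
            if not np.isfinite(float(loss)):
                raise RuntimeError("non-finite affine registration loss")
            val = float(ncc)
            if val > best_ncc + cfg.min_improvement:
                best_ncc = val
                best_state = (L.data.copy(), t.data.copy())
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
            opt.zero_grad()
            loss.backward()
            opt.step()
        L.data, t.data = best_state[0].copy(), best_state[1].copy()
        candidates.append(best_state)

    # pick the candidate with the largest NCC at the finest level
    src_f, tgt_f = levels[-1]
    tgt_t = ad.Tensor(tgt_f.data)
    best_val, best = -np.inf, candidates[0]
    for Lc, tc in candidates:
        A = _center_to_world(Lc, tc * half, center)
        coords = affine_coords_tensor(src_f, A.matrix, A.translation)
        warped = ad.grid_sample(ad.Tensor(src_f.data[None]), coords)
        val = float(local_ncc(warped.reshape(src_f.shape), tgt_t,
                              cfg.ncc_window))
        if val > best_val:
            best_val, best = val, (Lc, tc)
    return _center_to_world(best[0], best[1] * half, center)
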