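"""Nonrigid registration by multilevel instance optimization.

A dense displacement field is optimized directly per voxel — no spline
parameterization; smoothness comes from the diffusive term of the loss —
coarse to fine over an 8/4/2 mm pyramid. Each level minimizes the
unsupervised objective (optionally plus the tumor volume penalty, using
the level-resampled mask), retains the best-loss field seen, and the
upsampled best field initializes the next level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .objectives import (ObjectiveConfig, unsupervised_objective,
                         volume_penalty)
from .preprocessing import resample_isotropic
from .volumes_io import DisplacementField, Image3D, SegmentationMask

__all__ = ["InstanceNonrigidConfig", "register_nonrigid_instance"]


@dataclass
class InstanceNonrigidConfig:
    pyramid_spacings: tuple = (8.0, 4.0, 2.0)
    learning_rate: float = 0.02
    alpha: float = 700.0
    ncc_window: int = 5
    use_volume_penalty: bool = False
    volume_penalty_weight: float = 1.0
    max_iters_per_level: int = 500
    patience: int = 50
    min_improvement: float = 1e-5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        sp = list(self.pyramid_spacings)
        if any(s2 >= s1 for s1, s2 in zip(sp, sp[1:])):
            raise ValueError("pyramid spacings must strictly decrease")


def register_nonrigid_instance(source: Image3D, target: Image3D,
                               cfg: InstanceNonrigidConfig | None = None,
                               tumor_mask: SegmentationMask | None = None
                               ) -> DisplacementField:
    """Dense displacement field mapping the target grid into the source.

    Expects an affinely pre-aligned, preprocessed pair. With
    ``cfg.use_volume_penalty`` a tumor mask on the source grid is required
    and the penalty is added at every pyramid level.
    """
    cfg = cfg or InstanceNonrigidConfig()
    if cfg.use_volume_penalty and tumor_mask is None:
        raise ValueError("volume penalty enabled but no tumor mask given")
    if source.shape != target.shape or not np.allclose(source.spacing,
                                                       target.spacing):
        raise ValueError("nonrigid registration expects a same-grid pair")

    ocfg = ObjectiveConfig(ncc_window=cfg.ncc_window, alpha=cfg.alpha,
                           volume_penalty_weight=cfg.volume_penalty_weight)

    levels = []
    for s in cfg.pyramid_spacings:
        if np.allclose(source.spacing, s):
            src_lv, tgt_lv = source, target
            msk_lv = tumor_mask
        else:
            src_lv = resample_isotropic(source, s)
            tgt_lv = resample_isotropic(target, s)
            msk_lv = (resample_isotropic(tumor_mask, s)
                      if tumor_mask is not None else None)
        levels.append((src_lv, tgt_lv, msk_lv))

    u_init = None
    best_field = None
    for idx, (src_lv, tgt_lv, msk_lv) in enumerate(levels):
        if u_init is None:
            u = ad.Tensor(np.zeros((3,) + src_lv.shape), requires_grad=True)
        else:
            up = u_init  # DisplacementField upsampled onto this grid
            u = ad.Tensor(up.data.copy(), requires_grad=True)
        opt = ad.Adam([u], lr=cfg.learning_rate)
        best_loss, best_u, stall = np.inf, u.data.copy(), 0
        for _ in range(cfg.max_iters_per_level):
            loss = unsupervised_objective(src_lv, tgt_lv, u, ocfg)
            if cfg.use_volume_penalty and msk_lv is not None \
                    and msk_lv.data.sum() > 0:
                loss = loss + cfg.volume_penalty_weight \
                    * volume_penalty(msk_lv, u)
            lval = float(loss)
            if not np.isfinite(lval):
                raise RuntimeError("non-finite nonrigid registration loss")
            if lval < best_loss - cfg.min_improvement:
                best_loss, best_u, stall = lval, u.data.copy(), 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
            opt.zero_grad()
            loss.backward()
            opt.step()
        best_field = DisplacementField(best_u, src_lv.spacing.copy(),
                                       src_lv.origin.copy())
        if idx + 1 < len(levels):
            from .transforms import upsample_field
            u_init = upsample_field(best_field, levels[idx + 1][0])
    return best_field
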