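"""Differentiable registration objectives.

The loss family combines:

* a similarity term ``S`` — negative local normalized cross-correlation
  (NCC), the windowed correlation ``sum((M - muM)(F - muF)) / (N sigM sigF)``
  averaged over all fully-contained voxel-centered windows;
* a diffusive regularizer ``R`` — mean squared forward-difference spatial
  gradient of the displacement components;
* a tumor volume penalty — ``V(Ms o u) / V(Ms)``, the ratio of warped to
  original tumor-mask volume, encoding that the tumor is fully resected
  and should be driven to zero volume;
* an inverse-consistency term on the composition of the forward and
  backward fields, for the symmetric training variant.

The unsupervised objective is ``J(M, F, u) = S(M o u, F) + alpha R(u)``;
the semi-supervised variant adds the volume penalty with unit weight; the
symmetric variant sums both directed objectives plus the inverse
consistency of the composed fields.

Units convention: displacement fields are stored in voxel units, but the
regularization and inverse-consistency magnitudes are evaluated on the
field rescaled per component by ``2 / shape_c`` (the half-extent
normalization common in learning-based registration), which is the
convention the default weight ``alpha = 700`` is calibrated against. The
bare :func:`diffusive_regularizer` and :func:`inverse_consistency`
operate on whatever units their input carries.

All functions accept :class:`~tumorbedreg.volumes_io.Image3D` /
:class:`~tumorbedreg.volumes_io.DisplacementField` objects, bare numpy
arrays, or autodiff Tensors, and return a scalar autodiff Tensor (use
``float(...)`` for the value).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .transforms import identity_coords, warp_tensor
from .preprocessing import resample_isotropic

__all__ = ["ObjectiveConfig", "local_ncc", "diffusive_regularizer",
           "volume_penalty", "inverse_consistency", "unsupervised_objective",
           "semi_supervised_objective", "symmetric_objective",
           "multilevel_objective"]

#: windows whose std-dev product falls below this contribute zero to the NCC
NCC_EPS = 1e-5


@dataclass
class ObjectiveConfig:
    """Weights and window sizes of the loss family.

    ``alpha`` follows the published default (700) under the normalized
    field-unit convention described in the module docstring.
    """

    ncc_window: int = 5
    alpha: float = 700.0
    volume_penalty_weight: float = 1.0
    ic_weight: float = 1.0
    level_weights: list | None = None
    normalized_field_units: bool = True

    def __post_init__(self):
        if self.ncc_window < 3 or self.ncc_window % 2 == 0:
            raise ValueError("ncc_window must be odd and >= 3")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


def _arr(x):
    """Unwrap domain objects to Tensors/ndarrays, keeping Tensors live."""
    if isinstance(x, Tensor):
        return x
    if hasattr(x, "data"):
        return np.asarray(x.data, dtype=float)
    return np.asarray(x, dtype=float)


def _grid_shape(x):
    t = _arr(x)
    shape = t.shape
    return shape[1:] if len(shape) == 4 else shape


def local_ncc(m, f, window: int) -> Tensor:
    """Mean windowed NCC of two same-grid volumes; value in [-1, 1].

    Windows are the fully-contained ``window``-cubed neighbourhoods;
    windows with (near-)constant intensity in either image contribute 0.
    """
    if window % 2 == 0:
        raise ValueError("NCC window must be odd")
    mt, ft = ad.as_tensor(_arr(m)), ad.as_tensor(_arr(f))
    if mt.shape != ft.shape:
        raise ValueError("NCC inputs must share a grid")
    if min(mt.shape) < window:
        raise ValueError("volume smaller than the NCC window")
    n = float(window ** 3)
    sm = ad.box_sum_valid(mt, window)
    sf = ad.box_sum_valid(ft, window)
    smm = ad.box_sum_valid(mt * mt, window)
    sff = ad.box_sum_valid(ft * ft, window)
    smf = ad.box_sum_valid(mt * ft, window)
    mu_m, mu_f = sm / n, sf / n
    cross = smf / n - mu_m * mu_f
    var_m = (smm / n - mu_m * mu_m).clip_min(0.0)
    var_f = (sff / n - mu_f * mu_f).clip_min(0.0)
    denom = (var_m * var_f).sqrt()
    valid = (denom.data > NCC_EPS).astype(float)
    safe = denom * valid + (1.0 - valid)
    ncc = cross * valid / safe
    return ncc.mean()


def diffusive_regularizer(u) -> Tensor:
    """Mean squared forward-difference gradient of the field components.

    The mean runs over every finite difference (3 components x 3 axes),
    in the units the field is expressed in.
    """
    ut = ad.as_tensor(_arr(u))
    if min(ut.shape[1:]) < 2:
        raise ValueError("field too small for finite differences")
    total, count = None, 0
    slicers = [
        (np.s_[:, 1:, :, :], np.s_[:, :-1, :, :]),
        (np.s_[:, :, 1:, :], np.s_[:, :, :-1, :]),
        (np.s_[:, :, :, 1:], np.s_[:, :, :, :-1]),
    ]
    for hi, lo in slicers:
        d = ut[hi] - ut[lo]
        sq = (d * d).sum()
        count += int(np.prod(d.shape))
        total = sq if total is None else total + sq
    return total / float(count)


def volume_penalty(mask, u) -> Tensor:
    """Ratio of warped to original tumor volume, ``V(Ms o u) / V(Ms)``.

    Differentiable with respect to ``u``; the warped (fractional) mask is
    obtained by backward trilinear warping, so driving the ratio to zero
    moves every fixed-grid sample position out of the mask support.
    """
    marr = _arr(mask)
    mdata = marr.data if isinstance(marr, Tensor) else marr
    v0 = float(mdata.sum())
    if v0 <= 0:
        raise ValueError("volume penalty needs a non-empty mask")
    ut = ad.as_tensor(_arr(u))
    warped = warp_tensor(ad.as_tensor(marr).reshape((1,) + tuple(mdata.shape)),
                         ut)
    return warped.sum() / v0


def _compose_tensor(u1, u2) -> Tensor:
    """Differentiable field composition ``u1(x) + u2(x + u1(x))``."""
    u1t, u2t = ad.as_tensor(_arr(u1)), ad.as_tensor(_arr(u2))
    ident = Tensor(identity_coords(u1t.shape[1:], dtype=u1t.dtype))
    return u1t + ad.grid_sample(u2t, ident + u1t)


def inverse_consistency(umf, ufm) -> Tensor:
    """Mean squared magnitude of the composed forward/backward fields."""
    u1t, u2t = ad.as_tensor(_arr(umf)), ad.as_tensor(_arr(ufm))
    if u1t.shape != u2t.shape:
        raise ValueError("fields must share a grid")
    comp = _compose_tensor(u1t, u2t)
    nvox = int(np.prod(comp.shape[1:]))
    return (comp * comp).sum() / float(nvox)


def _norm_scale(u) -> Tensor:
    """Rescale a voxel-unit field to half-extent-normalized units."""
    ut = ad.as_tensor(_arr(u))
    fac = (2.0 / np.array(ut.shape[1:], dtype=float)).reshape(3, 1, 1, 1)
    return ut * Tensor(fac)


def unsupervised_objective(m, f, u, cfg: ObjectiveConfig) -> Tensor:
    """Unsupervised loss ``-NCC(M o u, F) + alpha R(u)``."""
    mt = ad.as_tensor(_arr(m))
    ut = ad.as_tensor(_arr(u))
    warped = warp_tensor(mt.reshape((1,) + tuple(mt.shape)), ut)
    sim = local_ncc(warped.reshape(tuple(mt.shape)), f, cfg.ncc_window)
    reg_input = _norm_scale(ut) if cfg.normalized_field_units else ut
    return -sim + cfg.alpha * diffusive_regularizer(reg_input)


def semi_supervised_objective(m, f, u, mask, cfg: ObjectiveConfig) -> Tensor:
    """Unsupervised objective plus the tumor volume penalty."""
    return (unsupervised_objective(m, f, u, cfg)
            + cfg.volume_penalty_weight * volume_penalty(mask, u))


def symmetric_objective(m, f, umf, ufm, cfg: ObjectiveConfig) -> Tensor:
    """Both directed objectives plus inverse consistency of the composition."""
    j_fwd = unsupervised_objective(m, f, umf, cfg)
    j_bwd = unsupervised_objective(f, m, ufm, cfg)
    comp = _compose_tensor(umf, ufm)
    if cfg.normalized_field_units:
        comp = _norm_scale(comp)
    nvox = int(np.prod(comp.shape[1:]))
    ic = (comp * comp).sum() / float(nvox)
    return j_fwd + j_bwd + cfg.ic_weight * ic


def _level_masks(mask, pyr_levels):
    """Resample a finest-grid mask to every pyramid level (coarse->fine)."""
    out = []
    for lv in pyr_levels:
        sp = float(np.asarray(lv.spacing)[0]) if hasattr(lv, "spacing") else None
        if sp is None or mask.shape == _grid_shape(lv):
            out.append(mask)
        else:
            res = resample_isotropic(mask, sp)
            out.append(res)
    return out


def multilevel_objective(pyr_m, pyr_f, fields_per_level, cfg: ObjectiveConfig,
                         mask=None) -> Tensor:
    """Sum of per-level objectives over a coarse-to-fine pyramid.

    ``fields_per_level`` holds one displacement field per pyramid level
    (coarse to fine, grids matching the level grids). When ``mask`` is
    given it is resampled to each level and the volume penalty is added
    at every level.
    """
    levels_m = list(pyr_m)
    levels_f = list(pyr_f)
    fields = list(fields_per_level)
    if not (len(levels_m) == len(levels_f) == len(fields)):
        raise ValueError("need exactly one field per pyramid level")
    weights = cfg.level_weights or [1.0] * len(fields)
    if len(weights) != len(fields):
        raise ValueError("level_weights length must match the level count")
    masks = _level_masks(mask, levels_m) if mask is not None else None
    total = None
    for k, (mlv, flv, ulv) in enumerate(zip(levels_m, levels_f, fields)):
        if mask is None:
            j = unsupervised_objective(mlv, flv, ulv, cfg)
        else:
            j = semi_supervised_objective(mlv, flv, ulv, masks[k], cfg)
        j = j * float(weights[k])
        total = j if total is None else total + j
    return total
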