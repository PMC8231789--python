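"""Loss terms against brute-force scalar oracles, plus analytic properties."""

import numpy as np
import pytest

from tumorbedreg import autodiff as ad
from tumorbedreg.objectives import (ObjectiveConfig, diffusive_regularizer,
                                    inverse_consistency, local_ncc,
                                    multilevel_objective,
                                    semi_supervised_objective,
                                    symmetric_objective,
                                    unsupervised_objective, volume_penalty)
from tumorbedreg.preprocessing import build_pyramid
from tumorbedreg.transforms import identity_coords
from tumorbedreg.volumes_io import Image3D, SegmentationMask

from oracles import (diffusive_brute, inverse_consistency_brute,
                     invert_field_fixed_point, ncc_brute, numerical_gradient,
                     volume_penalty_brute)


def _cfg(**kw):
    return ObjectiveConfig(**kw)


# ---------------------------------------------------------------------------
# local NCC
# ---------------------------------------------------------------------------

def test_ncc_perfect_and_anti_correlation(rng):
    m = rng.random((9, 9, 9))
    assert float(local_ncc(m, m, 5)) == pytest.approx(1.0, abs=1e-6)
    assert float(local_ncc(m, -m + 1.0, 5)) == pytest.approx(-1.0, abs=1e-6)


def test_ncc_matches_brute_force(rng):
    m = rng.random((7, 7, 7))
    f = rng.random((7, 7, 7))
    assert float(local_ncc(m, f, 5)) == pytest.approx(ncc_brute(m, f, 5),
                                                      rel=1e-6)


def test_ncc_affine_intensity_invariance(rng):
    m = rng.random((8, 8, 8))
    for a, b in ((2.0, 0.3), (0.5, -1.0), (10.0, 100.0)):
        assert float(local_ncc(m, a * m + b, 5)) == pytest.approx(1.0,
                                                                  abs=1e-5)


def test_ncc_constant_windows_contribute_zero():
    m = np.zeros((7, 7, 7))
    f = np.zeros((7, 7, 7))
    assert float(local_ncc(m, f, 5)) == 0.0


def test_ncc_rejects_bad_inputs(rng):
    m = rng.random((7, 7, 7))
    with pytest.raises(ValueError):
        local_ncc(m, m, 4)
    with pytest.raises(ValueError):
        local_ncc(m, rng.random((6, 6, 6)), 5)


# ---------------------------------------------------------------------------
# diffusive regularizer
# ---------------------------------------------------------------------------

def test_diffusive_zero_for_constant_field():
    u = np.tile(np.array([1.0, 2.0, -3.0]).reshape(3, 1, 1, 1), (1, 4, 4, 4))
    assert float(diffusive_regularizer(u)) == 0.0


def test_diffusive_linear_field_closed_form():
    k = 0.37
    u = np.zeros((3, 5, 5, 5))
    u[0] = k * identity_coords((5, 5, 5))[0]
    # every forward difference of u_x along x equals k; others are zero
    n_x = 4 * 5 * 5
    n_total = 3 * (3 * 4 * 5 * 5)
    expected = n_x * k ** 2 / n_total
    assert float(diffusive_regularizer(u)) == pytest.approx(expected,
                                                            rel=1e-12)


def test_diffusive_matches_brute_force(rng):
    u = rng.normal(scale=0.3, size=(3, 4, 4, 4))
    assert float(diffusive_regularizer(u)) == pytest.approx(
        diffusive_brute(u), abs=1e-8)


# ---------------------------------------------------------------------------
# volume penalty
# ---------------------------------------------------------------------------

def test_volume_penalty_identity_is_one(phantom_small):
    u = np.zeros((3,) + phantom_small.tumor_mask.shape)
    assert float(volume_penalty(phantom_small.tumor_mask, u)) \
        == pytest.approx(1.0, abs=1e-12)


def test_volume_penalty_matches_brute_force(rng):
    mask = (rng.random((5, 5, 5)) > 0.6).astype(float)
    u = rng.normal(scale=0.5, size=(3, 5, 5, 5))
    assert float(volume_penalty(mask, u)) == pytest.approx(
        volume_penalty_brute(mask, u), abs=1e-10)


def test_volume_penalty_scaling_field_eighth():
    # pull-back through u(x) = (s-1)(x-c) with s=2 samples the mask on a
    # grid expanded about its center: the warped volume is ~(1/s)^3
    shape = (33, 33, 33)
    c = 16.0
    xw = identity_coords(shape)
    dist = np.sqrt(((xw - c) ** 2).sum(axis=0))
    mask = (dist <= 12.0).astype(float)
    u = (2.0 - 1.0) * (xw - c)
    ratio = float(volume_penalty(mask, u))
    assert ratio == pytest.approx(1.0 / 8.0, rel=0.1)


def test_volume_penalty_translation_out_of_volume_goes_to_zero():
    shape = (12, 12, 12)
    xw = identity_coords(shape)
    mask = (np.sqrt(((xw - 6.0) ** 2).sum(axis=0)) <= 3.0).astype(float)
    u = np.zeros((3,) + shape)
    u[0] = 50.0  # samples land far outside; border-clamped background is 0
    assert float(volume_penalty(mask, u)) == pytest.approx(0.0, abs=1e-12)


def test_volume_penalty_invariant_to_mask_scaling(rng):
    mask = (rng.random((6, 6, 6)) > 0.5).astype(float)
    u = rng.normal(scale=0.4, size=(3, 6, 6, 6))
    full = float(volume_penalty(mask, u))
    half = float(volume_penalty(0.5 * mask, u))
    assert half == pytest.approx(full, rel=1e-12)


def test_volume_penalty_empty_mask_raises():
    with pytest.raises(ValueError):
        volume_penalty(np.zeros((4, 4, 4)), np.zeros((3, 4, 4, 4)))


# ---------------------------------------------------------------------------
# inverse consistency
# ---------------------------------------------------------------------------

def test_inverse_consistency_zero_cases():
    z = np.zeros((3, 6, 6, 6))
    assert float(inverse_consistency(z, z)) == 0.0
    t = np.tile(np.array([1.0, -0.5, 0.25]).reshape(3, 1, 1, 1), (1, 6, 6, 6))
    # constant +t then -t compose to zero away from the clamped border
    ic = float(inverse_consistency(t[:, 1:-1, 1:-1, 1:-1] * 0 + t[:, :6, :6,
                                   :6][:, 1:-1, 1:-1, 1:-1],
                                   -t[:, 1:-1, 1:-1, 1:-1]))
    assert ic == pytest.approx(0.0, abs=1e-10)


def test_inverse_consistency_with_numerical_inverse(rng):
    from scipy.ndimage import gaussian_filter
    u = np.stack([gaussian_filter(rng.normal(size=(8, 8, 8)), 2.0)
                  for _ in range(3)])
    u *= 0.8 / np.abs(u).max()
    inv = invert_field_fixed_point(u)
    assert float(inverse_consistency(u, inv)) < 1e-2


def test_inverse_consistency_matches_brute_force(rng):
    u1 = rng.normal(scale=0.3, size=(3, 5, 5, 5))
    u2 = rng.normal(scale=0.3, size=(3, 5, 5, 5))
    assert float(inverse_consistency(u1, u2)) == pytest.approx(
        inverse_consistency_brute(u1, u2), abs=1e-10)


# ---------------------------------------------------------------------------
# combined objectives
# ---------------------------------------------------------------------------

def test_unsupervised_identity_pair_is_minus_one(rng):
    m = rng.random((9, 9, 9))
    u = np.zeros((3, 9, 9, 9))
    val = float(unsupervised_objective(m, m, u, _cfg()))
    assert val == pytest.approx(-1.0, abs=1e-6)


def test_unsupervised_alpha_zero_is_pure_dissimilarity(rng):
    m, f = rng.random((8, 8, 8)), rng.random((8, 8, 8))
    u = rng.normal(scale=0.2, size=(3, 8, 8, 8))
    from tumorbedreg.transforms import warp_image, DisplacementField
    val = float(unsupervised_objective(m, f, u, _cfg(alpha=0.0)))
    from tumorbedreg.volumes_io import Image3D
    img = Image3D(m)
    warped = warp_image(img, DisplacementField(u)).data
    assert val == pytest.approx(-ncc_brute(warped, f, 5), abs=1e-6)


def test_unsupervised_monotone_in_alpha(rng):
    m, f = rng.random((8, 8, 8)), rng.random((8, 8, 8))
    u = rng.normal(scale=0.5, size=(3, 8, 8, 8))
    vals = [float(unsupervised_objective(m, f, u, _cfg(alpha=a)))
            for a in (0.0, 10.0, 700.0, 1e4)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_semi_supervised_adds_unit_weight_penalty(phantom_small):
    src = phantom_small.source
    mask = phantom_small.tumor_mask
    u = np.zeros((3,) + src.shape)
    unsup = float(unsupervised_objective(src, src, u, _cfg()))
    semi = float(semi_supervised_objective(src, src, u, mask, _cfg()))
    assert semi == pytest.approx(unsup + 1.0, abs=1e-10)


def test_symmetric_identity_pair_is_minus_two(rng):
    m = rng.random((9, 9, 9))
    z = np.zeros((3, 9, 9, 9))
    val = float(symmetric_objective(m, m, z, z, _cfg()))
    assert val == pytest.approx(-2.0, abs=1e-5)


def test_symmetric_objective_is_symmetric(rng):
    m, f = rng.random((8, 8, 8)), rng.random((8, 8, 8))
    umf = rng.normal(scale=0.2, size=(3, 8, 8, 8))
    ufm = rng.normal(scale=0.2, size=(3, 8, 8, 8))
    a = float(symmetric_objective(m, f, umf, ufm, _cfg()))
    b = float(symmetric_objective(f, m, ufm, umf, _cfg()))
    # exchanging (m, umf) <-> (f, ufm) changes only the IC composition order
    ic_ab = float(inverse_consistency(umf, ufm))
    ic_ba = float(inverse_consistency(ufm, umf))
    fac = (2.0 / 8.0) ** 2
    assert a - fac * ic_ab == pytest.approx(b - fac * ic_ba, abs=1e-8)


def test_multilevel_reduces_to_single_level(phantom_small):
    src, tgt = phantom_small.source, phantom_small.target
    u = np.zeros((3,) + src.shape)
    single = float(unsupervised_objective(src, tgt, u, _cfg()))
    multi = float(multilevel_objective([src], [tgt], [u], _cfg()))
    assert multi == pytest.approx(single, abs=1e-12)


def test_multilevel_identical_pyramids_zero_fields(rng, phantom_small):
    # textured everywhere so no window is intensity-degenerate
    src = Image3D(rng.random((32, 32, 32)), np.full(3, 2.0))
    pyr = build_pyramid(src, (8.0, 4.0, 2.0))
    fields = [np.zeros((3,) + lv.shape) for lv in pyr]
    val = float(multilevel_objective(pyr, pyr, fields, _cfg()))
    assert val == pytest.approx(-3.0, abs=1e-4)
    mask = SegmentationMask(phantom_small.tumor_mask.data,
                            src.spacing, src.origin)
    with_mask = float(multilevel_objective(pyr, pyr, fields, _cfg(),
                                           mask=mask))
    assert with_mask == pytest.approx(val + 3.0, abs=1e-3)  # +1 per level


def test_multilevel_level_count_mismatch(phantom_small):
    pyr = build_pyramid(phantom_small.source, (8.0, 4.0, 2.0))
    with pytest.raises(ValueError):
        multilevel_objective(pyr, pyr, [np.zeros((3, 4, 4, 4))], _cfg())


def test_multilevel_three_level_fixture_oracle(phantom_small):
    src, tgt = phantom_small.source, phantom_small.target
    pyr_m = build_pyramid(src, (8.0, 4.0, 2.0))
    pyr_f = build_pyramid(tgt, (8.0, 4.0, 2.0))
    rng = np.random.default_rng(0)
    fields = [rng.normal(scale=0.2, size=(3,) + lv.shape) for lv in pyr_m]
    total = float(multilevel_objective(pyr_m, pyr_f, fields, _cfg()))
    per_level = sum(float(unsupervised_objective(m, f, u, _cfg()))
                    for m, f, u in zip(pyr_m, pyr_f, fields))
    assert total == pytest.approx(per_level, rel=1e-12)


# ---------------------------------------------------------------------------
# autodiff gradients vs central differences (5^3 fixtures)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("objective", ["unsupervised", "semi", "symmetric",
                                       "penalty", "ic"])
def test_objective_gradients_match_central_differences(rng, objective):
    m = rng.random((5, 5, 5))
    f = rng.random((5, 5, 5))
    mask = (rng.random((5, 5, 5)) > 0.5).astype(float)
    u2 = rng.normal(scale=0.2, size=(3, 5, 5, 5))
    cfg = _cfg(alpha=10.0)
    fns = {
        "unsupervised": lambda t: unsupervised_objective(m, f, t, cfg),
        "semi": lambda t: semi_supervised_objective(m, f, t, mask, cfg),
        "symmetric": lambda t: symmetric_objective(m, f, t, ad.Tensor(u2),
                                                   cfg),
        "penalty": lambda t: volume_penalty(mask, t),
        "ic": lambda t: inverse_consistency(t, ad.Tensor(u2)),
    }
    fn = fns[objective]
    u = rng.normal(scale=0.2, size=(3, 5, 5, 5))
    t = ad.Tensor(u.copy(), requires_grad=True)
    fn(t).backward()
    num = numerical_gradient(lambda a: float(fn(ad.Tensor(a))), u)
    denom = np.maximum(np.abs(num), 1e-4)
    assert (np.abs(t.grad - num) / denom).max() < 1e-3
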