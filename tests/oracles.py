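"""Independent scalar reference implementations used as test oracles.

Everything here is written as plain per-voxel loops / closed forms,
deliberately independent of the package's vectorized implementations.
"""

import numpy as np

NCC_EPS = 1e-5


def trilinear_sample(vol, x, y, z):
    """Scalar trilinear interpolation with border clamping."""
    sx, sy, sz = vol.shape
    x = min(max(x, 0.0), sx - 1)
    y = min(max(y, 0.0), sy - 1)
    z = min(max(z, 0.0), sz - 1)
    x0 = min(int(np.floor(x)), sx - 2) if sx > 1 else 0
    y0 = min(int(np.floor(y)), sy - 2) if sy > 1 else 0
    z0 = min(int(np.floor(z)), sz - 2) if sz > 1 else 0
    fx, fy, fz = x - x0, y - y0, z - z0
    x1, y1, z1 = min(x0 + 1, sx - 1), min(y0 + 1, sy - 1), min(z0 + 1, sz - 1)
    out = 0.0
    for bx, wx in ((x0, 1 - fx), (x1, fx)):
        for by, wy in ((y0, 1 - fy), (y1, fy)):
            for bz, wz in ((z0, 1 - fz), (z1, fz)):
                out += wx * wy * wz * vol[bx, by, bz]
    return out


def warp_brute(vol, u):
    """Backward warp computed voxel by voxel."""
    out = np.zeros_like(vol, dtype=float)
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                out[i, j, k] = trilinear_sample(
                    vol, i + u[0, i, j, k], j + u[1, i, j, k],
                    k + u[2, i, j, k])
    return out


def compose_brute(u1, u2):
    """(u2 after u1)(x) = u1(x) + u2(x + u1(x)), per voxel."""
    out = np.zeros_like(u1)
    for i in range(u1.shape[1]):
        for j in range(u1.shape[2]):
            for k in range(u1.shape[3]):
                x = i + u1[0, i, j, k]
                y = j + u1[1, i, j, k]
                z = k + u1[2, i, j, k]
                for c in range(3):
                    out[c, i, j, k] = u1[c, i, j, k] + trilinear_sample(
                        u2[c], x, y, z)
    return out


def ncc_brute(m, f, w):
    """Mean windowed NCC over fully-contained windows (population stats)."""
    r = w // 2
    vals = []
    for i in range(r, m.shape[0] - r):
        for j in range(r, m.shape[1] - r):
            for k in range(r, m.shape[2] - r):
                wm = m[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1]
                wf = f[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1]
                var_m = max(wm.var(), 0.0)
                var_f = max(wf.var(), 0.0)
                denom = np.sqrt(var_m * var_f)
                if denom > NCC_EPS:
                    cross = (wm * wf).mean() - wm.mean() * wf.mean()
                    vals.append(cross / denom)
                else:
                    vals.append(0.0)
    return float(np.mean(vals))


def diffusive_brute(u):
    """Mean squared forward difference over components and axes."""
    sq, n = 0.0, 0
    for c in range(3):
        for ax in range(3):
            d = np.diff(u[c], axis=ax)
            sq += float((d ** 2).sum())
            n += d.size
    return sq / n


def volume_penalty_brute(mask, u):
    return warp_brute(mask, u).sum() / mask.sum()


def inverse_consistency_brute(umf, ufm):
    comp = compose_brute(umf, ufm)
    return float((comp ** 2).sum(axis=0).mean())


def numerical_gradient(fn, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


def invert_field_fixed_point(u, iters=60):
    """Numerically invert a displacement field by fixed-point iteration."""
    from tumorbedreg.transforms import identity_coords
    from tumorbedreg import autodiff as ad

    inv = np.zeros_like(u)
    ident = identity_coords(u.shape[1:])
    for _ in range(iters):
        coords = ident + inv
        u_at = ad.grid_sample(ad.Tensor(u), ad.Tensor(coords)).data
        inv = -u_at
    return inv
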