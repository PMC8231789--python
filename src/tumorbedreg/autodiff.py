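"""Reverse-mode automatic differentiation over numpy arrays.

This module provides the differentiation machinery used by the registration
objectives, the instance-optimization loops, and the displacement network:
a :class:`Tensor` wrapping an ``numpy.ndarray`` together with the handful of
vectorized operations the method needs — elementwise algebra, reductions,
trilinear grid sampling (differentiable in both the sampled values and the
sampling coordinates), 3-D convolution, box sums for windowed statistics,
average pooling — and an :class:`Adam` optimizer.

Gradients are accumulated by a topological-order sweep from the scalar loss.
Only operations whose inputs require gradients record a backward closure, so
inference-style evaluation carries no tape overhead.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "as_tensor", "stack", "concatenate", "grid_sample",
           "conv3d", "box_sum_valid", "avg_pool3d", "group_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad = self.grad + np.asarray(g, dtype=self.data.dtype)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- elementwise algebra ----------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data + o.data, req)
        if req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if o.requires_grad:
                    o._accumulate(_unbroadcast(g, o.shape))
            out._parents, out._backward = (self, o), bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        if self.requires_grad:
            out._parents, out._backward = (self,), lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data * o.data, req)
        if req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * o.data, self.shape))
                if o.requires_grad:
                    o._accumulate(_unbroadcast(g * self.data, o.shape))
            out._parents, out._backward = (self, o), bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data / o.data, req)
        if req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / o.data, self.shape))
                if o.requires_grad:
                    o._accumulate(_unbroadcast(-g * self.data / (o.data ** 2), o.shape))
            out._parents, out._backward = (self, o), bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        if self.requires_grad:
            def bw(g):
                self._accumulate(g * p * self.data ** (p - 1))
            out._parents, out._backward = (self,), bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), self.requires_grad)
        if self.requires_grad:
            def bw(g):
                self._accumulate(g * 0.5 / np.maximum(np.sqrt(self.data), 1e-300))
            out._parents, out._backward = (self,), bw
        return out

    def clip_min(self, lo: float):
        """max(x, lo); subgradient 0 where x < lo."""
        mask = self.data >= lo
        out = Tensor(np.where(mask, self.data, lo), self.requires_grad)
        if self.requires_grad:
            out._parents, out._backward = (self,), lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data >= 0
        out = Tensor(np.where(mask, self.data, slope * self.data), self.requires_grad)
        if self.requires_grad:
            def bw(g):
                self._accumulate(g * np.where(mask, 1.0, slope))
            out._parents, out._backward = (self,), bw
        return out

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if self.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad)
        if self.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                full[key] = g
                self._accumulate(full)
            out._parents, out._backward = (self,), bw
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if self.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape))
            out._parents, out._backward = (self,), bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def __matmul__(self, other):
        o = as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data @ o.data, req)
        if req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g @ o.data.T)
                if o.requires_grad:
                    o._accumulate(self.data.T @ g)
            out._parents, out._backward = (self, o), bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in ts)
    out = Tensor(np.stack([t.data for t in ts], axis=axis), req)
    if req:
        def bw(g):
            pieces = np.split(g, len(ts), axis=axis)
            for t, p in zip(ts, pieces):
                if t.requires_grad:
                    t._accumulate(np.squeeze(p, axis=axis))
        out._parents, out._backward = tuple(ts), bw
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in ts)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), req)
    if req:
        splits = np.cumsum([t.shape[axis] for t in ts])[:-1]

        def bw(g):
            for t, p in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(p)
        out._parents, out._backward = tuple(ts), bw
    return out


# ---------------------------------------------------------------------------
# Trilinear grid sampling
# ---------------------------------------------------------------------------

def grid_sample(values, coords, coord_grad_mask: bool = True) -> Tensor:
    """Sample ``values`` at fractional voxel ``coords`` with trilinear weights.

    Parameters
    ----------
    values : Tensor, shape (C, X, Y, Z)
        Channel-first scalar fields to sample.
    coords : Tensor, shape (3, *out_shape)
        Voxel-index coordinates into the grid of ``values``. Out-of-bounds
        coordinates are clamped to the border (border/replicate policy), and
        their coordinate gradient is zeroed when ``coord_grad_mask`` is set.

    Returns
    -------
    Tensor, shape (C, *out_shape)
    """
    v, c = as_tensor(values), as_tensor(coords)
    if v.ndim != 4 or c.shape[0] != 3:
        raise ValueError("grid_sample expects values (C,X,Y,Z), coords (3,...)")
    C = v.shape[0]
    S = v.shape[1:]
    out_shape = c.shape[1:]
    P = c.data.reshape(3, -1)
    N = P.shape[1]
    hi = np.array(S, dtype=P.dtype).reshape(3, 1) - 1.0
    cl = np.clip(P, 0.0, hi)
    x0 = np.minimum(np.floor(cl), hi - 1).astype(np.int64)
    x0 = np.maximum(x0, 0)
    f = cl - x0
    V = v.data.reshape(C, -1)
    SY, SZ = S[1], S[2]

    corner_idx, corner_w = [], []
    for bx in (0, 1):
        wx = f[0] if bx else 1.0 - f[0]
        ix = np.minimum(x0[0] + bx, S[0] - 1)
        for by in (0, 1):
            wy = f[1] if by else 1.0 - f[1]
            iy = np.minimum(x0[1] + by, S[1] - 1)
            for bz in (0, 1):
                wz = f[2] if bz else 1.0 - f[2]
                iz = np.minimum(x0[2] + bz, S[2] - 1)
                corner_idx.append((ix * SY + iy) * SZ + iz)
                corner_w.append(wx * wy * wz)

    out = np.zeros((C, N), dtype=np.result_type(v.dtype, c.dtype))
    for idx, w in zip(corner_idx, corner_w):
        out += V[:, idx] * w

    req = v.requires_grad or c.requires_grad
    res = Tensor(out.reshape((C,) + out_shape), req)
    if req:
        nsvox = int(np.prod(S))
        inb = ((P > 0.0) & (P < hi)).astype(f.dtype) if coord_grad_mask else 1.0

        def bw(g):
            g2 = g.reshape(C, N)
            if v.requires_grad:
                dv = np.zeros(C * nsvox, dtype=v.dtype)
                ch_off = (np.arange(C, dtype=np.int64) * nsvox)[:, None]
                for idx, w in zip(corner_idx, corner_w):
                    comb = (ch_off + idx[None, :]).ravel()
                    dv += np.bincount(comb, weights=(g2 * w).ravel(),
                                      minlength=C * nsvox)
                v._accumulate(dv.reshape(v.shape))
            if c.requires_grad:
                dcoord = np.zeros((3, N), dtype=c.dtype)
                k = 0
                for bx in (0, 1):
                    for by in (0, 1):
                        for bz in (0, 1):
                            val = (V[:, corner_idx[k]] * g2).sum(axis=0)
                            wx = f[0] if bx else 1.0 - f[0]
                            wy = f[1] if by else 1.0 - f[1]
                            wz = f[2] if bz else 1.0 - f[2]
                            sx = 1.0 if bx else -1.0
                            sy = 1.0 if by else -1.0
                            sz = 1.0 if bz else -1.0
                            dcoord[0] += val * sx * wy * wz
                            dcoord[1] += val * wx * sy * wz
                            dcoord[2] += val * wx * wy * sz
                            k += 1
                dcoord *= inb
                c._accumulate(dcoord.reshape(c.shape))
        res._parents, res._backward = (v, c), bw
    return res


# ---------------------------------------------------------------------------
# 3-D convolution (stride 1, same padding, odd kernel)
# ---------------------------------------------------------------------------

def _sliding_windows(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-padded (Cin, X, Y, Z, k, k, k) window view for a same-size conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    return np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                    axis=(1, 2, 3))


def _conv3d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (Cin,X,Y,Z), w (Cout,Cin,k,k,k) -> (Cout,X,Y,Z), stride 1, same pad."""
    win = _sliding_windows(x, w.shape[-1])
    return np.einsum("cxyzijk,ocijk->oxyz", win, w, optimize=True)


def conv3d(x, w, b) -> Tensor:
    """Channel-first 3-D convolution, stride 1, zero 'same' padding."""
    xt, wt, bt = as_tensor(x), as_tensor(w), as_tensor(b)
    out = _conv3d_raw(xt.data, wt.data) + bt.data.reshape(-1, 1, 1, 1)
    req = xt.requires_grad or wt.requires_grad or bt.requires_grad
    res = Tensor(out, req)
    if req:
        def bw(g):
            if bt.requires_grad:
                bt._accumulate(g.sum(axis=(1, 2, 3)))
            if wt.requires_grad:
                win = _sliding_windows(xt.data, wt.shape[-1])
                dw = np.einsum("cxyzijk,oxyz->ocijk", win, g, optimize=True)
                wt._accumulate(dw)
            if xt.requires_grad:
                wflip = wt.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                xt._accumulate(_conv3d_raw(g, np.ascontiguousarray(wflip)))
        res._parents, res._backward = (xt, wt, bt), bw
    return res


# ---------------------------------------------------------------------------
# Box sums (valid windows, trailing three axes) — backbone of local NCC
# ---------------------------------------------------------------------------

def _box_sum_valid_np(a: np.ndarray, w: int) -> np.ndarray:
    for ax in (-3, -2, -1):
        c = np.cumsum(a, axis=ax, dtype=a.dtype)
        zshape = list(c.shape)
        zshape[ax] = 1
        cp = np.concatenate([np.zeros(zshape, dtype=a.dtype), c], axis=ax)
        n = a.shape[ax]
        idx_hi = [slice(None)] * a.ndim
        idx_lo = [slice(None)] * a.ndim
        idx_hi[ax] = slice(w, n + 1)
        idx_lo[ax] = slice(0, n + 1 - w)
        a = cp[tuple(idx_hi)] - cp[tuple(idx_lo)]
    return a


def box_sum_valid(x, w: int) -> Tensor:
    """Sum over all fully-contained w^3 windows of the trailing three axes."""
    xt = as_tensor(x)
    out = Tensor(_box_sum_valid_np(xt.data, w), xt.requires_grad)
    if xt.requires_grad:
        def bw(g):
            pad = [(0, 0)] * (g.ndim - 3) + [(w - 1, w - 1)] * 3
            xt._accumulate(_box_sum_valid_np(np.pad(g, pad), w))
        out._parents, out._backward = (xt,), bw
    return out


def avg_pool3d(x, factor: int = 2) -> Tensor:
    """Average pooling over non-overlapping factor^3 blocks; (C,X,Y,Z) input."""
    xt = as_tensor(x)
    C, X, Y, Z = xt.shape
    f = factor
    if X % f or Y % f or Z % f:
        raise ValueError("avg_pool3d requires spatial shape divisible by factor")
    r = xt.data.reshape(C, X // f, f, Y // f, f, Z // f, f)
    out = Tensor(r.mean(axis=(2, 4, 6)), xt.requires_grad)
    if xt.requires_grad:
        def bw(g):
            gg = np.broadcast_to(
                g[:, :, None, :, None, :, None],
                (C, X // f, f, Y // f, f, Z // f, f)) / f ** 3
            xt._accumulate(gg.reshape(xt.shape))
        out._parents, out._backward = (xt,), bw
    return out


def group_norm(x, gamma, beta, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over (C, X, Y, Z) features."""
    xt = as_tensor(x)
    C = xt.shape[0]
    if C % groups:
        raise ValueError("channels must be divisible by the group count")
    spatial = xt.shape[1:]
    g = xt.reshape(groups, -1)
    mu = g.mean(axis=1, keepdims=True)
    cen = g - mu
    var = (cen * cen).mean(axis=1, keepdims=True)
    xn = cen / (var + eps).sqrt()
    xn = xn.reshape((C,) + spatial)
    gam = as_tensor(gamma).reshape(C, 1, 1, 1)
    bet = as_tensor(beta).reshape(C, 1, 1, 1)
    return xn * gam + bet


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; state initialized deterministically to zero."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
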