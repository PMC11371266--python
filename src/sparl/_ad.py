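"""Minimal reverse-mode automatic differentiation on numpy arrays.

The unrolled training of the mask-generator parameters needs exact gradients
through a few dozen algorithm iterations.  Rather than pulling in a deep
learning framework, this module provides a small tape: a :class:`Var` wraps an
``ndarray`` and records the backward closure of the operation that produced
it.  Only the primitives the solvers use are implemented — arithmetic,
``sum``, ``abs``, ``clip``, the logistic function, same-size 2-D convolution
with its exact adjoint, and uniform-grid linear-spline evaluation.

Every function in this module accepts either a plain ``ndarray`` or a
:class:`Var` and returns the same kind, so the solver code has a single code
path for inference (numpy) and training (taped).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Var",
    "val",
    "is_var",
    "stop_grad",
    "asum",
    "aabs",
    "clip",
    "sigmoid",
    "reshape",
    "conv2d",
    "conv2d_adjoint",
    "spline_channels",
]


def val(x):
    """Underlying ndarray of ``x`` (identity on plain arrays)."""
    if isinstance(x, Var):
        return x.value
    arr = np.asarray(x)
    if np.iscomplexobj(arr):
        return arr
    return np.asarray(arr, dtype=np.float64)


def is_var(*xs) -> bool:
    return any(isinstance(x, Var) for x in xs)


def _sum_to(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


class Var:
    """Node of the tape: a value plus the closure that propagates gradients."""

    __slots__ = ("value", "parents", "bw", "grad")
    __array_ufunc__ = None  # force ndarray <op> Var to defer to Var

    def __init__(self, value, parents=(), bw=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = tuple(p for p in parents if isinstance(p, Var))
        self.bw = bw
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def detach(self) -> np.ndarray:
        return self.value

    def item(self) -> float:
        return float(self.value)

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate ``.grad`` on every leaf reachable from ``self``."""
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.bw is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in node.bw(g):
                if p is None or not isinstance(p, Var):
                    continue
                pg = _sum_to(np.asarray(pg, dtype=np.float64), p.value.shape)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        ov = val(other)
        return Var(self.value + ov, (self, other),
                   lambda g, a=self, b=other: [(a, g), (b, g) if isinstance(b, Var) else (None, None)])

    __radd__ = __add__

    def __sub__(self, other):
        ov = val(other)
        return Var(self.value - ov, (self, other),
                   lambda g, a=self, b=other: [(a, g), (b, -g) if isinstance(b, Var) else (None, None)])

    def __rsub__(self, other):
        ov = val(other)
        return Var(ov - self.value, (self,), lambda g, a=self: [(a, -g)])

    def __neg__(self):
        return Var(-self.value, (self,), lambda g, a=self: [(a, -g)])

    def __mul__(self, other):
        ov = val(other)
        sv = self.value
        return Var(sv * ov, (self, other),
                   lambda g, a=self, b=other, av=sv, bv=ov: [
                       (a, g * bv),
                       (b, g * av) if isinstance(b, Var) else (None, None)])

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Var):
            raise TypeError("Var/Var division is not supported")
        return self * (1.0 / val(other))


def stop_grad(x):
    """Detach ``x`` from the tape (returns a plain ndarray)."""
    return val(x)


def _unary(x, out, dfun):
    if isinstance(x, Var):
        return Var(out, (x,), lambda g, a=x: [(a, dfun(g))])
    return out


def asum(x):
    xv = val(x)
    out = np.asarray(xv.sum())
    return _unary(x, out, lambda g, shape=xv.shape: np.broadcast_to(g, shape))


def aabs(x):
    xv = val(x)
    s = np.sign(xv)
    return _unary(x, np.abs(xv), lambda g, s=s: g * s)


def sigmoid(x):
    xv = val(x)
    out = 1.0 / (1.0 + np.exp(-xv))
    return _unary(x, out, lambda g, o=out: g * o * (1.0 - o))


def reshape(x, shape):
    xv = val(x)
    out = xv.reshape(shape)
    return _unary(x, out, lambda g, s=xv.shape: g.reshape(s))


def clip(x, lo, hi):
    """Componentwise clamp to ``[lo, hi]``; the bounds may be taped scalars."""
    xv, lov, hiv = val(x), val(lo), val(hi)
    out = np.clip(xv, lov, hiv)
    if not is_var(x, lo, hi):
        return out
    below = xv < lov
    above = xv > hiv

    def bw(g):
        res = []
        if isinstance(x, Var):
            res.append((x, np.where(below | above, 0.0, g)))
        if isinstance(lo, Var):
            res.append((lo, np.asarray((g * below).sum())))
        if isinstance(hi, Var):
            res.append((hi, np.asarray((g * above).sum())))
        return res

    return Var(out, (x, lo, hi), bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pad(x, p, padding):
    mode = "constant" if padding == "zero" else "wrap"
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode=mode)


def _conv_fwd(x, k, padding, groups):
    B, Cin, H, W = x.shape
    Cout, Cpg, kh, kw = k.shape
    if kh % 2 != 1 or kh != kw:
        raise ValueError("kernels must be square with odd size")
    if Cin != Cpg * groups or Cout % groups:
        raise ValueError("channel/group mismatch")
    p = kh // 2
    win = sliding_window_view(_pad(x, p, padding), (kh, kw), axis=(2, 3))
    if groups == 1:
        return np.einsum("bchwij,ocij->bohw", win, k, optimize=True)
    if groups == Cin and Cpg == 1 and Cout == Cin:
        return np.einsum("bchwij,cij->bchw", win, k[:, 0], optimize=True)
    opg = Cout // groups
    outs = [np.einsum("bchwij,ocij->bohw",
                      win[:, g * Cpg:(g + 1) * Cpg],
                      k[g * opg:(g + 1) * opg], optimize=True)
            for g in range(groups)]
    return np.concatenate(outs, axis=1)


def _transpose_kernel(k, groups):
    """Kernel realizing the adjoint convolution: spatial flip + channel swap."""
    kf = k[:, :, ::-1, ::-1]
    Cout, Cpg, kh, kw = k.shape
    if groups == 1:
        return np.ascontiguousarray(kf.transpose(1, 0, 2, 3))
    if Cpg == 1 and Cout == groups:  # depthwise
        return np.ascontiguousarray(kf)
    opg = Cout // groups
    blocks = [np.ascontiguousarray(kf[g * opg:(g + 1) * opg].transpose(1, 0, 2, 3))
              for g in range(groups)]
    return np.concatenate(blocks, axis=0)


def _conv_bwd_x(gy, k, padding, groups, in_shape):
    """Transpose of ``x -> conv(x, k)``; also the forward of the adjoint op.

    For 'same' correlation with symmetric zero or circular padding, the
    adjoint is again a 'same' correlation, with the spatially flipped and
    channel-transposed kernel.
    """
    return _conv_fwd(gy, _transpose_kernel(k, groups), padding, groups)


def _conv_bwd_k(gy, x, padding, groups, kshape):
    Cout, Cpg, kh, kw = kshape
    B, Cin, H, W = x.shape
    p = kh // 2
    win = sliding_window_view(_pad(x, p, padding), (kh, kw), axis=(2, 3))
    if groups == 1:
        return np.einsum("bohw,bchwij->ocij", gy, win, optimize=True)
    if groups == Cin and Cpg == 1 and Cout == Cin:
        return np.einsum("bchw,bchwij->cij", gy, win, optimize=True)[:, None]
    opg = Cout // groups
    gk = np.empty(kshape)
    for g in range(groups):
        gk[g * opg:(g + 1) * opg] = np.einsum(
            "bohw,bchwij->ocij", gy[:, g * opg:(g + 1) * opg],
            win[:, g * Cpg:(g + 1) * Cpg], optimize=True)
    return gk


def conv2d(x, k, *, padding="zero", groups=1):
    """Same-size multi-channel 2-D cross-correlation, ``(B,Cin,H,W) -> (B,Cout,H,W)``."""
    xv, kv = val(x), val(k)
    out = _conv_fwd(xv, kv, padding, groups)
    if not is_var(x, k):
        return out

    def bw(g):
        res = []
        if isinstance(x, Var):
            res.append((x, _conv_bwd_x(g, kv, padding, groups, xv.shape)))
        if isinstance(k, Var):
            res.append((k, _conv_bwd_k(g, xv, padding, groups, kv.shape)))
        return res

    return Var(out, (x, k), bw)


def conv2d_adjoint(y, k, *, padding="zero", groups=1):
    """Exact adjoint of :func:`conv2d` in its first argument."""
    yv, kv = val(y), val(k)
    Cout, Cpg, kh, kw = kv.shape
    B = yv.shape[0]
    in_shape = (B, Cpg * groups, yv.shape[2], yv.shape[3])
    out = _conv_bwd_x(yv, kv, padding, groups, in_shape)
    if not is_var(y, k):
        return out

    def bw(g):
        res = []
        if isinstance(y, Var):
            res.append((y, _conv_fwd(g, kv, padding, groups)))
        if isinstance(k, Var):
            # <g, A(k)^T y> = <A(k) g, y>  =>  same bilinear form as conv's dk
            res.append((k, _conv_bwd_k(yv, g, padding, groups, kv.shape)))
        return res

    return Var(out, (y, k), bw)


# ---------------------------------------------------------------------------
# linear splines on a uniform grid
# ---------------------------------------------------------------------------

def spline_channels(x, d, delta, x0):
    """Per-channel piecewise-linear interpolation with linear extrapolation.

    ``x`` has shape ``(B, C, H, W)``; ``d`` holds the knot values, one row of
    length ``n`` per channel, on the uniform grid ``x0 + delta*{0,...,n-1}``.
    Outside the grid the boundary segment's slope is continued, which is the
    natural behaviour of clamping the cell index.
    """
    xv, dv = val(x), val(d)
    B, C, H, W = xv.shape
    n = dv.shape[1]
    t = (xv - x0) / delta
    i = np.clip(np.floor(t).astype(np.int64), 0, n - 2)
    frac = t - i
    cidx = np.broadcast_to(np.arange(C)[None, :, None, None], xv.shape)
    lo = dv[cidx, i]
    hi = dv[cidx, i + 1]
    out = lo * (1.0 - frac) + hi * frac
    if not is_var(x, d):
        return out

    def bw(g):
        res = []
        if isinstance(x, Var):
            res.append((x, g * (hi - lo) / delta))
        if isinstance(d, Var):
            flat_lo = (cidx * n + i).ravel()
            gd = np.bincount(flat_lo, weights=(g * (1.0 - frac)).ravel(),
                             minlength=C * n)
            gd += np.bincount(flat_lo + 1, weights=(g * frac).ravel(),
                              minlength=C * n)
            res.append((d, gd.reshape(C, n)))
        return res

    return Var(out, (x, d), bw)
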