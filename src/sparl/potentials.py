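"""Shape-constrained scalar nonlinearities.

The mask generators are built from learnable linear splines on uniform grids:

* :class:`LinearSpline` — free spline on ``{-MΔ, ..., MΔ}`` with linear
  extrapolation, the building block of the solution-adaptive mask network;
* :class:`HalfLineSpline` — spline on ``{0, Δ, ..., MΔ}`` used for the
  derivative profiles of the concave potentials;
* :class:`ConcaveProfileDeriv` — ``ψ'(x) = clip_[0,1](σ(r x))`` with a
  non-increasing σ satisfying ``σ(0) = 1``, so that the potential ψ is
  increasing, concave and piecewise quadratic with ``ψ'(0) = 1``;
* :class:`SigmoidSpline` — a linear spline composed with the logistic
  function, mapping into ``(0, 1)``.

:func:`monotone_projection` maps arbitrary knot values onto the feasible set
of the profile splines (non-increasing, first value 1) by clipping the
forward differences at zero and re-accumulating them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _ad

__all__ = [
    "LinearSpline",
    "HalfLineSpline",
    "ConcaveProfileDeriv",
    "SigmoidSpline",
    "eval_linear_spline",
    "clip_interval",
    "monotone_projection",
    "eval_psi_prime",
    "eval_psi",
    "eval_sigmoid_spline",
]


def _eval_uniform_spline(x, d: np.ndarray, delta: float, x0: float):
    """Piecewise-linear interpolation on a uniform grid, linear extrapolation."""
    arr = np.asarray(x, dtype=np.float64)
    out = _ad.spline_channels(arr.reshape(1, 1, 1, -1), np.asarray(d, dtype=np.float64)[None, :],
                              delta, x0)
    return out.reshape(arr.shape) if arr.shape else float(out.reshape(-1)[0])


@dataclass
class LinearSpline:
    """Linear spline with 2M+1 knot values ``d`` on ``{-MΔ, ..., MΔ}``."""

    M: int
    delta: float
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.delta <= 0:
            raise ValueError("grid step must be positive")
        if self.d.shape != (2 * self.M + 1,):
            raise ValueError("expected 2M+1 knot values")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("knot values must be finite")

    def __call__(self, x):
        return _eval_uniform_spline(x, self.d, self.delta, -self.M * self.delta)


@dataclass
class HalfLineSpline:
    """Linear spline with M+1 knot values on ``{0, Δ, ..., MΔ}``."""

    M: int
    delta: float
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.delta <= 0:
            raise ValueError("grid step must be positive")
        if self.d.shape != (self.M + 1,):
            raise ValueError("expected M+1 knot values")

    def __call__(self, x):
        return _eval_uniform_spline(x, self.d, self.delta, 0.0)


@dataclass
class ConcaveProfileDeriv:
    """Derivative profile ``ψ'(x) = clip_[0,1](σ(r x))`` of a concave potential."""

    sigma: HalfLineSpline
    r: float = 1.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("scale r must be positive")
        d = self.sigma.d
        if abs(d[0] - 1.0) > 1e-9 or np.any(np.diff(d) > 1e-9):
            raise ValueError("profile knots must be non-increasing and start at 1 "
                             "(apply monotone_projection first)")


@dataclass
class SigmoidSpline:
    """Logistic function applied to a linear spline; values in (0, 1)."""

    spline: LinearSpline


def eval_linear_spline(s: LinearSpline, x):
    return s(x)


def clip_interval(a, k1: float, k2: float):
    """Componentwise clamp of ``a`` to ``[k1, k2]``; idempotent and 1-Lipschitz."""
    if k1 > k2:
        raise ValueError("empty interval: k1 > k2")
    arr = np.asarray(a, dtype=np.float64)
    out = np.clip(arr, k1, k2)
    return out if arr.shape else float(out)


def monotone_projection(d) -> np.ndarray:
    """Map knot values onto {non-increasing sequences with first entry 1}.

    Forward differences are clipped at zero and cumulatively summed back,
    then the offset is fixed so the first entry is exactly 1.  Idempotent on
    feasible inputs.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a vector of at least two knot values")
    steps = np.minimum(np.diff(d), 0.0)
    return np.concatenate([[0.0], np.cumsum(steps)]) + 1.0


def eval_psi_prime(p: ConcaveProfileDeriv, x):
    """``ψ'(x) = clip_[0,1](σ(r x))`` for ``x >= 0``; non-increasing, ψ'(0)=1."""
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("psi' is only defined for nonnegative arguments")
    return clip_interval(p.sigma(p.r * arr), 0.0, 1.0)


def _integral_clipped_linear(a, b, va, vb):
    """``∫_a^b clip_[0,1](ℓ(t)) dt`` for the linear ℓ with ℓ(a)=va, ℓ(b)=vb.

    Vectorized closed form: the integrand is piecewise linear with at most two
    interior breakpoints (the 0- and 1-crossings of ℓ), so a three-segment
    trapezoid rule over the sorted breakpoints is exact.
    """
    a, b, va, vb = np.broadcast_arrays(*(np.asarray(v, dtype=np.float64)
                                         for v in (a, b, va, vb)))
    length = b - a
    slope_num = vb - va
    with np.errstate(divide="ignore", invalid="ignore"):
        cz = np.where(slope_num != 0, a + (0.0 - va) * length / slope_num, a)
        co = np.where(slope_num != 0, a + (1.0 - va) * length / slope_num, a)
    cz = np.clip(cz, a, b)
    co = np.clip(co, a, b)
    p0 = np.minimum(cz, co)
    p1 = np.maximum(cz, co)

    def value_at(t):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(length > 0, (t - a) / np.where(length > 0, length, 1.0), 0.0)
        return np.clip(va + slope_num * frac, 0.0, 1.0)

    total = np.zeros_like(length)
    for lo, hi in ((a, p0), (p0, p1), (p1, b)):
        total += 0.5 * (value_at(lo) + value_at(hi)) * (hi - lo)
    return total


def eval_psi(p: ConcaveProfileDeriv, x):
    """Antiderivative ``ψ(x) = ∫_0^x ψ'`` with ψ(0)=0, evaluated in closed form.

    ψ is nonnegative, non-decreasing, concave and piecewise quadratic.
    """
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("psi is only defined for nonnegative arguments")
    d = p.sigma.d
    delta = p.sigma.delta
    M = p.sigma.M
    # exact integrals of clip01(sigma) over the grid cells, plus cumulative sums
    cell_lo = np.arange(M) * delta
    cell_int = _integral_clipped_linear(cell_lo, cell_lo + delta, d[:-1], d[1:])
    cum = np.concatenate([[0.0], np.cumsum(cell_int)])  # cum[m] = ∫_0^{mΔ}

    u = p.r * arr  # integrate sigma up to u, then scale by 1/r
    i = np.clip(np.floor(u / delta).astype(np.int64), 0, M - 1)
    inside = u <= M * delta
    i = np.where(inside, i, M - 1)
    # partial cell [iΔ, min(u, MΔ)]
    lo_t = i * delta
    hi_t = np.minimum(u, M * delta)
    va = d[i]
    vb = d[np.minimum(i + 1, M)]
    # interpolate sigma at hi_t within the cell
    with np.errstate(invalid="ignore"):
        v_hi = va + (vb - va) * (hi_t - lo_t) / delta
    part = _integral_clipped_linear(lo_t, hi_t, va, v_hi)
    total = cum[i] + part
    # tail beyond the grid: sigma extrapolates with the last segment's slope
    tail_slope = (d[-1] - d[-2]) / delta if M >= 1 else 0.0
    tail_hi = np.maximum(u, M * delta)
    v_tail = d[-1] + tail_slope * (tail_hi - M * delta)
    total = total + _integral_clipped_linear(M * delta, tail_hi, d[-1], v_tail)
    out = total / p.r
    return out if arr.shape else float(out)


def eval_sigmoid_spline(s: SigmoidSpline, x):
    out = _ad.sigmoid(np.asarray(s.spline(x), dtype=np.float64))
    return out if np.asarray(x).shape else float(out)
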