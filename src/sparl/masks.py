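"""Attentive mask generators.

A mask is a per-channel, per-pixel weight field Λ that locally rescales the
L1-analysis penalty ``λ Σ_c <Λ_c, |W_c x|>``: small weights on image structure
let edges and texture survive the regularization, weights near one keep full
noise suppression.

Two generators are provided:

* the majorization-minimization (MMR) generator
  ``Λ_c(x) = B_cᵀ ψ'_c(B_c |W_c x|)`` with nonnegative, row-normalized
  averaging filters ``B_c`` and non-increasing profiles ``ψ'_c ∈ [0, 1]``.
  These masks are exactly the linearization weights of a concave potential,
  which is what guarantees the descent property of the outer iterations.
* the solution-adaptive (SAFI) generator, a 3-layer convolutional network
  ``Λ̃_c(x) = ϕ_{3,c}(B̂_c ϕ₂(B̃ ϕ₁(W̃ x)))`` whose last activation is a
  spline composed with the logistic function, keeping the mask in (0, 1).

Both operate on single images ``(H, W)`` or batches ``(B, H, W)`` and accept
taped parameters, so the training module can differentiate through them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _ad
from ._ad import val
from .operators import AnalysisOperator, ConvOperator, MaskField
from .potentials import ConcaveProfileDeriv, HalfLineSpline, monotone_projection

__all__ = [
    "MMRMaskGenerator",
    "SAFIMaskGenerator",
    "mmr_mask",
    "safi_mask",
    "build_weighted_analysis",
]


def _to_batched_image(x):
    """(H,W) or (B,H,W) -> ((B,1,H,W), was_batched)."""
    nd = val(x).ndim
    if nd == 2:
        return _ad.reshape(x, (1, 1) + val(x).shape), False
    if nd == 3:
        s = val(x).shape
        return _ad.reshape(x, (s[0], 1, s[1], s[2])), True
    raise ValueError("expected an (H,W) image or a (B,H,W) batch")


def _restore_mask(m, batched):
    return m if batched else _ad.reshape(m, val(m).shape[1:])


@dataclass
class MMRMaskGenerator:
    """Mask generator of the majorization-minimization scheme.

    ``W`` holds the zero-mean analysis filters (1 -> N_C channels), ``B`` the
    depthwise simplex-constrained averaging filters, ``sigma_knots`` the rows
    of profile knot values (one ``HalfLineSpline`` per channel, feasible:
    non-increasing, first entry 1) and ``r`` the positive input scales.
    ``lam`` is the regularization strength learned alongside.
    """

    W: ConvOperator
    B: ConvOperator
    sigma_knots: object  # (N_C, M+1)
    r: object            # (N_C,)
    delta: float = 0.05
    lam: float = 1e-4

    scheme = "mmr"

    @property
    def n_channels(self) -> int:
        return self.W.out_channels

    @property
    def profiles(self) -> list:
        """Per-channel concave-potential derivative profiles (detached view)."""
        d = np.asarray(val(self.sigma_knots))
        r = np.abs(np.asarray(val(self.r)))
        M = d.shape[1] - 1
        return [ConcaveProfileDeriv(HalfLineSpline(M, self.delta, d[c]), float(r[c]))
                for c in range(d.shape[0])]

    @classmethod
    def random(cls, n_channels: int = 8, kernel_size: int = 5, n_layers: int = 1,
               M: int = 20, delta: float = 0.05, padding: str = "zero",
               profile_init: str = "paper", lam: float = 1e-4,
               seed: int = 0) -> "MMRMaskGenerator":
        """Random filters; profiles either at the canonical init (knots
        ``(1, 0, ..., 0)``) or random feasible (``profile_init='random'``)."""
        rng = np.random.default_rng(seed)
        W = ConvOperator.random(1, n_channels, n_layers, kernel_size, groups=1,
                                constraint="zero_mean", padding=padding,
                                seed=int(rng.integers(2 ** 31)))
        B = ConvOperator.random(n_channels, n_channels, n_layers, kernel_size,
                                groups=n_channels, constraint="simplex",
                                padding=padding, seed=int(rng.integers(2 ** 31)))
        knots = np.zeros((n_channels, M + 1))
        knots[:, 0] = 1.0
        if profile_init == "random":
            raw = rng.standard_normal((n_channels, M + 1))
            knots = np.stack([monotone_projection(row) for row in raw])
        r = np.ones(n_channels)
        if profile_init == "random":
            r = rng.uniform(0.5, 2.0, n_channels)
        return cls(W, B, knots, r, delta, lam)

    def parameters(self) -> dict:
        return {"W": self.W.kernels, "B": self.B.kernels,
                "sigma_knots": self.sigma_knots, "r": self.r, "lam": self.lam}

    def project(self) -> None:
        """Re-establish all constraints after a parameter update."""
        self.W.project()
        self.B.project()
        d = np.asarray(val(self.sigma_knots))
        proj = np.stack([monotone_projection(row) for row in d])
        if isinstance(self.sigma_knots, _ad.Var):
            self.sigma_knots.value[...] = proj
        else:
            self.sigma_knots = proj

    def mask(self, x) -> MaskField:
        x4, batched = _to_batched_image(x)
        wx = self.W.apply(x4)                       # (B, C, H, W)
        ba = self.B.apply(_ad.aabs(wx))             # B_c |W_c x|
        r = _ad.reshape(_ad.aabs(self.r), (1, self.n_channels, 1, 1))
        scaled = ba * r
        psi_p = _ad.clip(_ad.spline_channels(scaled, self.sigma_knots, self.delta, 0.0),
                         0.0, 1.0)
        m = self.B.adjoint(psi_p)                   # B_cᵀ ψ'_c(...)
        if val(m).ndim == 3:  # single-channel generator: keep the channel axis
            m = _ad.reshape(m, (val(m).shape[0], 1) + val(m).shape[1:])
        return MaskField(_restore_mask(m, batched))


@dataclass
class SAFIMaskGenerator:
    """3-layer convolutional mask generator of the solution-adaptive scheme.

    ``Wt`` (1 -> N_C), ``Bt`` and ``Bh`` (N_C -> N_C) are unconstrained
    convolutions; ``phi1``/``phi2`` are free per-channel linear splines shared
    across all pixels of a channel, and the final activation is a spline
    followed by the logistic function, so every mask entry lies in (0, 1).
    ``Bh`` stacks the per-channel readout rows B̂_c as one convolution.
    """

    W: ConvOperator
    Wt: ConvOperator
    Bt: ConvOperator
    Bh: ConvOperator
    phi1: object  # (N_C, 2M+1)
    phi2: object
    phi3: object
    M: int = 10
    delta: float = 0.1
    lam: float = 1e-4

    scheme = "safi"

    @property
    def n_channels(self) -> int:
        return self.W.out_channels

    @classmethod
    def random(cls, n_channels: int = 8, kernel_size: int = 5, n_layers: int = 1,
               M: int = 10, delta: float = 0.1, padding: str = "zero",
               spline_init: str = "zero", lam: float = 1e-4,
               seed: int = 0) -> "SAFIMaskGenerator":
        """Random filters; spline coefficients all zero by default, in which
        case every mask is identically 1/2 and the first subproblem is a
        uniformly weighted L1-analysis problem."""
        rng = np.random.default_rng(seed)
        W = ConvOperator.random(1, n_channels, n_layers, kernel_size, groups=1,
                                constraint="zero_mean", padding=padding,
                                seed=int(rng.integers(2 ** 31)))
        mk = lambda cin: ConvOperator.random(cin, n_channels, 1, kernel_size,
                                             groups=1, constraint="none",
                                             padding=padding,
                                             seed=int(rng.integers(2 ** 31)))
        Wt, Bt, Bh = mk(1), mk(n_channels), mk(n_channels)
        n_knots = 2 * M + 1
        if spline_init == "random":
            phi = lambda: 0.2 * rng.standard_normal((n_channels, n_knots))
        else:
            phi = lambda: np.zeros((n_channels, n_knots))
        return cls(W, Wt, Bt, Bh, phi(), phi(), phi(), M, delta, lam)

    def parameters(self) -> dict:
        return {"W": self.W.kernels, "Wt": self.Wt.kernels, "Bt": self.Bt.kernels,
                "Bh": self.Bh.kernels, "phi1": self.phi1, "phi2": self.phi2,
                "phi3": self.phi3, "lam": self.lam}

    def project(self) -> None:
        self.W.project()

    def _spline(self, x, knots):
        return _ad.spline_channels(x, knots, self.delta, -self.M * self.delta)

    def mask(self, x) -> MaskField:
        x4, batched = _to_batched_image(x)
        h = self._spline(self.Wt.apply(x4), self.phi1)
        h = self._spline(self.Bt.apply(h), self.phi2)
        h = self._spline(self.Bh.apply(h), self.phi3)
        m = _ad.sigmoid(h)
        return MaskField(_restore_mask(m, batched))


def mmr_mask(g: MMRMaskGenerator, x) -> MaskField:
    """``Λ_c(x) = B_cᵀ ψ'_c(B_c |W_c x|)``; entrywise nonnegative."""
    return g.mask(x)


def safi_mask(g: SAFIMaskGenerator, x) -> MaskField:
    """``Λ̃_c(x) = ϕ_{3,c}(B̂_c ϕ₂(B̃ ϕ₁(W̃ x)))``; entries in (0, 1)."""
    return g.mask(x)


def build_weighted_analysis(mask, W: ConvOperator) -> AnalysisOperator:
    """Weighted analysis operator ``L = [diag(Λ_c) W_c]_c`` from a mask."""
    values = mask.values if isinstance(mask, MaskField) else mask
    if val(values).shape[-3] != W.out_channels:
        raise ValueError("mask channels do not match the analysis operator")
    return AnalysisOperator(W, values)
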