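"""Linear operators for image reconstruction.

Three families live here:

* forward (measurement) models ``H`` — identity (denoising), dense matrices,
  and the column-undersampled Fourier transform used in single-coil MRI;
* constrained multi-layer convolution stacks (the analysis filters ``W`` and
  the nonnegative averaging filters ``B`` of the mask generators);
* spatially re-weighted analysis operators ``L = [diag(mask_c) W_c]_c``.

All operators expose ``apply``/``adjoint`` pairs that are exact transposes of
each other, which the tests verify with random inner-product probes.
Convolution stacks accept taped variables (see ``sparl._ad``) so the training
module can differentiate through them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _ad
from ._ad import val

__all__ = [
    "ForwardModel",
    "IdentityModel",
    "DenseModel",
    "MaskedFourierModel",
    "make_forward_model",
    "apply_forward",
    "ConvOperator",
    "MaskField",
    "AnalysisOperator",
    "weighted_analysis_apply",
    "project_zero_mean",
    "project_simplex",
    "estimate_sq_spectral_norm",
    "select_kspace_columns",
]

#: safety factor applied to power-iteration estimates so that FBS step sizes
#: 1/||.||^2 built from them never exceed the true admissible step
POWER_ITERATION_SAFETY = 1.01


# ---------------------------------------------------------------------------
# kernel constraint projections
# ---------------------------------------------------------------------------

def project_zero_mean(kernel: np.ndarray) -> np.ndarray:
    """Remove the mean of a kernel so that its entries sum to zero."""
    k = np.asarray(kernel, dtype=np.float64)
    if k.size == 0:
        raise ValueError("empty kernel")
    return k - k.mean()


def project_simplex(kernel: np.ndarray) -> np.ndarray:
    """Map a kernel onto the probability simplex via ``|b| / sum|b|``."""
    k = np.abs(np.asarray(kernel, dtype=np.float64))
    s = k.sum()
    if s == 0:
        raise ValueError("invalid kernel: all entries are zero")
    return k / s


# ---------------------------------------------------------------------------
# spectral norm estimation
# ---------------------------------------------------------------------------

def estimate_sq_spectral_norm(apply_fn, adjoint_fn, shape, iters: int = 100,
                              tol: float = 1e-6, seed: int = 0) -> float:
    """Squared spectral norm of a linear operator via power iteration on AᵀA.

    ``apply_fn``/``adjoint_fn`` must form a consistent adjoint pair; ``shape``
    is the domain shape.  Returns the dominant eigenvalue of AᵀA, i.e.
    ``||A||_2^2``.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(shape)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("degenerate probe")
    v /= nrm
    lam_prev = 0.0
    for _ in range(iters):
        w = adjoint_fn(apply_fn(v))
        w = np.asarray(val(w), dtype=np.float64)
        lam = float(np.linalg.norm(w))
        if not np.isfinite(lam):
            raise FloatingPointError("power iteration produced non-finite values")
        if lam == 0.0:
            return 0.0
        v = w / lam
        # eigenvalue increments shrink faster than the error itself; require a
        # margin so the returned value is accurate to ~tol for separated spectra
        if abs(lam - lam_prev) <= 0.05 * tol * lam:
            return lam
        lam_prev = lam
    return lam_prev


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

@dataclass
class ForwardModel:
    """Linear measurement operator ``H`` with apply/adjoint contracts."""

    kind: str
    shape: tuple  # image-domain shape (H, W)
    measurement_shape: tuple
    sq_spectral_norm: float
    sigma_min: Optional[float] = None

    def apply(self, x):
        raise NotImplementedError

    def adjoint(self, y):
        raise NotImplementedError

    @property
    def is_identity(self) -> bool:
        return self.kind == "identity"

    def __call__(self, x, adjoint: bool = False):
        return self.adjoint(x) if adjoint else self.apply(x)


class IdentityModel(ForwardModel):
    def __init__(self, shape):
        shape = tuple(shape)
        super().__init__("identity", shape, shape, 1.0, 1.0)

    def apply(self, x):
        self._check(x)
        return x

    adjoint = apply

    def _check(self, x):
        if val(x).shape[-2:] != self.shape:
            raise ValueError(f"shape mismatch: expected {self.shape}")


class DenseModel(ForwardModel):
    """Explicit matrix acting on the flattened image."""

    def __init__(self, matrix: np.ndarray, shape):
        matrix = np.asarray(matrix, dtype=np.float64)
        shape = tuple(shape)
        if matrix.shape[1] != int(np.prod(shape)):
            raise ValueError("matrix columns must match the image size")
        s = np.linalg.svd(matrix, compute_uv=False)
        sigma_min = float(s[-1]) if matrix.shape[0] == matrix.shape[1] else None
        super().__init__("dense", shape, (matrix.shape[0],), float(s[0] ** 2), sigma_min)
        self.matrix = matrix

    def apply(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-2:] != self.shape:
            raise ValueError(f"shape mismatch: expected {self.shape}")
        flat = x.reshape(*x.shape[:-2], -1)
        return flat @ self.matrix.T

    def adjoint(self, y):
        y = np.asarray(y, dtype=np.float64)
        if y.shape[-1] != self.matrix.shape[0]:
            raise ValueError("measurement shape mismatch")
        return (y @ self.matrix).reshape(*y.shape[:-1], *self.shape)


def select_kspace_columns(width: int, m_acc: float, center_fraction: float,
                          seed: int = 0) -> np.ndarray:
    """Indices of k-space columns to keep: ``floor(width/m_acc)`` of them.

    A contiguous center block of ``round(center_fraction * width)`` columns
    (low frequencies, array center after fftshift) is always retained; the
    remaining columns are drawn uniformly without replacement.
    """
    if m_acc < 1:
        raise ValueError("M_acc must be >= 1")
    if m_acc > width:
        raise ValueError("M_acc exceeds the image width")
    n_keep = int(width // m_acc)
    n_center = int(round(center_fraction * width))
    if n_center > n_keep:
        raise ValueError("center_fraction is infeasible for this acceleration")
    mid = width // 2
    center = np.arange(mid - n_center // 2, mid - n_center // 2 + n_center)
    rest = np.setdiff1d(np.arange(width), center)
    rng = np.random.default_rng(seed)
    extra = rng.choice(rest, size=n_keep - n_center, replace=False)
    return np.sort(np.concatenate([center, extra]))


class MaskedFourierModel(ForwardModel):
    """Column-undersampled unitary 2-D Fourier transform (single-coil MRI).

    Measurements are the retained (fftshifted) k-space columns of the image
    and are complex; the adjoint zero-fills, inverts the transform and takes
    the real part, since the reconstruction variable is a real image.
    """

    def __init__(self, shape, m_acc: float = 4.0, center_fraction: float = 0.08,
                 seed: int = 0, columns: Optional[np.ndarray] = None):
        shape = tuple(shape)
        H, W = shape
        if columns is None:
            columns = select_kspace_columns(W, m_acc, center_fraction, seed)
        columns = np.asarray(columns, dtype=np.int64)
        sigma_min = 1.0 if columns.size == W else None
        super().__init__("masked_fourier", shape, (H, columns.size),
                         1.0, sigma_min)
        self.m_acc = float(m_acc)
        self.center_fraction = float(center_fraction)
        self.columns = columns

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=np.int8)
        m[:, self.columns] = 1
        return m

    def apply(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-2:] != self.shape:
            raise ValueError(f"shape mismatch: expected {self.shape}")
        F = np.fft.fftshift(np.fft.fft2(x, norm="ortho"), axes=(-2, -1))
        return F[..., :, self.columns]

    def adjoint(self, y):
        y = np.asarray(y)
        full = np.zeros(y.shape[:-2] + self.shape, dtype=np.complex128)
        full[..., :, self.columns] = y
        img = np.fft.ifft2(np.fft.ifftshift(full, axes=(-2, -1)), norm="ortho")
        return np.real(img)


def make_forward_model(kind: str, shape, params: Optional[dict] = None,
                       seed: int = 0) -> ForwardModel:
    """Factory for the supported forward models.

    ``params`` carries ``M_acc``/``center_fraction`` (masked_fourier) or
    ``matrix`` (dense).
    """
    params = dict(params or {})
    if kind == "identity":
        return IdentityModel(shape)
    if kind == "dense":
        return DenseModel(params["matrix"], shape)
    if kind == "masked_fourier":
        return MaskedFourierModel(
            shape,
            m_acc=params.get("M_acc", 4.0),
            center_fraction=params.get("center_fraction", 0.08),
            seed=seed,
            columns=params.get("columns"),
        )
    raise ValueError(f"unknown forward-model kind: {kind!r}")


def apply_forward(model: ForwardModel, x, adjoint_flag: bool = False):
    return model(x, adjoint=adjoint_flag)


# ---------------------------------------------------------------------------
# convolution stacks
# ---------------------------------------------------------------------------

def _normalize_input(x, channels: int):
    """Normalize to (B, C, H, W) and name the input form.

    A 3-D array is a batch of images ``(B, H, W)`` when the operator expects
    one channel, otherwise a single channel field ``(C, H, W)``.
    """
    s = val(x).shape
    nd = len(s)
    if nd == 4:
        return x, "bchw"
    if nd == 3:
        if channels == 1:
            return _ad.reshape(x, (s[0], 1, s[1], s[2])), "bhw"
        return _ad.reshape(x, (1,) + s), "chw"
    if nd == 2 and channels == 1:
        return _ad.reshape(x, (1, 1) + s), "hw"
    raise ValueError("input must be (B,C,H,W), (C,H,W), (B,H,W) for 1-channel "
                     "operators, or (H,W)")


def _restore_output(out, form: str, channels_out: int, to_image_domain: bool = False):
    """Undo :func:`_normalize_input`.

    ``to_image_domain`` (the adjoint of a single-input-channel operator)
    drops the singleton channel axis so results live in the image domain.
    """
    s = val(out).shape  # (B, C_out, H, W)
    if form == "bchw":
        if to_image_domain and s[1] == 1:
            return _ad.reshape(out, (s[0], s[2], s[3]))
        return out
    if form == "bhw":
        if to_image_domain and s[1] == 1:
            return _ad.reshape(out, (s[0], s[2], s[3]))
        return out
    if form == "chw":
        if to_image_domain and s[1] == 1:
            return _ad.reshape(out, s[2:])
        return _ad.reshape(out, s[1:])
    # "hw"
    return _ad.reshape(out, s[2:] if s[1] == 1 else s[1:])


class ConvOperator:
    """Stack of ``S`` same-size 2-D convolution layers with shared constraints.

    ``groups`` controls channel mixing as in grouped convolutions: ``G = 1``
    mixes all channels, ``G = out_channels`` is depthwise.  The first layer
    maps ``in_channels`` to ``out_channels`` and is always fully connected
    across its (typically single) input channel; subsequent layers map
    ``out_channels`` to ``out_channels`` with the stated group size.
    ``constraint`` is one of ``zero_mean``/``simplex``/``none`` and is
    enforced by :meth:`project` on every individual 2-D kernel.
    """

    def __init__(self, kernels: Sequence, in_channels: int, out_channels: int,
                 groups: int = 1, constraint: str = "none", padding: str = "zero"):
        if constraint not in ("zero_mean", "simplex", "none"):
            raise ValueError(f"unknown constraint {constraint!r}")
        if padding not in ("zero", "circular"):
            raise ValueError(f"unknown padding {padding!r}")
        if out_channels % groups:
            raise ValueError("out_channels must be divisible by groups")
        self.kernels = list(kernels)
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.groups = int(groups)
        self.constraint = constraint
        self.padding = padding

    # -- construction ----------------------------------------------------
    @classmethod
    def random(cls, in_channels: int, out_channels: int, n_layers: int = 1,
               kernel_size: int = 3, groups: int = 1, constraint: str = "none",
               padding: str = "zero", seed: int = 0) -> "ConvOperator":
        """Kernels uniform in ±1/sqrt(fan_in), then projected onto the constraint."""
        rng = np.random.default_rng(seed)
        kernels = []
        for layer in range(n_layers):
            cin = in_channels if layer == 0 else out_channels
            g = 1 if layer == 0 and in_channels < groups else groups
            cpg = cin // g
            bound = 1.0 / np.sqrt(cpg * kernel_size ** 2)
            k = rng.uniform(-bound, bound, size=(out_channels, cpg, kernel_size, kernel_size))
            kernels.append(k)
        op = cls(kernels, in_channels, out_channels, groups, constraint, padding)
        op.project()
        return op

    @property
    def n_layers(self) -> int:
        return len(self.kernels)

    @property
    def kernel_size(self) -> int:
        return val(self.kernels[0]).shape[-1]

    def _layer_groups(self, layer: int) -> int:
        cin = self.in_channels if layer == 0 else self.out_channels
        k = val(self.kernels[layer])
        g = cin // k.shape[1]
        return g

    # -- linear action ---------------------------------------------------
    def apply(self, x):
        x4, form = _normalize_input(x, self.in_channels)
        if val(x4).shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels")
        out = x4
        for layer, k in enumerate(self.kernels):
            out = _ad.conv2d(out, k, padding=self.padding, groups=self._layer_groups(layer))
        return _restore_output(out, form, self.out_channels)

    def adjoint(self, u):
        u4, form = _normalize_input(u, self.out_channels)
        if val(u4).shape[1] != self.out_channels:
            raise ValueError(f"expected {self.out_channels} channels")
        out = u4
        for layer in reversed(range(self.n_layers)):
            out = _ad.conv2d_adjoint(out, self.kernels[layer], padding=self.padding,
                                     groups=self._layer_groups(layer))
        return _restore_output(out, form, self.in_channels,
                               to_image_domain=(self.in_channels == 1))

    def __call__(self, x, adjoint: bool = False):
        return self.adjoint(x) if adjoint else self.apply(x)

    # -- constraints and estimates ---------------------------------------
    def project(self) -> None:
        """Project every 2-D kernel onto the operator's constraint set."""
        if self.constraint == "none":
            return
        proj = project_zero_mean if self.constraint == "zero_mean" else project_simplex
        for idx, k in enumerate(self.kernels):
            kv = np.array(val(k), dtype=np.float64)
            for o in range(kv.shape[0]):
                for c in range(kv.shape[1]):
                    kv[o, c] = proj(kv[o, c])
            if isinstance(k, _ad.Var):
                k.value[...] = kv
            else:
                self.kernels[idx] = kv

    def detached(self) -> "ConvOperator":
        return ConvOperator([np.array(val(k)) for k in self.kernels],
                            self.in_channels, self.out_channels, self.groups,
                            self.constraint, self.padding)

    def sq_norm(self, spatial_shape, iters: int = 100, tol: float = 1e-6,
                seed: int = 0) -> float:
        op = self.detached()
        shape = (self.in_channels,) + tuple(spatial_shape)
        est = estimate_sq_spectral_norm(op.apply, op.adjoint, shape, iters, tol, seed)
        return POWER_ITERATION_SAFETY * est


def apply_conv(op: ConvOperator, x, adjoint_flag: bool = False):
    return op(x, adjoint=adjoint_flag)


# ---------------------------------------------------------------------------
# masked analysis operators
# ---------------------------------------------------------------------------

@dataclass
class MaskField:
    """Per-channel, per-pixel regularization weights Λ."""

    values: object  # (C, H, W) or (B, C, H, W); ndarray or taped Var

    @property
    def shape(self):
        return val(self.values).shape

    def detach(self) -> np.ndarray:
        return np.asarray(val(self.values))


class AnalysisOperator:
    """Weighted analysis operator ``L x = [mask_c ⊙ (W_c x)]_c``.

    With an all-ones mask this is exactly the base convolution stack; the
    adjoint is ``Lᵀ u = Σ_c W_cᵀ (mask_c ⊙ u_c)``.
    """

    def __init__(self, base: ConvOperator, weights=None):
        self.base = base
        if isinstance(weights, MaskField):
            weights = weights.values
        self.weights = weights  # None means all-ones

    def _check(self, w, channels_axis_len):
        if w is not None and val(w).shape[-3] != self.base.out_channels:
            raise ValueError("mask channels do not match the analysis operator")

    def apply(self, x):
        out = self.base.apply(x)
        if self.weights is None:
            return out
        self._check(self.weights, None)
        return out * self.weights if isinstance(out, _ad.Var) else _mul(self.weights, out)

    def adjoint(self, u):
        if self.weights is None:
            return self.base.adjoint(u)
        self._check(self.weights, None)
        w = self.weights
        prod = u * w if isinstance(u, _ad.Var) else _mul(w, u)
        return self.base.adjoint(prod)

    def __call__(self, x, adjoint: bool = False):
        return self.adjoint(x) if adjoint else self.apply(x)

    def detached(self) -> "AnalysisOperator":
        w = None if self.weights is None else np.array(val(self.weights))
        return AnalysisOperator(self.base.detached(), w)

    def sq_norm(self, spatial_shape, iters: int = 100, tol: float = 1e-6,
                seed: int = 0) -> float:
        op = self.detached()
        shape = (self.base.in_channels,) + tuple(spatial_shape)
        est = estimate_sq_spectral_norm(op.apply, op.adjoint, shape, iters, tol, seed)
        return POWER_ITERATION_SAFETY * est


def _mul(a, b):
    """Multiply where either side may be taped."""
    if isinstance(a, _ad.Var):
        return a * b
    if isinstance(b, _ad.Var):
        return b * a
    return np.asarray(a) * np.asarray(b)


def weighted_analysis_apply(L: AnalysisOperator, x, adjoint_flag: bool = False):
    return L(x, adjoint=adjoint_flag)


class MatrixOperator:
    """Explicit-matrix analysis operator (dense oracles and small problems)."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=np.float64)

    def apply(self, x):
        return val(x) @ self.matrix.T if not isinstance(x, np.ndarray) else x @ self.matrix.T

    def adjoint(self, u):
        return np.asarray(u) @ self.matrix

    def __call__(self, x, adjoint: bool = False):
        return self.adjoint(x) if adjoint else self.apply(x)

    def sq_norm(self, shape=None, seed: int = 0) -> float:
        return float(np.linalg.svd(self.matrix, compute_uv=False)[0] ** 2)
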