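"""Synthetic images, patches, noise and k-space sampling masks.

Everything the solvers and the training loop consume can be generated here,
so tests and demos run without external downloads.  The generators are pure
functions of their arguments (including the seed).

The patch generator emulates the statistics that matter for learning a
sparsifying analysis prior from natural images: piecewise-smooth regions with
sharp boundaries (random ellipse fields) plus band-limited ``1/f`` texture.
Its finite-difference distribution is heavy-tailed (positive excess
kurtosis), which is the property the re-weighted L1 prior exploits; it does
not emulate the semantic content of photographic data, nor MRI anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .operators import select_kspace_columns

__all__ = [
    "PatchSet",
    "make_phantom",
    "make_patches",
    "add_noise",
    "make_kspace_mask",
    "make_mri_instance",
    "SHEPP_LOGAN_ELLIPSES",
]

# modified Shepp-Logan head phantom: (intensity, a, b, x0, y0, angle_deg)
SHEPP_LOGAN_ELLIPSES = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def _ellipse_field(shape, ellipses) -> np.ndarray:
    # convention: x along columns in [-1, 1], y along rows from +1 (top) to -1
    h, w = shape
    yy, xx = np.meshgrid(np.linspace(1, -1, h), np.linspace(-1, 1, w), indexing="ij")
    img = np.zeros(shape)
    for inten, a, b, x0, y0, ang in ellipses:
        th = np.deg2rad(ang)
        xr = (xx - x0) * np.cos(th) + (yy - y0) * np.sin(th)
        yr = (yy - y0) * np.cos(th) - (xx - x0) * np.sin(th)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += inten
    return img


def make_phantom(shape, kind: str = "shepp_logan", seed: int = 0) -> np.ndarray:
    """Deterministic test image with values in [0, 1].

    ``shepp_logan`` rasterizes the standard modified ellipse table;
    ``random_ellipses`` overlays 3-8 random ellipses; ``piecewise_poly``
    tiles low-order polynomial patches with sharp block boundaries.
    """
    shape = tuple(shape)
    if kind == "shepp_logan":
        return np.clip(_ellipse_field(shape, SHEPP_LOGAN_ELLIPSES), 0.0, 1.0)
    rng = np.random.default_rng(seed)
    if kind == "random_ellipses":
        n = int(rng.integers(3, 9))
        ells = [(rng.uniform(-0.5, 0.8), rng.uniform(0.05, 0.6), rng.uniform(0.05, 0.6),
                 rng.uniform(-0.6, 0.6), rng.uniform(-0.6, 0.6), rng.uniform(0, 180))
                for _ in range(n)]
        img = _ellipse_field(shape, ells) + 0.35
        return np.clip(img, 0.0, 1.0)
    if kind == "piecewise_poly":
        h, w = shape
        img = np.zeros(shape)
        rsplit = np.sort(rng.choice(np.arange(1, h), size=min(3, h - 1), replace=False))
        csplit = np.sort(rng.choice(np.arange(1, w), size=min(3, w - 1), replace=False))
        for r0, r1 in zip(np.r_[0, rsplit], np.r_[rsplit, h]):
            for c0, c1 in zip(np.r_[0, csplit], np.r_[csplit, w]):
                if r1 <= r0 or c1 <= c0:
                    continue
                yy, xx = np.meshgrid(np.linspace(-1, 1, r1 - r0),
                                     np.linspace(-1, 1, c1 - c0), indexing="ij")
                coef = rng.uniform(-0.5, 0.5, size=6)
                tile = (coef[0] + coef[1] * xx + coef[2] * yy + coef[3] * xx * yy
                        + coef[4] * xx ** 2 + coef[5] * yy ** 2)
                img[r0:r1, c0:c1] = tile + rng.uniform(0.2, 0.8)
        return np.clip(img, 0.0, 1.0)
    raise ValueError(f"unknown phantom kind {kind!r}")


@dataclass
class PatchSet:
    """Clean training patches with (optionally) matched noisy versions."""

    clean: np.ndarray            # (n, size, size) in [0, 1]
    noisy: Optional[np.ndarray]  # same shape, or None before noise is added
    sigma: float
    seed: int

    def __len__(self) -> int:
        return self.clean.shape[0]

    def with_noise(self, sigma: float, seed: int = 0) -> "PatchSet":
        return PatchSet(self.clean, add_noise(self.clean, sigma, seed), sigma, seed)


def _texture(shape, rng, exponent: float = 1.0) -> np.ndarray:
    """Band-limited 1/f^exponent noise, normalized to unit max amplitude."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fy ** 2 + fx ** 2)
    radius[0, 0] = 1.0
    spec = np.fft.fft2(rng.standard_normal(shape)) / radius ** exponent
    spec[0, 0] = 0.0
    tex = np.real(np.fft.ifft2(spec))
    m = np.max(np.abs(tex))
    return tex / m if m > 0 else tex


def make_patches(n: int, size: int, seed: int = 0) -> PatchSet:
    """Natural-image-like clean patches: ellipse cartoons plus 1/f texture."""
    rng = np.random.default_rng(seed)
    clean = np.empty((n, size, size))
    for i in range(n):
        cartoon = make_phantom((size, size), "random_ellipses",
                               seed=int(rng.integers(2 ** 31)))
        tex = _texture((size, size), rng)
        amp = rng.uniform(0.02, 0.15)
        clean[i] = np.clip(cartoon + amp * tex, 0.0, 1.0)
    return PatchSet(clean, None, 0.0, seed)


def add_noise(x: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Additive white Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return np.array(x, copy=True)
    rng = np.random.default_rng(seed)
    return np.asarray(x) + sigma * rng.standard_normal(np.shape(x))


def make_kspace_mask(shape, m_acc: float, center_fraction: float = 0.08,
                     seed: int = 0) -> np.ndarray:
    """Binary column-sampling mask with ``floor(width/M_acc)`` kept columns.

    A centered block of ``round(center_fraction*width)`` low-frequency
    columns is always retained (k-space center after fftshift).
    """
    h, w = shape
    cols = select_kspace_columns(w, m_acc, center_fraction, seed)
    mask = np.zeros((h, w), dtype=np.int8)
    mask[:, cols] = 1
    return mask


def make_mri_instance(shape=(64, 64), m_acc: float = 4.0,
                      center_fraction: float = 0.08, noise_sigma: float = 2e-3,
                      phantom_kind: str = "shepp_logan", seed: int = 0):
    """Single-coil measurement simulation: phantom -> undersampled k-space.

    Complex Gaussian noise of standard deviation ``noise_sigma`` is added per
    real/imaginary component.  Returns ``(ground_truth, forward_model, y)``.
    """
    from .operators import MaskedFourierModel

    rng = np.random.default_rng(seed)
    x = make_phantom(shape, phantom_kind, seed=int(rng.integers(2 ** 31)))
    H = MaskedFourierModel(shape, m_acc=m_acc, center_fraction=center_fraction,
                           seed=int(rng.integers(2 ** 31)))
    y = H.apply(x)
    noise = noise_sigma * (rng.standard_normal(y.shape)
                           + 1j * rng.standard_normal(y.shape))
    return x, H, y + noise
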