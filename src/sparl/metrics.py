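"""Reconstruction quality metrics."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "ssim"]


def psnr(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(peak^2 / MSE)`` in decibels.

    Returns ``inf`` when the images coincide exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError("shape mismatch")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


def ssim(x: np.ndarray, ref: np.ndarray) -> float:
    """Structural-similarity index with the conventional constants, range 1."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError("shape mismatch")
    return float(structural_similarity(x, ref, data_range=1.0))
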