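"""Radiograph intensity preprocessing: percentile clipping, CLAHE, 8-bit RGB.

The pipeline clips gray values at the 2nd percentile (low end) and the 99.5th
percentile (high end), applies contrast-limited adaptive histogram
equalization, rescales to 8-bit and replicates the result to three identical
channels — the standard input shape for ImageNet-pretrained networks.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure

__all__ = ["preprocess_intensity"]


def preprocess_intensity(
    image: np.ndarray,
    low_pct: float = 2.0,
    high_pct: float = 0.5,
    apply_clahe: bool = True,
    clahe_tiles: int = 8,
    clahe_clip_limit: float = 0.01,
) -> np.ndarray:
    """Clip, contrast-enhance and convert a grayscale image to 3-channel uint8.

    Parameters
    ----------
    image
        2-D array of finite gray values.
    low_pct, high_pct
        Percent of the value range clipped at the lower / upper end; the
        clip bounds are the ``low_pct`` and ``100 - high_pct`` percentiles.
    apply_clahe
        Apply CLAHE after clipping.  Turn off for deterministic, strictly
        order-preserving output (clip + linear rescale only).
    clahe_tiles
        Number of CLAHE tiles along each axis (kernel = shape // tiles).
    clahe_clip_limit
        CLAHE clip limit as a fraction of the local histogram range.

    Returns
    -------
    ``(H, W, 3)`` uint8 array with three identical channels.  A constant
    input maps to constant mid-gray 128 rather than raising.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")

    lo = np.percentile(img, low_pct)
    hi = np.percentile(img, 100.0 - high_pct)
    if hi <= lo:  # constant (or near-constant) image: nothing to stretch
        flat = np.full(img.shape, 128, dtype=np.uint8)
        return np.stack([flat] * 3, axis=-1)

    clipped = np.clip(img, lo, hi)
    scaled = (clipped - lo) / (hi - lo)  # in [0, 1]
    if apply_clahe:
        kernel = (
            max(1, img.shape[0] // clahe_tiles),
            max(1, img.shape[1] // clahe_tiles),
        )
        scaled = exposure.equalize_adapthist(
            scaled, kernel_size=kernel, clip_limit=clahe_clip_limit
        )
    out8 = np.clip(np.rint(scaled * 255.0), 0, 255).astype(np.uint8)
    return np.stack([out8] * 3, axis=-1)
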