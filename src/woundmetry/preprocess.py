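"""Image normalisation applied before detection.

Raw photographs arrive in a landscape/portrait mix and at full camera
resolution; both are normalised once, up front: every image is brought to
portrait orientation (a lossless 90° rotation when width exceeds height)
and down-sampled to half size with area averaging.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = ["normalize_orientation", "downsample_half"]


def normalize_orientation(image: np.ndarray) -> np.ndarray:
    """Rotate to portrait: if width > height, rotate 90° counter-clockwise.

    Idempotent and pixel-count preserving; portrait or square input is
    returned unchanged.
    """
    image = np.asarray(image)
    if image.size == 0 or image.ndim < 2:
        raise InputError("expected a non-empty image")
    h, w = image.shape[:2]
    if w > h:
        return np.rot90(image, k=1, axes=(0, 1))
    return image


def downsample_half(image: np.ndarray) -> np.ndarray:
    """Half-size down-sampling by exact 2x2 area averaging.

    Odd trailing rows/columns are dropped (floor division); averages are
    rounded to the nearest integer (ties to even, so a 0/255 checkerboard
    block becomes 128).
    """
    image = np.asarray(image)
    if image.ndim < 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise InputError(f"image too small to downsample: {image.shape}")
    h2, w2 = image.shape[0] // 2, image.shape[1] // 2
    x = image[: 2 * h2, : 2 * w2].astype(np.float64)
    x = x.reshape((h2, 2, w2, 2) + x.shape[2:]).mean(axis=(1, 3))
    if np.issubdtype(image.dtype, np.integer):
        return np.rint(x).astype(image.dtype)
    return x.astype(image.dtype)
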