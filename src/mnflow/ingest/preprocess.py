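"""Image standardisation: min/max illumination rescale and crop/zero-pad."""

from __future__ import annotations

import warnings

import numpy as np

U16_MAX = 65535


def normalize_channel(image: np.ndarray) -> np.ndarray:
    """Min/max rescale a single-channel image onto the full 16-bit range.

    output = round((x - min) / (max - min) * 65535), with the half-range
    convention that an exact mid-value maps to 32768. Order-preserving and
    idempotent up to quantisation. A constant image maps to all zeros (a
    UserWarning is emitted).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant image: normalize_channel returns all zeros")
        return np.zeros(img.shape, dtype=np.uint16)
    scaled = (img - lo) / (hi - lo) * U16_MAX
    # floor(x + 0.5): round-half-up, so 0.5 of range -> 32768
    return np.floor(scaled + 0.5).astype(np.uint16)


def crop_pad(image: np.ndarray, target: int = 64) -> np.ndarray:
    """Centre-crop / zero-pad a single-channel array to target x target.

    Dimensions smaller than target are zero-padded symmetrically (extra
    row/column goes after); larger dimensions are centre-cropped (extra
    row/column removed from the end).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {img.shape}")
    out = img
    for axis in (0, 1):
        n = out.shape[axis]
        if n > target:
            start = (n - target) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif n < target:
            before = (target - n) // 2
            after = target - n - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant", constant_values=0)
    return out


def standardize_image(fluor: np.ndarray, brightfield: np.ndarray, target: int = 64) -> np.ndarray:
    """Normalise both channels and crop/pad to (target, target, 2) uint16."""
    ch0 = crop_pad(normalize_channel(fluor), target)
    ch1 = crop_pad(normalize_channel(brightfield), target)
    return np.stack([ch0, ch1], axis=-1)
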