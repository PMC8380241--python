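"""Training-time image augmentation: reflection, rotation, translation, scale.

All transforms compose into a single affine map about the image centre and
are applied with bilinear interpolation, zero-filling uncovered regions.
Parameter draws are deterministic given the seed / generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation parameter ranges.

    Rotation and translation ranges are free parameters (bounded so image
    content stays in frame); scaling spans 90-110% as published.
    """

    reflect_x: bool = True
    reflect_y: bool = True
    rotation_deg: float = 15.0
    translation_px: float = 4.0
    scale_range: tuple[float, float] = (0.90, 1.10)

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi < 2):
            raise ValueError(f"scale_range must lie within (0, 2), got {self.scale_range}")
        if self.rotation_deg < 0 or self.translation_px < 0:
            raise ValueError("rotation_deg and translation_px must be >= 0")


IDENTITY = AugmentConfig(reflect_x=False, reflect_y=False, rotation_deg=0.0,
                         translation_px=0.0, scale_range=(1.0, 1.0))


def _draw_params(rng: np.random.Generator, cfg: AugmentConfig):
    flip_x = bool(cfg.reflect_x and rng.uniform() < 0.5)
    flip_y = bool(cfg.reflect_y and rng.uniform() < 0.5)
    angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)) if cfg.rotation_deg else 0.0
    tx = float(rng.uniform(-cfg.translation_px, cfg.translation_px)) if cfg.translation_px else 0.0
    ty = float(rng.uniform(-cfg.translation_px, cfg.translation_px)) if cfg.translation_px else 0.0
    lo, hi = cfg.scale_range
    scale = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return flip_x, flip_y, angle, tx, ty, scale


def _apply_affine(image: np.ndarray, flip_x, flip_y, angle, tx, ty, scale) -> np.ndarray:
    """Apply the composed transform to an (H, W, C) image."""
    if not (flip_x or flip_y) and angle == 0.0 and tx == 0.0 and ty == 0.0 and scale == 1.0:
        return image.copy()
    out = image
    # exact flips by slicing (no interpolation)
    if flip_x:
        out = out[:, ::-1]
    if flip_y:
        out = out[::-1, :]
    if angle == 0.0 and tx == 0.0 and ty == 0.0 and scale == 1.0:
        return np.ascontiguousarray(out)
    h, w = out.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rad = np.deg2rad(angle)
    cos, sin = np.cos(rad), np.sin(rad)
    # inverse map (output -> input): rotate by -angle, scale by 1/scale
    m = np.array([[cos, sin], [-sin, cos]]) / scale
    offset = np.array([cy, cx]) - m @ np.array([cy + ty, cx + tx])
    src = out.astype(np.float64)
    res = np.empty_like(src)
    for ch in range(src.shape[2]):
        res[:, :, ch] = ndimage.affine_transform(
            src[:, :, ch], m, offset=offset, order=1, mode="constant", cval=0.0
        )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        res = np.clip(np.rint(res), info.min, info.max)
    return res.astype(image.dtype)


def augment(image: np.ndarray, seed, cfg: AugmentConfig | None = None) -> np.ndarray:
    """Randomly augment one (64, 64, 2) image; deterministic given the seed.

    ``seed`` may be an int or a numpy Generator.
    """
    cfg = cfg or AugmentConfig()
    img = np.asarray(image)
    if img.ndim != 3:
        raise ValueError(f"expected an (H, W, C) image, got shape {img.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _apply_affine(img, *_draw_params(rng, cfg))


def augment_batch(images: np.ndarray, rng: np.random.Generator,
                  cfg: AugmentConfig | None = None) -> np.ndarray:
    """Augment a batch of (N, H, W, C) images in place-order, one draw each."""
    cfg = cfg or AugmentConfig()
    return np.stack([_apply_affine(img, *_draw_params(rng, cfg)) for img in images])
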