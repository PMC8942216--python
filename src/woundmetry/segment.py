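"""Per-class score maps for wound and splint-inner regions on crops.

Two backends produce :class:`ProbabilityMaps`:

* a trainable compact encoder-decoder (see :mod:`woundmetry.unet`), trained
  with on-the-fly augmentation and a dice-based loss;
* :func:`reference_segment`, a deterministic colour-palette classifier that
  is exact on uncorrupted synthetic phantoms and serves as the default test
  backend so post-processing and measurement are exercisable without any
  training.

The wound and splint channels are independent (two sigmoid heads in the
trained model): the wound lies *inside* the splint-inner disk, so the two
target regions overlap and must not compete as softmax classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError

__all__ = [
    "ProbabilityMaps",
    "AugmentationConfig",
    "augment_sample",
    "dice_loss",
    "reference_segment",
    "DEFAULT_PALETTE",
]


@dataclass
class ProbabilityMaps:
    """8-bit per-class score maps over one crop (0 = absent, 255 = certain)."""

    wound: np.ndarray
    splint: np.ndarray

    def __post_init__(self) -> None:
        self.wound = np.asarray(self.wound, dtype=np.uint8)
        self.splint = np.asarray(self.splint, dtype=np.uint8)
        if self.wound.shape != self.splint.shape or self.wound.ndim != 2:
            raise InputError(
                f"score maps must be 2-D and share a shape, got "
                f"{self.wound.shape} and {self.splint.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.wound.shape


@dataclass
class AugmentationConfig:
    """On-the-fly augmentation recipe applied to each training sample.

    Defaults follow the recipe used for wound-photo training: vertical and
    horizontal flips each with probability 0.5, rotation uniform in
    [-90, 90] degrees, linear contrast ``127 + alpha * (v - 127)`` with
    alpha in [0.5, 1.5], a global intensity multiplier in [0.5, 1.5], and
    Gaussian blur applied 35 % of the time with sigma in [0, 6].
    """

    flip_prob: float = 0.5
    rotation_range: tuple[float, float] = (-90.0, 90.0)
    contrast_alpha_range: tuple[float, float] = (0.5, 1.5)
    intensity_range: tuple[float, float] = (0.5, 1.5)
    blur_prob: float = 0.35
    blur_sigma_range: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self) -> None:
        for p in (self.flip_prob, self.blur_prob):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"probabilities must be in [0, 1], got {p}")
        for name in (
            "rotation_range",
            "contrast_alpha_range",
            "intensity_range",
            "blur_sigma_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InputError(f"{name} must be ordered, got ({lo}, {hi})")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        """A configuration under which :func:`augment_sample` is a no-op."""
        return cls(
            flip_prob=0.0,
            rotation_range=(0.0, 0.0),
            contrast_alpha_range=(1.0, 1.0),
            intensity_range=(1.0, 1.0),
            blur_prob=0.0,
            blur_sigma_range=(0.0, 0.0),
        )


def augment_sample(
    image: np.ndarray,
    masks: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random draw of the augmentation recipe to a sample.

    Geometric transforms (flips, rotation) are applied identically to the
    image and to the mask stack; masks use nearest-neighbour resampling so
    they stay binary.  Photometric transforms (contrast, intensity, blur)
    touch the image only.  Pixel values are clipped to [0, 255].

    ``masks`` is an array whose leading axis indexes classes,
    shape ``(K, H, W)``.
    """
    image = np.asarray(image)
    masks = np.asarray(masks)
    if image.shape[:2] != masks.shape[-2:]:
        raise InputError(
            f"image {image.shape[:2]} and masks {masks.shape[-2:]} disagree"
        )

    # Draw all parameters first so the consumed randomness is independent of
    # the branch structure.
    do_vflip = rng.random() < config.flip_prob
    do_hflip = rng.random() < config.flip_prob
    angle = rng.uniform(*config.rotation_range)
    alpha = rng.uniform(*config.contrast_alpha_range)
    gain = rng.uniform(*config.intensity_range)
    do_blur = rng.random() < config.blur_prob
    sigma = rng.uniform(*config.blur_sigma_range)

    img = image.astype(np.float64)
    msk = masks.copy()
    if do_vflip:
        img = img[::-1]
        msk = msk[..., ::-1, :]
    if do_hflip:
        img = img[:, ::-1]
        msk = msk[..., :, ::-1]
    if angle != 0.0:
        img = ndimage.rotate(
            img, angle, axes=(0, 1), reshape=False, order=1, mode="reflect"
        )
        msk = np.stack(
            [
                ndimage.rotate(
                    m, angle, axes=(0, 1), reshape=False, order=0, mode="reflect"
                )
                for m in msk.reshape((-1,) + msk.shape[-2:])
            ]
        ).reshape(msk.shape)

    img = 127.0 + alpha * (img - 127.0)
    img = img * gain
    if do_blur and sigma > 0:
        blur_sigma = (sigma, sigma) + (0,) * (img.ndim - 2)
        img = ndimage.gaussian_filter(img, sigma=blur_sigma)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, np.ascontiguousarray(msk)


def dice_loss(
    predicted: np.ndarray, target: np.ndarray, smooth: float = 1.0
) -> float:
    """Soft dice loss, averaged over leading class channels.

    ``1 - (2 * sum(p*t) + s) / (sum(p) + sum(t) + s)`` per channel, with
    smoothing constant ``s`` (default 1) guarding the empty-empty case.
    Predictions are scores in [0, 1]; targets are binary.
    """
    p = np.asarray(predicted, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise InputError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.ndim == 2:
        p = p[None]
        t = t[None]
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    return float(np.mean(1.0 - (2.0 * inter + smooth) / (denom + smooth)))


# Flat colours used by the phantom renderer.  The classes differ in
# chromaticity (not just lightness) so classification can be made invariant
# to the phantom's lighting-gain corruption.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (205, 158, 148),  # shaved skin
    "inner_skin": (212, 146, 130),  # erythematous skin inside the splint ring
    "wound": (152, 36, 44),         # open granulation tissue
    "ring": (236, 234, 222),        # silicone splint
    "occluder": (120, 120, 120),    # tape / hair / dressing
}

#: Maximum chromaticity distance for a pixel to be assigned a class at all.
_CHROMA_MAX_DISTANCE = 0.08
#: Pixels darker than this total RGB sum are left unclassified.
_MIN_BRIGHTNESS = 30.0


def _chromaticity(rgb: np.ndarray) -> np.ndarray:
    total = rgb.sum(axis=-1, keepdims=True)
    return rgb / np.maximum(total, 1e-9)


def reference_segment(
    crop: np.ndarray,
    palette: dict[str, tuple[int, int, int]] | None = None,
) -> ProbabilityMaps:
    """Deterministic palette-based segmentation of a phantom crop.

    Each pixel is assigned to the palette class with the nearest
    *chromaticity* (RGB normalized by brightness), which makes the
    classification invariant to the global lighting gain a scene may carry;
    pixels far from every class chromaticity, or too dark to carry colour,
    stay unassigned.  The wound channel is the wound class; the
    splint-inner channel is the inner-skin class with enclosed holes
    filled, which on an intact phantom reconstructs the full inner disk
    including the wound it surrounds.
    """
    if palette is None:
        palette = DEFAULT_PALETTE
    img = np.asarray(crop, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputError(f"expected an RGB crop, got shape {img.shape}")
    names = list(palette)
    rgb = np.array([palette[n] for n in names], dtype=np.float64)

    # Pass 1: chromaticity classification (gain-invariant) to locate skin
    # background, from which the global lighting gain is estimated.
    chroma_colors = _chromaticity(rgb)
    chroma = _chromaticity(img)
    cdists = np.linalg.norm(chroma[:, :, None, :] - chroma_colors[None, None], axis=-1)
    cnearest = np.argmin(cdists, axis=-1)
    cknown = (np.min(cdists, axis=-1) <= _CHROMA_MAX_DISTANCE) & (
        img.sum(axis=-1) >= _MIN_BRIGHTNESS
    )
    bg = cknown & (cnearest == names.index("background"))
    if bg.sum() >= 50:
        gain = float(
            np.median(img[bg].sum(axis=-1)) / rgb[names.index("background")].sum()
        )
    else:
        gain = 1.0

    # Pass 2: nearest-class in gain-normalized linear RGB.  Resampling and
    # blur mix colours linearly there, so boundary pixels split evenly
    # between their two classes instead of favouring the brighter one.
    norm = img / max(gain, 1e-6)
    dists = np.linalg.norm(norm[:, :, None, :] - rgb[None, None], axis=-1)
    nearest = np.argmin(dists, axis=-1)
    known = cknown | (np.min(dists, axis=-1) <= 60.0)

    def class_mask(name: str) -> np.ndarray:
        return known & (nearest == names.index(name))

    wound = class_mask("wound")
    # The inner disk is only a valid reference when its silicone ring is
    # actually visible: without that gate, the thin wound/skin mixing band
    # on splint-less frames closes into a ring and hole-filling would
    # fabricate an "inner disk" around a bare wound.
    if class_mask("ring").sum() >= 50:
        inner = ndimage.binary_fill_holes(class_mask("inner_skin"))
    else:
        inner = np.zeros(wound.shape, dtype=bool)
    return ProbabilityMaps(
        wound=wound.astype(np.uint8) * 255,
        splint=inner.astype(np.uint8) * 255,
    )
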