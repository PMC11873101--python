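"""Stochastic view augmentations for contrastive pair construction.

Three transforms — horizontal flip, crop-and-resize, and rectangular
occlusion — are each applied with probability 0.5 by default. A positive
pair consists of two independent augmentation draws from the same coronal
slice; in a batch of N pairs the views occupy positions 2k-1 and 2k
(1-based), i.e. consecutive even/odd rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .volume import SliceRecord

__all__ = ["AugmentConfig", "ViewPair", "random_horizontal_flip",
           "random_crop_resize", "random_occlusion", "augment_slice",
           "make_view_pair"]


@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform probabilities and magnitudes.

    The transform set and the 0.5 probabilities are fixed by the training
    protocol; crop scale and occlusion box fraction are free parameters.
    """

    flip_p: float = 0.5
    crop_p: float = 0.5
    crop_scale: tuple[float, float] = (0.6, 1.0)
    occlude_p: float = 0.5
    occlude_fraction: tuple[float, float] = (0.05, 0.2)
    occlude_fill: float = 0.0


def random_horizontal_flip(x: np.ndarray, p: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Mirror along the left-right (second) axis with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if rng.random() < p:
        return x[:, ::-1].copy()
    return x


def random_crop_resize(x: np.ndarray, scale_range: tuple[float, float],
                       p: float, rng: np.random.Generator) -> np.ndarray:
    """Random area-fraction crop, resized back to the input shape (bilinear)."""
    lo, hi = scale_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("scale_range must be within (0, 1]")
    if rng.random() >= p:
        return x
    h, w = x.shape
    area = rng.uniform(lo, hi)
    side = np.sqrt(area)
    # clamp to at least 2x2 so interpolation stays well defined
    ch = max(2, int(round(side * h)))
    cw = max(2, int(round(side * w)))
    top = rng.integers(0, h - ch + 1)
    left = rng.integers(0, w - cw + 1)
    crop = x[top:top + ch, left:left + cw]
    if crop.shape == x.shape:
        return crop.copy()
    return resize(crop, x.shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True).astype(x.dtype)


def random_occlusion(x: np.ndarray, box_fraction_range: tuple[float, float],
                     p: float, fill: float, rng: np.random.Generator) -> np.ndarray:
    """Set a random axis-aligned rectangle (area fraction from range) to fill."""
    lo, hi = box_fraction_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("box fractions must lie in (0, 1)")
    if rng.random() >= p:
        return x
    h, w = x.shape
    area = rng.uniform(lo, hi)
    side = np.sqrt(area)
    bh = max(1, int(round(side * h)))
    bw = max(1, int(round(side * w)))
    top = rng.integers(0, h - bh + 1)
    left = rng.integers(0, w - bw + 1)
    out = x.copy()
    out[top:top + bh, left:left + bw] = fill
    return out


def augment_slice(x: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """One stochastic view: flip, then crop-resize, then occlusion."""
    x = random_horizontal_flip(x, cfg.flip_p, rng)
    x = random_crop_resize(x, cfg.crop_scale, cfg.crop_p, rng)
    x = random_occlusion(x, cfg.occlude_fraction, cfg.occlude_p,
                         cfg.occlude_fill, rng)
    return x


@dataclass
class ViewPair:
    """Two augmented views of one source slice."""

    view_a: np.ndarray
    view_b: np.ndarray
    source: SliceRecord

    def __post_init__(self) -> None:
        if self.view_a.shape != self.view_b.shape:
            raise ValueError("paired views must share a shape")


def make_view_pair(s: SliceRecord, cfg: AugmentConfig,
                   rng: np.random.Generator) -> ViewPair:
    """Two independent augmentation draws of the same slice (both augmented)."""
    return ViewPair(
        view_a=augment_slice(s.pixels, cfg, rng),
        view_b=augment_slice(s.pixels, cfg, rng),
        source=s,
    )
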