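"""Resize/normalize, paired geometric augmentation, and artifact reduction.

All geometry is applied identically to image and mask: the affine part
(rotate -> scale -> translate, in that fixed order, about the image centre)
is composed into a single warp, images are resampled bilinearly, masks with
nearest neighbour and re-binarized.  Out-of-canvas pixels are filled with 0,
matching the background semantics of the masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, resize, warp

from .synthetic import ImagePair


@dataclass
class AugmentConfig:
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.90, 1.10)
    translate_frac: tuple[float, float] = (-0.10, 0.10)
    flip_h: float = 0.5
    flip_v: float = 0.5
    apply_prob: float = 0.5  # per-transform gate for rotation/scale/translation
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.rotation_deg
        if not (-180.0 <= lo <= hi <= 180.0):
            raise ValueError("rotation_deg must be an interval within [-180, 180]")
        if self.scale_range[0] <= 0:
            raise ValueError("scale_range must be positive")
        for p in (self.flip_h, self.flip_v, self.apply_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class GeomTransform:
    """One sampled geometric transform, shared by image and mask."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translate: tuple[float, float] = (0.0, 0.0)  # (dy, dx) as fractions of side
    flip_h: bool = False
    flip_v: bool = False

    @property
    def is_identity(self) -> bool:
        return (self.rotation_deg == 0.0 and self.scale == 1.0
                and self.translate == (0.0, 0.0)
                and not self.flip_h and not self.flip_v)


def sample_transform(config: AugmentConfig, rng: np.random.Generator) -> GeomTransform:
    """Draw one transform; rotation/scale/translation are each gated by
    ``apply_prob``, flips by their own probabilities."""
    rot = (rng.uniform(*config.rotation_deg)
           if rng.random() < config.apply_prob else 0.0)
    scale = (rng.uniform(*config.scale_range)
             if rng.random() < config.apply_prob else 1.0)
    if rng.random() < config.apply_prob:
        translate = (rng.uniform(*config.translate_frac),
                     rng.uniform(*config.translate_frac))
    else:
        translate = (0.0, 0.0)
    return GeomTransform(
        rotation_deg=rot, scale=scale, translate=translate,
        flip_h=rng.random() < config.flip_h,
        flip_v=rng.random() < config.flip_v,
    )


def _affine_matrix(t: GeomTransform, shape: tuple[int, int]) -> np.ndarray:
    """Forward homogeneous matrix in (x, y) convention: rotation and scaling
    about the image centre, then translation."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = np.deg2rad(t.rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    rs = np.array([[t.scale * c, -t.scale * s, 0.0],
                   [t.scale * s, t.scale * c, 0.0],
                   [0.0, 0.0, 1.0]])
    to_centre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    back = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    dy, dx = t.translate
    shift = np.array([[1, 0, dx * w], [0, 1, dy * h], [0, 0, 1.0]])
    return shift @ back @ rs @ to_centre


def apply_transform(arr: np.ndarray, t: GeomTransform, order: int) -> np.ndarray:
    """Apply ``t`` to a 2-D array; ``order`` 1 = bilinear (images),
    0 = nearest neighbour (masks)."""
    arr = np.asarray(arr, dtype=np.float64)
    out = arr.copy()
    if t.rotation_deg != 0.0 or t.scale != 1.0 or t.translate != (0.0, 0.0):
        tform = AffineTransform(matrix=_affine_matrix(t, arr.shape))
        out = warp(out, tform.inverse, order=order, cval=0.0, preserve_range=True)
    if t.flip_h:
        out = out[:, ::-1]
    if t.flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_pair(pair: ImagePair, config: AugmentConfig,
                 rng: np.random.Generator) -> ImagePair:
    """Sample one transform and apply it to image (bilinear) and mask
    (nearest neighbour, re-binarized) identically."""
    t = sample_transform(config, rng)
    if t.is_identity:
        return ImagePair(image=pair.image.copy(), mask=pair.mask.copy(), id=pair.id)
    image = np.clip(apply_transform(pair.image, t, order=1), 0.0, 1.0)
    mask = (apply_transform(pair.mask, t, order=0) >= 0.5).astype(np.uint8)
    return ImagePair(image=image, mask=mask, id=pair.id)


def resize_normalize(pair: ImagePair, size: int) -> ImagePair:
    """Resize to ``size`` x ``size`` and scale intensities to [0, 1].

    8-bit style inputs (integer dtype or values above 1) are divided by 255;
    masks are resampled with nearest neighbour and re-thresholded at 0.5.
    """
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    image = np.asarray(pair.image, dtype=np.float64)
    if np.issubdtype(np.asarray(pair.image).dtype, np.integer) or image.max() > 1.0:
        image = image / 255.0
    if image.shape != (size, size):
        image = resize(image, (size, size), order=1, preserve_range=True,
                       anti_aliasing=False)
    image = np.clip(image, 0.0, 1.0)
    mask = pair.mask
    if mask.shape != (size, size):
        mask = resize(mask.astype(np.float64), (size, size), order=0,
                      preserve_range=True, anti_aliasing=False)
        mask = (mask >= 0.5).astype(np.uint8)
    return ImagePair(image=image, mask=mask, id=pair.id)


def gaussian_denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with the stated sigma; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    return gaussian_filter(image, sigma=sigma)


def hist_equalize(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization on the 8-bit quantized intensity.

    Classic CDF remapping: level v maps to
    ``(cdf(v) - cdf_min) / (n_pixels - cdf_min)``; a constant image is
    returned unchanged (degenerate CDF).  Output is in [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("hist_equalize expects intensities in [0, 1]")
    q = np.rint(image * 255).astype(np.int64)
    hist = np.bincount(q.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = hist > 0
    cdf_min = cdf[nonzero][0]
    n = q.size
    if n == cdf_min:  # single occupied level
        return image.copy()
    lut = (cdf - cdf_min) / (n - cdf_min)
    lut = np.clip(lut, 0.0, 1.0)
    return lut[q]
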