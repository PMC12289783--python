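"""Synthetic imbalanced-lesion image/mask generator.

Desk-scale stand-in for ultrasound/CT lesion segmentation corpora: each
sample is a textured grayscale background carrying a small number of smooth
bright blobs (randomly oriented ellipses with low-order angular harmonics on
the radius), with the pixel-level foreground fraction controlled to a target
interval.  Presets mirror the imbalance regimes typical of thyroid-nodule
and breast-lesion ultrasound (about 1:9 foreground:background) and liver-CT
tumours (about 1:50).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

MANIFEST_NAME = "manifest.tsv"


@dataclass
class ImagePair:
    """An image and its aligned binary mask; the unit of training/evaluation."""

    image: np.ndarray  # [H,W] float64 in [0,1]
    mask: np.ndarray   # [H,W] uint8 in {0,1}
    id: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape[-2:] != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch for {self.id}: "
                f"{self.image.shape} vs {self.mask.shape}")
        uniq = np.unique(self.mask)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"mask for {self.id} must be binary, got values {uniq}")
        self.mask = self.mask.astype(np.uint8)

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class SyntheticConfig:
    n_images: int = 100
    image_size: int = 256
    fg_fraction_range: tuple[float, float] = (0.08, 0.12)
    n_lesions_range: tuple[int, int] = (1, 3)
    lesion_contrast: float = 0.35
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.fg_fraction_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("fg_fraction_range must lie inside (0, 0.5)")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if 1.0 / self.image_size**2 > hi:
            raise ValueError(
                "fg_fraction_range infeasible: a single pixel "
                f"({1.0 / self.image_size ** 2:.2e}) exceeds the upper bound {hi}")
        if self.n_lesions_range[0] < 0 or self.n_lesions_range[0] > self.n_lesions_range[1]:
            raise ValueError("n_lesions_range must be a non-negative interval")

    # imbalance-regime presets (foreground fraction intervals)
    @classmethod
    def ddti_like(cls, **kw) -> "SyntheticConfig":
        """~1:9 nodule:background, typical of thyroid ultrasound."""
        return cls(fg_fraction_range=(0.08, 0.12), **kw)

    @classmethod
    def busi_like(cls, **kw) -> "SyntheticConfig":
        """~1:9 lesion:background, typical of breast ultrasound."""
        return cls(fg_fraction_range=(0.08, 0.12), **kw)

    @classmethod
    def lits_like(cls, **kw) -> "SyntheticConfig":
        """~1:50 tumour:background, typical of liver CT."""
        return cls(fg_fraction_range=(0.015, 0.025), **kw)


def _blob_mask(size: int, center, axes, angle: float, harmonics) -> np.ndarray:
    """Rasterize one deformed ellipse: inside iff the elliptic radius is below
    1 + sum_k a_k cos(k*theta + phi_k)."""
    cy, cx = center
    a, b = axes
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * x + sa * y) / a
    v = (-sa * x + ca * y) / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    bound = 1.0
    for k, amp, phase in harmonics:
        bound = bound + amp * np.cos(k * theta + phase)
    return rho <= bound


def _sample_mask(size: int, target: float, n_lesions: int,
                 rng: np.random.Generator) -> np.ndarray:
    if n_lesions == 0:
        return np.zeros((size, size), dtype=np.uint8)
    weights = rng.uniform(0.5, 1.0, n_lesions)
    weights /= weights.sum()
    specs = []
    for w in weights:
        area = w * target * size * size
        aspect = rng.uniform(0.65, 1.5)
        a = np.sqrt(area * aspect / np.pi)
        b = area / (np.pi * a)
        margin = min(1.3 * max(a, b) + 2, size / 2 - 1)
        center = rng.uniform(margin, size - margin, 2)
        angle = rng.uniform(0, np.pi)
        harmonics = [(k, rng.uniform(0.0, 0.12), rng.uniform(0, 2 * np.pi))
                     for k in (2, 3)]
        specs.append([center, a, b, angle, harmonics])

    scale = 1.0
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(15):
        mask = np.zeros((size, size), dtype=bool)
        for center, a, b, angle, harmonics in specs:
            mask |= _blob_mask(size, center, (max(scale * a, 0.8), max(scale * b, 0.8)),
                               angle, harmonics)
        frac = mask.mean()
        if frac <= 0:
            scale *= 1.5
            continue
        ratio = target / frac
        if 0.995 <= ratio <= 1.005:
            break
        scale *= np.sqrt(ratio)
    return mask.astype(np.uint8)


def generate_dataset(config: SyntheticConfig) -> list[ImagePair]:
    """Generate ``config.n_images`` image/mask pairs, deterministic per seed.

    Each mask's foreground fraction is driven into ``fg_fraction_range`` by
    rescaling the blob radii (up to rasterization quantization); images are
    background texture + ``lesion_contrast`` * smoothed mask + Gaussian noise,
    clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.fg_fraction_range
    size = config.image_size
    pairs = []
    for i in range(config.n_images):
        n_lesions = int(rng.integers(config.n_lesions_range[0],
                                     config.n_lesions_range[1] + 1))
        mask = np.zeros((size, size), dtype=np.uint8)
        if n_lesions > 0:
            for _attempt in range(6):
                target = rng.uniform(lo, hi)
                mask = _sample_mask(size, target, n_lesions, rng)
                if lo <= mask.mean() <= hi:
                    break

        texture = rng.normal(size=(size, size))
        texture = gaussian_filter(texture, sigma=size / 16.0)
        sd = texture.std()
        if sd > 0:
            texture = texture / sd
        image = 0.40 + 0.05 * texture
        if mask.any():
            image = image + config.lesion_contrast * gaussian_filter(
                mask.astype(np.float64), sigma=1.0)
        image = image + rng.normal(0.0, config.noise_sd, size=(size, size))
        image = np.clip(image, 0.0, 1.0)
        pairs.append(ImagePair(image=image, mask=mask, id=f"synth-{i:04d}"))
    return pairs


def write_pairs(pairs: list[ImagePair], directory: str | os.PathLike) -> str:
    """Write 8-bit grayscale PNGs (masks as 0/255) plus a TSV manifest.

    Returns the manifest path.  Re-reading reproduces masks exactly and
    images within 8-bit quantization (1/255 per pixel).
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = os.path.join(directory, MANIFEST_NAME)
    with open(manifest, "w") as fh:
        fh.write("id\timage\tmask\n")
        for pair in pairs:
            img_name = f"{pair.id}_image.png"
            msk_name = f"{pair.id}_mask.png"
            img8 = np.rint(np.clip(pair.image, 0, 1) * 255).astype(np.uint8)
            iio.imwrite(os.path.join(directory, img_name), img8)
            iio.imwrite(os.path.join(directory, msk_name), pair.mask * np.uint8(255))
            fh.write(f"{pair.id}\t{img_name}\t{msk_name}\n")
    return manifest


def read_pairs(directory: str | os.PathLike) -> list[ImagePair]:
    """Read pairs written by :func:`write_pairs`; an empty or manifest-less
    directory yields an empty list."""
    directory = os.fspath(directory)
    manifest = os.path.join(directory, MANIFEST_NAME)
    if not os.path.exists(manifest):
        return []
    pairs = []
    with open(manifest) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if not line:
                continue
            pid, img_name, msk_name = line.split("\t")
            img_path = os.path.join(directory, img_name)
            msk_path = os.path.join(directory, msk_name)
            if not os.path.exists(img_path):
                raise FileNotFoundError(f"missing image for id {pid!r}: {img_path}")
            if not os.path.exists(msk_path):
                raise FileNotFoundError(f"missing mask for id {pid!r}: {msk_path}")
            image = np.asarray(iio.imread(img_path), dtype=np.float64) / 255.0
            mask = (np.asarray(iio.imread(msk_path)) >= 128).astype(np.uint8)
            pairs.append(ImagePair(image=image, mask=mask, id=pid))
    return pairs
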