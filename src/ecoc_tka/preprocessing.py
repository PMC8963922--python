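"""Radiograph cleaning and tabular feature encoding.

Knee films carry burned-in annotations (patient text, side markers) in the
margins plus acquisition noise.  The cleaning pipeline applies, in order:

1. CLAHE — contrast-limited adaptive histogram equalization — to normalize
   local contrast across exposure conditions;
2. mean-shift smoothing in the joint spatial-intensity domain, an
   edge-preserving denoiser (pixels only average with spatial neighbours of
   similar intensity, so bone edges survive while film grain is flattened);
3. a central crop that discards the annotated margins.

Tabular features: gender is one-hot encoded (male, female); height and
weight are z-scored against statistics computed from the *training split
only* — test-set statistics must never leak into the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import exposure

__all__ = [
    "CropSpec",
    "RadiographPair",
    "TrainStats",
    "TabularFeatures",
    "clahe",
    "mean_shift_smooth",
    "crop",
    "preprocess_radiograph",
    "encode_tabular",
    "image_descriptor",
]

_GENDER_CODES = {
    "male": 0, "m": 0, "1": 0,
    "female": 1, "f": 1, "0": 1,
}


@dataclass
class CropSpec:
    """Crop window: top-left corner and output size, in pixels."""

    top: int
    left: int
    height: int
    width: int

    @classmethod
    def central(cls, shape: tuple[int, int], fraction: float = 0.85) -> "CropSpec":
        """Central window covering ``fraction`` of each dimension."""
        h = int(round(shape[0] * fraction))
        w = int(round(shape[1] * fraction))
        return cls(top=(shape[0] - h) // 2, left=(shape[1] - w) // 2, height=h, width=w)


@dataclass
class RadiographPair:
    """Anterior-posterior and lateral 8-bit grayscale knee images."""

    ap: np.ndarray
    lateral: np.ndarray

    def __post_init__(self):
        for name in ("ap", "lateral"):
            img = np.asarray(getattr(self, name))
            if img.ndim != 2 or img.size == 0:
                raise ValueError(f"{name} image must be a non-empty 2-D array")
            if img.min() < 0 or img.max() > 255:
                raise ValueError(f"{name} intensities must lie in [0, 255]")
            setattr(self, name, img.astype(np.uint8))


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    return img.astype(np.uint8)


def clahe(image: np.ndarray, clip_limit: float = 0.02, tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    ``clip_limit`` is the fractional clip of scikit-image (0..1);
    ``tile_grid`` sets the number of contextual tiles per axis.  A constant
    image has no contrast to redistribute and is returned unchanged.
    """
    img = _check_image(image)
    if img.max() == img.min():
        return img.copy()
    kernel = (max(1, img.shape[0] // tile_grid[0]), max(1, img.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(np.round(out * 255), 0, 255).astype(np.uint8)


def mean_shift_smooth(
    image: np.ndarray,
    spatial_bw: int = 5,
    range_bw: float = 10.0,
    max_iter: int = 3,
) -> np.ndarray:
    """Joint spatial-range mean-shift smoothing with flat kernels.

    Each pixel's intensity moves toward the mean of neighbours within a
    ``(2*spatial_bw + 1)``-pixel square window whose intensity differs by at
    most ``range_bw`` levels; repeated ``max_iter`` times.  This seeks local
    intensity modes: homogeneous regions flatten while edges (large intensity
    jumps) are preserved.
    """
    img = _check_image(image).astype(float)
    if spatial_bw < 1 or range_bw <= 0:
        raise ValueError("bandwidths must be positive")
    r = int(spatial_bw)
    for _ in range(max_iter):
        padded = np.pad(img, r, mode="edge")
        acc = np.zeros_like(img)
        cnt = np.zeros_like(img)
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                shifted = padded[r + dy: r + dy + img.shape[0], r + dx: r + dx + img.shape[1]]
                inside = np.abs(shifted - img) <= range_bw
                acc += np.where(inside, shifted, 0.0)
                cnt += inside
        img = acc / cnt  # cnt >= 1: the centre pixel always matches itself
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def crop(image: np.ndarray, spec: CropSpec) -> np.ndarray:
    """Crop to ``spec``; the window must lie fully inside the image."""
    img = _check_image(image)
    if spec.top < 0 or spec.left < 0 or spec.height < 1 or spec.width < 1:
        raise ValueError("crop window must be positive and inside the image")
    if spec.top + spec.height > img.shape[0] or spec.left + spec.width > img.shape[1]:
        raise ValueError(
            f"crop {spec} exceeds image bounds {img.shape}"
        )
    return img[spec.top: spec.top + spec.height, spec.left: spec.left + spec.width].copy()


def preprocess_radiograph(
    pair: RadiographPair,
    clip_limit: float = 0.02,
    tile_grid: tuple[int, int] = (8, 8),
    spatial_bw: int = 5,
    range_bw: float = 10.0,
    crop_spec: CropSpec | None = None,
    crop_fraction: float = 0.85,
) -> RadiographPair:
    """CLAHE -> mean-shift smoothing -> crop, applied to both views.

    With no explicit ``crop_spec`` the central ``crop_fraction`` of each
    dimension is kept, which removes margin annotations.  Deterministic:
    identical input and parameters give identical output bytes.
    """
    def one(img: np.ndarray) -> np.ndarray:
        spec = crop_spec or CropSpec.central(img.shape, crop_fraction)
        out = clahe(img, clip_limit=clip_limit, tile_grid=tile_grid)
        out = mean_shift_smooth(out, spatial_bw=spatial_bw, range_bw=range_bw)
        return crop(out, spec)

    return RadiographPair(ap=one(pair.ap), lateral=one(pair.lateral))


# ---------------------------------------------------------------------------
# Tabular features
# ---------------------------------------------------------------------------

@dataclass
class TrainStats:
    """Standardization statistics, fitted on the training split only."""

    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float

    def __post_init__(self):
        if self.height_sd <= 0 or self.weight_sd <= 0:
            raise ValueError("standard deviations must be positive")

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "TrainStats":
        return cls(
            height_mean=float(train["height_cm"].mean()),
            height_sd=float(train["height_cm"].std(ddof=0)),
            weight_mean=float(train["weight_kg"].mean()),
            weight_sd=float(train["weight_kg"].std(ddof=0)),
        )


@dataclass
class TabularFeatures:
    """One-hot gender plus z-scored height and weight (and optional BMI)."""

    gender_onehot: np.ndarray
    height_z: float
    weight_z: float
    bmi: float | None = None

    def as_vector(self, use_bmi: bool = False) -> np.ndarray:
        base = [*self.gender_onehot, self.height_z, self.weight_z]
        if use_bmi:
            base.append(self.bmi)
        return np.asarray(base, dtype=float)


def encode_tabular(
    gender: str | int,
    height_cm: float,
    weight_kg: float,
    train_stats: TrainStats,
) -> TabularFeatures:
    """Encode one patient's tabular features against training statistics.

    Gender accepts 'male'/'female' (case-insensitive), 'M'/'F', or the 0/1
    codes used in cohort tables (1 = male).  One-hot column order is fixed to
    (male, female).
    """
    code = _GENDER_CODES.get(str(gender).strip().lower())
    if code is None:
        raise ValueError(f"unknown gender code: {gender!r}")
    onehot = np.zeros(2)
    onehot[code] = 1.0
    height_m = height_cm / 100.0
    return TabularFeatures(
        gender_onehot=onehot,
        height_z=(height_cm - train_stats.height_mean) / train_stats.height_sd,
        weight_z=(weight_kg - train_stats.weight_mean) / train_stats.weight_sd,
        bmi=weight_kg / (height_m * height_m),
    )


def image_descriptor(image: np.ndarray, grid: int = 8) -> np.ndarray:
    """Compact descriptor of a preprocessed film for the desk-scale learner.

    Concatenates a ``grid x grid`` block-mean downsample with the full row
    and column mean-intensity profiles, all scaled to [0, 1].  The profiles
    carry the silhouette widths that encode component size.
    """
    img = _check_image(image).astype(float) / 255.0
    h, w = img.shape
    ys = np.linspace(0, h, grid + 1).astype(int)
    xs = np.linspace(0, w, grid + 1).astype(int)
    blocks = np.array(
        [img[ys[i]: ys[i + 1], xs[j]: xs[j + 1]].mean() for i in range(grid) for j in range(grid)]
    )
    return np.concatenate([blocks, img.mean(axis=1), img.mean(axis=0)])
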