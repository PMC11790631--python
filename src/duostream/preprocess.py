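"""Five-step image preprocessing: Canny edges, minimal-square background
crop, resize, rotation augmentation, per-channel normalization.

The crop step finds the bounding box of all edge pixels and cuts the
smallest axis-aligned square containing it, centered on the box and shifted
inward at image borders (never padded).  Normalization defaults to the
ImageNet channel statistics, since the canonical training recipe transfers
ImageNet-pretrained shallow weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import feature as _skfeature
from skimage import transform as _sktransform

# ITU-R 601 luminance weights for grayscale conversion before Canny
_LUMA = np.array([0.299, 0.587, 0.114])

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

#: speckle guard: never crop below this side length
MIN_CROP_SIDE = 8


@dataclass
class PreprocessConfig:
    canny_low: float = 50.0
    canny_high: float = 150.0
    target_size: int = 224
    max_rotation_deg: float = 15.0
    normalization_mean: tuple = IMAGENET_MEAN
    normalization_std: tuple = IMAGENET_STD
    augment: bool = False
    #: when augmenting, rotate front and back by the same angle if True
    lock_rotation: bool = False

    def __post_init__(self):
        if not (0 < self.canny_low < self.canny_high):
            raise ValueError("need 0 < canny_low < canny_high")
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if any(s <= 0 for s in self.normalization_std):
            raise ValueError("normalization std entries must be > 0")

    def to_dict(self) -> dict:
        return {
            "canny_low": self.canny_low,
            "canny_high": self.canny_high,
            "target_size": self.target_size,
            "max_rotation_deg": self.max_rotation_deg,
            "normalization_mean": list(self.normalization_mean),
            "normalization_std": list(self.normalization_std),
            "augment": self.augment,
            "lock_rotation": self.lock_rotation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        d["normalization_mean"] = tuple(d.get("normalization_mean", IMAGENET_MEAN))
        d["normalization_std"] = tuple(d.get("normalization_std", IMAGENET_STD))
        return cls(**d)


@dataclass
class ViewPair:
    """A preprocessed (front, back) pair: two equal-shape normalized HWC tensors."""

    front: np.ndarray
    back: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        if self.front.shape != self.back.shape:
            raise ValueError("front/back shapes differ")
        if not (np.isfinite(self.front).all() and np.isfinite(self.back).all()):
            raise ValueError("non-finite values in view pair")


def detect_edges(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Boolean Canny edge mask on the 8-bit luminance image."""
    img = np.asarray(image, dtype=np.float64)
    gray = img @ _LUMA if img.ndim == 3 else img
    return _skfeature.canny(
        gray, sigma=1.0, low_threshold=config.canny_low, high_threshold=config.canny_high
    )


def min_square_crop(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Smallest square sub-image containing all true mask pixels.

    The square is centered on the edge bounding box and shifted inward when
    it would cross an image border.  An empty mask returns the input
    unchanged; the side never drops below ``MIN_CROP_SIDE`` (speckle guard).
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} sizes differ")
    window = crop_window(mask)
    if window is None:
        return image
    top, left, side = window
    return image[top : top + side, left : left + side]


def crop_window(mask: np.ndarray):
    """(top, left, side) of the minimal-square crop, or None for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    h, w = mask.shape
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    side = max(r1 - r0 + 1, c1 - c0 + 1, MIN_CROP_SIDE)
    side = min(side, h, w)
    top = _center_interval(r0, r1, side, h)
    left = _center_interval(c0, c1, side, w)
    return top, left, side


def _center_interval(lo: int, hi: int, side: int, limit: int) -> int:
    """Start of a length-``side`` interval centered on [lo, hi], clipped to [0, limit)."""
    center2 = lo + hi  # 2 * center, avoids float arithmetic
    start = (center2 + 1 - side) // 2
    return int(np.clip(start, 0, limit - side))


def resize_image(image: np.ndarray, target_size: int) -> np.ndarray:
    """Resize to target_size x target_size x 3 (aspect not preserved)."""
    img = np.asarray(image, dtype=np.float64)
    if img.shape[:2] == (target_size, target_size):
        return img
    return _sktransform.resize(
        img, (target_size, target_size), order=1, preserve_range=True, anti_aliasing=True
    )


def augment_rotation(image: np.ndarray, max_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate by an angle uniform on [-max_deg, +max_deg] (bilinear, black fill)."""
    if max_deg < 0:
        raise ValueError("max_deg must be >= 0")
    if max_deg == 0:
        return np.asarray(image, dtype=np.float64)
    angle = rng.uniform(-max_deg, max_deg)
    return _sktransform.rotate(
        np.asarray(image, dtype=np.float64),
        angle,
        resize=False,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )


def normalize_image(image: np.ndarray, mean, std) -> np.ndarray:
    """(pixel/255 - mean) / std per channel."""
    mean = np.asarray(mean, dtype=np.float64)
    std = np.asarray(std, dtype=np.float64)
    if np.any(std <= 0):
        raise ValueError("std entries must be > 0")
    return (np.asarray(image, dtype=np.float64) / 255.0 - mean) / std


def preprocess_image(image: np.ndarray, config: PreprocessConfig, rng=None) -> np.ndarray:
    """Full single-view pipeline: edges -> crop -> resize -> (rotate) -> normalize."""
    mask = detect_edges(image, config)
    out = min_square_crop(image, mask)
    out = resize_image(out, config.target_size)
    if config.augment:
        if rng is None:
            raise ValueError("augmentation requires an rng")
        out = augment_rotation(out, config.max_rotation_deg, rng)
    return normalize_image(out, config.normalization_mean, config.normalization_std)


def preprocess_pipeline(raw_pair, config: PreprocessConfig, rng=None, pair_id: str = "") -> ViewPair:
    """Apply the pipeline independently to the front and back views.

    With ``config.lock_rotation`` both views get the same rotation angle
    (one rng substream per view otherwise).
    """
    front_raw, back_raw = raw_pair
    if config.augment and config.lock_rotation:
        seed = rng.integers(0, 2**31)
        rng_f = np.random.default_rng(seed)
        rng_b = np.random.default_rng(seed)
    else:
        rng_f = rng_b = rng
    front = preprocess_image(front_raw, config, rng_f)
    back = preprocess_image(back_raw, config, rng_b)
    return ViewPair(front=front, back=back, provenance=pair_id)
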