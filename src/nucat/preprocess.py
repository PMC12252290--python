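"""ROI extraction and image preprocessing for slit-lamp pupil images.

The pipeline's two classifiers both consume 224x224 RGB crops of the pupil
region. Raw inputs arrive either as RGBA images whose alpha channel marks the
manually extracted pupil (transparent background), or as a full eye image plus
a user-drawn circle. This module turns both into normalized model inputs:

1. ``apply_circular_roi`` — rasterize a circle selection into an alpha mask;
2. ``extract_visible_roi`` — tight-crop to the alpha>0 bounding box, composite
   transparent pixels onto black, and resize with area (box-filter)
   interpolation to 224x224;
3. ``normalize_for_model`` — scale to [0,1] and standardize with the ImageNet
   channel statistics.

Conventions: 0-based (row, col) pixel coordinates, top-left origin; images are
uint8 numpy arrays H x W x C; model inputs are float32 (3, 224, 224) CHW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

INPUT_SIZE = 224
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


class EmptyRoiError(ValueError):
    """Raised when a selection or alpha mask covers no pixel."""


@dataclass(frozen=True)
class CircleSpec:
    """Circular pupil selection: center in (x, y) pixel coordinates, radius in px."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class AugmentationSpec:
    """Training-time augmentation: flip, small rotation, brightness/contrast jitter."""

    hflip_prob: float = 0.5
    rotation_range: float = 15.0
    jitter_factor: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be in [0, 1]")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        if self.jitter_factor < 0:
            raise ValueError("jitter_factor must be >= 0")


def apply_circular_roi(image: np.ndarray, circle: CircleSpec) -> np.ndarray:
    """Turn an H x W x 3 image into RGBA with alpha=255 inside the circle.

    A pixel is inside when its center (row+0, col+0 in index coordinates) lies
    within ``radius`` (inclusive) of ``(center_y, center_x)``. RGB is unchanged.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    d2 = (rows - circle.center_y) ** 2 + (cols - circle.center_x) ** 2
    mask = d2 <= circle.radius ** 2
    if not mask.any():
        raise EmptyRoiError("circle does not cover any pixel (empty ROI)")
    out = np.empty((h, w, 4), dtype=np.uint8)
    out[:, :, :3] = img
    out[:, :, 3] = np.where(mask, 255, 0).astype(np.uint8)
    return out


def alpha_bounding_box(rgba: np.ndarray) -> tuple[int, int, int, int]:
    """Minimal (row0, row1, col0, col1) inclusive box containing all alpha>0 pixels."""
    alpha = rgba[:, :, 3]
    rows = np.flatnonzero(alpha.any(axis=1))
    cols = np.flatnonzero(alpha.any(axis=0))
    if rows.size == 0:
        raise EmptyRoiError("no visible pixels (all alpha = 0)")
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def extract_visible_roi(rgba: np.ndarray, size: int = INPUT_SIZE) -> np.ndarray:
    """Crop an RGBA image to its visible region and resize to ``size`` square.

    Transparent pixels inside the bounding box are composited onto black before
    the box-filter (area) resize, so only masked pupil pixels contribute.
    Returns a uint8 size x size x 3 array.
    """
    img = np.asarray(rgba)
    if img.ndim != 3 or img.shape[2] != 4:
        raise ValueError(f"expected H x W x 4 RGBA image, got shape {img.shape}")
    r0, r1, c0, c1 = alpha_bounding_box(img)
    crop = img[r0:r1 + 1, c0:c1 + 1]
    rgb = crop[:, :, :3].astype(np.uint8)
    visible = (crop[:, :, 3] > 0)[:, :, None]
    rgb = np.where(visible, rgb, 0).astype(np.uint8)
    if rgb.shape[0] == size and rgb.shape[1] == size:
        return rgb
    resized = Image.fromarray(rgb, "RGB").resize((size, size), Image.BOX)
    return np.asarray(resized, dtype=np.uint8)


def normalize_for_model(image: np.ndarray) -> np.ndarray:
    """224x224x3 uint8 -> float32 CHW tensor, [0,1]-scaled then ImageNet-standardized."""
    img = np.asarray(image)
    if img.shape != (INPUT_SIZE, INPUT_SIZE, 3):
        raise ValueError(f"expected ({INPUT_SIZE}, {INPUT_SIZE}, 3), got {img.shape}")
    x = img.astype(np.float32) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def denormalize(tensor: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_for_model`, back to uint8 HWC."""
    x = tensor.transpose(1, 2, 0) * IMAGENET_STD + IMAGENET_MEAN
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def tensor_to_intensity(tensor: np.ndarray) -> np.ndarray:
    """ImageNet-normalized CHW tensor -> [0,1] intensity CHW (autoencoder scale)."""
    x = tensor * IMAGENET_STD[:, None, None] + IMAGENET_MEAN[:, None, None]
    return np.clip(x, 0.0, 1.0).astype(np.float32)


def augment(image: np.ndarray, spec: AugmentationSpec,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """One stochastic augmentation draw: flip -> rotate -> brightness -> contrast.

    Rotation exposes corners, which are filled black, matching the black
    composite background of the ROI crops. Deterministic given the generator
    state (or ``spec.seed`` when no generator is supplied).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out = img
    if rng.random() < spec.hflip_prob:
        out = out[:, ::-1, :]
    angle = rng.uniform(-spec.rotation_range, spec.rotation_range)
    if angle != 0.0:
        pil = Image.fromarray(np.ascontiguousarray(out), "RGB")
        pil = pil.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
        out = np.asarray(pil)
    brightness = rng.uniform(1 - spec.jitter_factor, 1 + spec.jitter_factor)
    contrast = rng.uniform(1 - spec.jitter_factor, 1 + spec.jitter_factor)
    x = out.astype(np.float32) * brightness
    mean = x.mean()
    x = (x - mean) * contrast + mean
    return np.clip(np.round(x), 0, 255).astype(np.uint8)


def load_image_as_model_input(path) -> np.ndarray:
    """Read PNG/JPEG, run the full preprocessing chain, return a CHW tensor."""
    with Image.open(path) as pil:
        if pil.mode == "RGBA":
            arr = np.asarray(pil)
            rgb = extract_visible_roi(arr)
        else:
            rgb = np.asarray(pil.convert("RGB"))
            if rgb.shape[:2] != (INPUT_SIZE, INPUT_SIZE):
                rgb = np.asarray(Image.fromarray(rgb).resize(
                    (INPUT_SIZE, INPUT_SIZE), Image.BOX))
    return normalize_for_model(rgb)
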