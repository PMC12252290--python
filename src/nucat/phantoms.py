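"""Synthetic slit-lamp eye phantoms with a controllable nuclear-cataract grade.

Real inputs are slit-lamp photographs of the pupil, graded 1-6 for nuclear
cataract (NC) on the LOCS III scale, plus an IOL class (pseudophakic eyes with
a clear artificial lens). The clinical database cannot ship with the package,
so this module renders simplified phantoms that reproduce the features the
pipeline actually keys on:

* a roughly circular pupil disc on a darker iris-textured background;
* for grade g in 1..6, a central nuclear opacity whose yellow-brown chroma and
  brightness ramp up strictly monotonically with g (opacity strength
  (g - 0.5) / 6);
* for IOL, a dark low-chroma pupil with a few small specular glints from the
  lens implant and a faint bluish rim reflex;
* Gaussian pixel noise and an optional saturated overexposure patch emulating
  poor acquisition.

Rendering is fully deterministic given (spec, seed); per-image seeds in
``generate_dataset`` derive from the master seed via ``numpy`` SeedSequence so
datasets are reproducible and order-independent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import preprocess

GRADE_LABELS = ("1", "2", "3", "4", "5", "6")
IOL_LABEL = "IOL"
ALL_LABELS = GRADE_LABELS + (IOL_LABEL,)

# peak color of a fully opacified (brunescent) nucleus, 8-bit RGB
_NUCLEUS_COLOR = np.array([225.0, 180.0, 60.0])
_PUPIL_BASE = np.array([36.0, 29.0, 25.0])
_IOL_PUPIL = np.array([14.0, 15.0, 20.0])
_IRIS_BASE = np.array([105.0, 82.0, 60.0])


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one rendered phantom."""

    label: str
    size: int = 224
    pupil_radius_frac: float = 0.8
    noise_sd: float = 8.0
    overexposed: bool = False
    seed: int = 0
    opacity_strength: float | None = None  # derived from grade when None

    def __post_init__(self):
        if self.label not in ALL_LABELS:
            raise ValueError(
                f"invalid label {self.label!r}; expected one of {ALL_LABELS}")
        if not 0 < self.pupil_radius_frac <= 1:
            raise ValueError("pupil_radius_frac must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def grade(self) -> int | None:
        return int(self.label) if self.label in GRADE_LABELS else None

    def strength(self) -> float:
        if self.opacity_strength is not None:
            return float(self.opacity_strength)
        if self.grade is None:
            return 0.0
        return (self.grade - 0.5) / 6.0


@dataclass(frozen=True)
class LabeledImage:
    """A 224x224x3 uint8 image with its NC grade (or IOL) label."""

    image: np.ndarray = field(repr=False)
    label: str
    source_id: str = ""

    def __post_init__(self):
        if self.label not in ALL_LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        if self.image.shape != (224, 224, 3):
            raise ValueError(f"expected 224x224x3 image, got {self.image.shape}")


def _disc(size: int, cy: float, cx: float, radius: float,
          soft: float = 1.5) -> np.ndarray:
    """Anti-aliased disc membership in [0,1] with a ``soft``-pixel edge."""
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    d = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2)
    return np.clip((radius - d) / soft + 0.5, 0.0, 1.0)


def generate_eye_phantom(spec: PhantomSpec) -> LabeledImage:
    """Render one phantom. Deterministic given (spec, spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    half = size / 2.0
    cy = half + rng.uniform(-0.03, 0.03) * size
    cx = half + rng.uniform(-0.03, 0.03) * size
    pupil_r = spec.pupil_radius_frac * half * rng.uniform(0.92, 1.0)

    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    theta = np.arctan2(rows - cy, cols - cx)
    radial = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2) / half

    # iris background: brownish base with radial fiber texture
    fibers = 0.5 + 0.5 * np.sin(theta * rng.integers(24, 40)
                                + rng.uniform(0, 2 * np.pi))
    iris = (_IRIS_BASE[None, None, :]
            * (0.75 + 0.3 * fibers[:, :, None])
            * (1.0 - 0.25 * np.clip(radial - 1.0, 0, 1))[:, :, None])
    img = iris.copy()

    pupil_mask = _disc(size, cy, cx, pupil_r)
    if spec.label == IOL_LABEL:
        pupil = np.ones((size, size, 3)) * _IOL_PUPIL[None, None, :]
        # faint bluish rim reflex of the implanted lens optic
        rim = _disc(size, cy, cx, pupil_r * 0.85) - _disc(size, cy, cx, pupil_r * 0.70)
        pupil += rim[:, :, None] * np.array([10.0, 12.0, 22.0])[None, None, :]
    else:
        s = spec.strength()
        pupil = np.ones((size, size, 3)) * _PUPIL_BASE[None, None, :]
        # nuclear opacity: bright yellow-brown core fading toward the pupil edge
        core = _disc(size, cy, cx, pupil_r * 0.78, soft=pupil_r * 0.45)
        pupil += s * core[:, :, None] * _NUCLEUS_COLOR[None, None, :]
    img = img * (1 - pupil_mask[:, :, None]) + pupil * pupil_mask[:, :, None]

    if spec.label == IOL_LABEL:
        # 1-3 small specular glints off the intraocular lens
        for _ in range(int(rng.integers(1, 4))):
            gr = rng.uniform(0.02, 0.05) * size
            gy = cy + rng.uniform(-0.45, 0.45) * pupil_r
            gx = cx + rng.uniform(-0.45, 0.45) * pupil_r
            glint = _disc(size, gy, gx, gr, soft=1.0)
            img = img * (1 - glint[:, :, None]) + glint[:, :, None] * 250.0

    if spec.overexposed:
        oy = cy + rng.uniform(-0.3, 0.3) * pupil_r
        ox = cx + rng.uniform(-0.3, 0.3) * pupil_r
        a, b = rng.uniform(0.25, 0.5, size=2) * pupil_r
        ell = np.clip(1.0 - ((rows - oy) / a) ** 2 - ((cols - ox) / b) ** 2, 0, 1)
        patch = (ell > 0).astype(float)
        img = img * (1 - patch[:, :, None]) + patch[:, :, None] * 255.0

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return LabeledImage(image=out, label=spec.label,
                        source_id=f"phantom-{spec.label}-{spec.seed}")


def derive_seed(master_seed: int, label: str, index: int) -> int:
    """Stable per-image seed from (master seed, label, index)."""
    label_code = 0 if label == IOL_LABEL else int(label)
    ss = np.random.SeedSequence([int(master_seed), label_code, int(index) + 1])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(n_per_class: int, labels=ALL_LABELS, seed: int = 0,
                     **spec_kwargs) -> list[LabeledImage]:
    """``n_per_class`` phantoms per label, deterministically seeded and shuffled."""
    labels = tuple(labels)
    if not labels:
        raise ValueError("label set must not be empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images: list[LabeledImage] = []
    for label in labels:
        for i in range(n_per_class):
            s = derive_seed(seed, label, i)
            spec = PhantomSpec(label=str(label), seed=s, **spec_kwargs)
            img = generate_eye_phantom(spec)
            images.append(replace(img, source_id=f"phantom-{label}-{i:04d}"))
    order = np.random.default_rng(derive_seed(seed, IOL_LABEL, -1)).permutation(
        len(images))
    return [images[i] for i in order]


def pupil_mask(size: int = 224, radius_frac: float = 0.8) -> np.ndarray:
    """Boolean central-pupil mask used by chroma/brightness statistics."""
    half = size / 2.0
    return _disc(size, half, half, radius_frac * half * 0.7) > 0.5


def mean_pupil_chroma(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Yellow-brown chroma statistic (R+G)/2 - B averaged over the pupil."""
    if mask is None:
        mask = pupil_mask(image.shape[0])
    px = image[mask].astype(np.float64)
    return float(((px[:, 0] + px[:, 1]) / 2.0 - px[:, 2]).mean())


def mean_pupil_brightness(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    if mask is None:
        mask = pupil_mask(image.shape[0])
    return float(image[mask].astype(np.float64).mean())


# ---------------------------------------------------------------------------
# dataset I/O (same manifest dialect as the optional real-data loader)
# ---------------------------------------------------------------------------

def save_dataset(images: list[LabeledImage], out_dir) -> Path:
    """Write PNGs plus a ``manifest.csv`` with columns ``path,label``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(images):
        name = f"{i:05d}_{item.label}.png"
        Image.fromarray(item.image, "RGB").save(out / name)
        rows.append((name, item.label))
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(rows)
    return manifest


def load_manifest(csv_path, image_root=None) -> list[LabeledImage]:
    """Load a ``path,label`` manifest; RGBA sources are routed through ROI
    extraction, RGB sources are resized if needed. Errors name the bad row."""
    csv_path = Path(csv_path)
    root = Path(image_root) if image_root is not None else csv_path.parent
    if not csv_path.exists():
        raise FileNotFoundError(f"manifest not found: {csv_path}")
    items: list[LabeledImage] = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise ValueError("manifest must have columns 'path' and 'label'")
        for lineno, row in enumerate(reader, start=2):
            label = row["label"].strip()
            if label not in ALL_LABELS:
                raise ValueError(
                    f"row {lineno}: unknown label {label!r} (path {row['path']!r})")
            path = root / row["path"]
            if not path.exists():
                raise FileNotFoundError(f"row {lineno}: missing image file {path}")
            with Image.open(path) as pil:
                if pil.mode == "RGBA":
                    rgb = preprocess.extract_visible_roi(np.asarray(pil))
                else:
                    rgb = np.asarray(pil.convert("RGB"))
                    if rgb.shape[:2] != (224, 224):
                        rgb = np.asarray(Image.fromarray(rgb).resize(
                            (224, 224), Image.BOX))
            items.append(LabeledImage(image=rgb, label=label,
                                      source_id=str(row["path"])))
    return items
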