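"""Stage 1: one-class cataract gate via convolutional-autoencoder reconstruction.

No public slit-lamp dataset of healthy eyes exists, so the binary
cataract / non-cataract decision is posed as reversed one-class anomaly
detection: a convolutional autoencoder (CAE) is trained *only on cataract
images*, which play the role of the "normal" class. At inference the mean
squared reconstruction error (MSE) of an image under the trained CAE is
compared against a percentile threshold calibrated on the training-error
distribution; images the CAE reconstructs well (error <= tau) are labeled
CATARACT, poorly reconstructed ones NON-CATARACT.

The CAE mirrors the two-stage app's first model: an encoder of four strided
3x3 convolutions, each followed by ReLU, and a decoder of four transposed
convolutions, each followed by ReLU, reconstructing the 224x224x3 input.
Errors are computed on the [0,1] intensity representation (not the
ImageNet-normalized tensors) so the MSE scale is stable across images.

The percentile and the decision direction are explicit model fields. With the
shipped direction ``low_error_is_cataract`` the threshold defaults to the 99th
percentile of training errors, so ~99% of cataract-class training images fall
inside the accepted region; a 1st-percentile threshold is available for the
strictest gate, which accepts only the most accurately reconstructed images.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import tensor_to_intensity

CATARACT = "CATARACT"
NON_CATARACT = "NON-CATARACT"

DIRECTIONS = ("low_error_is_cataract", "high_error_is_anomaly")


@dataclass(frozen=True)
class CaeConfig:
    """CAE architecture and training hyperparameters (4 conv + 4 deconv layers)."""

    channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    input_size: int = 224
    epochs: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != 4:
            raise ValueError("encoder must have exactly 4 convolutional layers")
        if self.epochs < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid training hyperparameters")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def build_cae(config: CaeConfig) -> nn.Sequential:
    """Encoder: 4x (conv3x3 stride2 + ReLU); decoder: 4x (deconv4x4 stride2 + ReLU)."""
    rng = np.random.default_rng(config.seed)
    c = config.channels
    layers: list[nn.Module] = []
    widths = (3,) + c
    for i in range(4):
        layers += [nn.Conv2d(f"enc{i}", widths[i], widths[i + 1], k=3, stride=2,
                             pad=1, rng=rng), nn.ReLU()]
    rev = (c[3], c[2], c[1], c[0], 3)
    for i in range(4):
        layers += [nn.ConvTranspose2d(f"dec{i}", rev[i], rev[i + 1], k=4,
                                      stride=2, pad=1, rng=rng), nn.ReLU()]
    return nn.Sequential(*layers)


def _to_intensity_batch(images) -> np.ndarray:
    """Stack ModelInput tensors and map them back to the [0,1] intensity scale."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    if arr.ndim != 4 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3, H, W) model inputs, got {arr.shape}")
    return np.stack([tensor_to_intensity(t) for t in arr])


def train_cae(images, config: CaeConfig = CaeConfig()):
    """Train the CAE on cataract-class images; returns (net, per-image errors,
    per-epoch mean loss history). Deterministic given ``config.seed``."""
    if len(images) == 0:
        raise ValueError("cannot train on an empty image list")
    x = _to_intensity_batch(images)
    if x.shape[2] != config.input_size or x.shape[3] != config.input_size:
        raise ValueError(
            f"images must be {config.input_size}x{config.input_size}, got {x.shape}")
    net = build_cae(config)
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history: list[float] = []
    for _ in range(config.epochs):
        losses = []
        for idx in nn.iterate_minibatches(len(x), config.batch_size, rng):
            xb = x[idx]
            opt.zero_grad()
            recon = net.forward(xb, train=True)
            loss, grad = nn.mse_loss(recon, xb)
            net.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    errors = reconstruction_errors(net, images)
    return net, errors, history


def reconstruction_errors(net: nn.Sequential, images, batch_size: int = 32) -> np.ndarray:
    """Per-image MSE between [0,1] intensity input and its CAE reconstruction."""
    x = _to_intensity_batch(images)
    out = np.empty(len(x), dtype=np.float64)
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        recon = net.forward(xb, train=False)
        diff = recon.astype(np.float64) - xb.astype(np.float64)
        out[start:start + len(xb)] = (diff * diff).mean(axis=(1, 2, 3))
    return out


def reconstruction_error(net: nn.Sequential, image) -> float:
    return float(reconstruction_errors(net, [image])[0])


def calibrate_threshold(errors, percentile: float) -> float:
    """P-th percentile of the error distribution, linear interpolation between
    order statistics (tau for the gate)."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        raise ValueError("cannot calibrate a threshold from an empty error list")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(errors, percentile))


@dataclass
class GateModel:
    """Trained CAE plus calibrated threshold, percentile and decision direction."""

    net: nn.Sequential
    config: CaeConfig
    threshold: float
    percentile: float
    direction: str = "low_error_is_cataract"
    train_error_summary: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not np.isfinite(self.threshold) or self.threshold < 0:
            raise ValueError("threshold must be finite and >= 0")


@dataclass(frozen=True)
class GateDecision:
    label: str
    error: float

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("reconstruction error must be >= 0")


def calibrate_gate(net: nn.Sequential, config: CaeConfig, train_errors,
                   percentile: float = 99.0,
                   direction: str = "low_error_is_cataract") -> GateModel:
    """Build a calibrated GateModel from training-set reconstruction errors."""
    errors = np.asarray(train_errors, dtype=np.float64)
    tau = calibrate_threshold(errors, percentile)
    summary = {"n": int(errors.size), "mean": float(errors.mean()),
               "min": float(errors.min()), "max": float(errors.max()),
               "median": float(np.median(errors))}
    return GateModel(net=net, config=config, threshold=tau,
                     percentile=float(percentile), direction=direction,
                     train_error_summary=summary)


def train_gate(images, config: CaeConfig = CaeConfig(),
               percentile: float = 99.0,
               direction: str = "low_error_is_cataract") -> GateModel:
    """Convenience: train the CAE and calibrate the threshold in one call."""
    net, errors, _ = train_cae(images, config)
    return calibrate_gate(net, config, errors, percentile, direction)


def classify_binary(model: GateModel, image) -> GateDecision:
    """CATARACT iff reconstruction error <= tau (ties -> CATARACT)."""
    if model.net is None:
        raise ValueError("gate model is not calibrated")
    err = reconstruction_error(model.net, image)
    label = CATARACT if err <= model.threshold else NON_CATARACT
    return GateDecision(label=label, error=err)


def classify_binary_batch(model: GateModel, images) -> list[GateDecision]:
    errs = reconstruction_errors(model.net, images)
    return [GateDecision(label=CATARACT if e <= model.threshold else NON_CATARACT,
                         error=float(e)) for e in errs]


@dataclass
class BinaryReport:
    """Binary gate metrics; confusion rows = true (CATARACT, NON-CATARACT)."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: list  # 2x2, rows true, cols predicted
    n: int
    warning: str | None = None


def binary_report_from_confusion(confusion: np.ndarray,
                                 warning: str | None = None) -> BinaryReport:
    cm = np.asarray(confusion, dtype=np.int64)
    n = int(cm.sum())
    tp, fn = int(cm[0, 0]), int(cm[0, 1])
    fp, tn = int(cm[1, 0]), int(cm[1, 1])
    acc = (tp + tn) / n if n else 0.0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return BinaryReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        confusion=cm.tolist(), n=n, warning=warning)


def evaluate_gate(model: GateModel, images, labels) -> BinaryReport:
    """Evaluate on a labeled CATARACT / NON-CATARACT set."""
    labels = list(labels)
    if len(labels) != len(images) or not labels:
        raise ValueError("need one label per image and at least one item")
    decisions = classify_binary_batch(model, images)
    cm = np.zeros((2, 2), dtype=np.int64)
    classes = (CATARACT, NON_CATARACT)
    for truth, dec in zip(labels, decisions):
        if truth not in classes:
            raise ValueError(f"unknown binary label {truth!r}")
        cm[classes.index(truth), classes.index(dec.label)] += 1
    warning = None
    present = {lbl for lbl in labels}
    if len(present) < 2:
        warning = f"only one true class present: {present.pop()}"
    return binary_report_from_confusion(cm, warning=warning)


# ---------------------------------------------------------------------------
# persistence: weights file + JSON sidecar
# ---------------------------------------------------------------------------

def save_gate(model: GateModel, stem) -> tuple[Path, Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    weights_path = stem.with_suffix(".npz")
    sidecar_path = stem.with_suffix(".json")
    np.savez(weights_path, **nn.state_dict(model.net))
    sidecar = {"threshold": model.threshold, "percentile": model.percentile,
               "direction": model.direction, "config": asdict(model.config),
               "config_hash": model.config.digest(),
               "train_error_summary": model.train_error_summary}
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return weights_path, sidecar_path


def load_gate(stem) -> GateModel:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["channels"] = tuple(cfg_dict["channels"])
    config = CaeConfig(**cfg_dict)
    net = build_cae(config)
    with np.load(stem.with_suffix(".npz")) as data:
        nn.load_state_dict(net, dict(data))
    return GateModel(net=net, config=config, threshold=sidecar["threshold"],
                     percentile=sidecar["percentile"],
                     direction=sidecar["direction"],
                     train_error_summary=sidecar.get("train_error_summary", {}))
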