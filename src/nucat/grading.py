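"""Stage 2: six-grade LOCS III nuclear-cataract classification.

Covers the full supervised leg of the pipeline: stratified dataset splitting,
offline augmentation, a zoo of six convolutional classifier families, the
training recipe (cross-entropy, Adam, ReduceLROnPlateau with patience 2,
best-validation-accuracy checkpointing), macro-averaged evaluation metrics,
and a stratified k-fold cross-validation overfit check.

The zoo exposes the six family ids ``vgg11``, ``vgg16``, ``resnet18``,
``resnet50``, ``mobilenet_v3`` and ``efficientnet_b0``. Each is a compact,
family-faithful variant built from this package's CNN toolkit: the VGG
variants are plain 3x3-conv/maxpool ladders with a fully connected head, the
ResNet variants use basic respectively bottleneck residual blocks, and the
mobile variants use inverted residual blocks with depthwise separable
convolutions (MobileNet) and expansion-6 MBConv-style blocks (EfficientNet).
Channel widths are scaled down (~0.1-0.5M parameters) so the networks are
trainable from scratch on a single CPU; there is no bundled ImageNet weight
zoo, hence ``pretrained_init`` must remain False.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from . import nn
from .phantoms import LabeledImage, GRADE_LABELS
from .preprocess import IMAGENET_MEAN, IMAGENET_STD, AugmentationSpec, augment

ARCHITECTURES = ("vgg11", "vgg16", "resnet18", "resnet50",
                 "mobilenet_v3", "efficientnet_b0")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Classifier training recipe: cross-entropy + Adam + reduce-on-plateau."""

    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 32
    scheduler_patience: int = 2
    scheduler_factor: float = 0.1
    pretrained_init: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def largest_remainder(total: int, fractions) -> list[int]:
    """Integer allocation of ``total`` by the largest-remainder rule.

    Floors the exact quotas, then hands leftover units to the largest
    fractional remainders; ties break toward the earlier subset, so a
    singleton class lands in the first (training) subset under 0.8/0.1/0.1.
    """
    quotas = [total * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = total - sum(counts)
    remainders = [(-(q - c), i) for i, (q, c) in enumerate(zip(quotas, counts))]
    for _, i in sorted(remainders)[:leftover]:
        counts[i] += 1
    return counts


def stratified_split(data: list[LabeledImage], spec: SplitSpec = SplitSpec()):
    """Deterministic (train, val, test) split preserving class proportions."""
    data = list(data)
    rng = np.random.default_rng(spec.seed)
    subsets: tuple[list, list, list] = ([], [], [])
    if spec.stratified:
        by_class: dict[str, list[int]] = {}
        for i, item in enumerate(data):
            by_class.setdefault(item.label, []).append(i)
        for label in sorted(by_class):
            idx = np.array(by_class[label])
            idx = idx[rng.permutation(len(idx))]
            counts = largest_remainder(len(idx), spec.fractions)
            start = 0
            for subset, cnt in zip(subsets, counts):
                subset.extend(int(j) for j in idx[start:start + cnt])
                start += cnt
    else:
        idx = rng.permutation(len(data))
        counts = largest_remainder(len(data), spec.fractions)
        start = 0
        for subset, cnt in zip(subsets, counts):
            subset.extend(int(j) for j in idx[start:start + cnt])
            start += cnt
    return tuple([data[j] for j in sorted(s)] for s in subsets)


def expand_with_augmentation(train: list[LabeledImage], spec: AugmentationSpec,
                             multiplier: int) -> list[LabeledImage]:
    """Offline dataset expansion: originals plus multiplier-1 augmented copies."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    out = list(train)
    for copy in range(1, multiplier):
        for i, item in enumerate(train):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, copy, i]))
            aug = augment(item.image, spec, rng)
            out.append(LabeledImage(image=aug, label=item.label,
                                    source_id=f"{item.source_id}#aug{copy}"))
    return out


# ---------------------------------------------------------------------------
# architecture zoo
# ---------------------------------------------------------------------------

def _conv_bn_relu(name, c_in, c_out, k, s, p, rng):
    return [nn.Conv2d(name, c_in, c_out, k=k, stride=s, pad=p, rng=rng,
                      bias=False),
            nn.BatchNorm2d(f"{name}.bn", c_out), nn.ReLU()]


def _vgg(rng, n_classes, convs_per_stage):
    layers: list[nn.Module] = []
    widths = [16, 32, 64, 128]
    c_in = 3
    for stage, c_out in enumerate(widths):
        for j in range(convs_per_stage):
            stride = 2 if stage == 0 and j == 0 else 1
            layers += _conv_bn_relu(f"s{stage}c{j}", c_in, c_out, 3, stride, 1, rng)
            c_in = c_out
        layers.append(nn.MaxPool2d())
    # 224 -> 112 (strided conv) -> 56 -> 28 -> 14 -> 7
    layers += [nn.Flatten(), nn.Linear("fc1", 128 * 7 * 7, 128, rng), nn.ReLU(),
               nn.Linear("fc2", 128, n_classes, rng)]
    return nn.Sequential(*layers)


def _basic_block(name, c_in, c_out, stride, rng):
    main = nn.Sequential(
        *_conv_bn_relu(f"{name}.a", c_in, c_out, 3, stride, 1, rng),
        nn.Conv2d(f"{name}.b", c_out, c_out, 3, 1, 1, rng, bias=False),
        nn.BatchNorm2d(f"{name}.b.bn", c_out))
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential(
            nn.Conv2d(f"{name}.sc", c_in, c_out, 1, stride, 0, rng, bias=False),
            nn.BatchNorm2d(f"{name}.sc.bn", c_out))
    return nn.Residual(main, shortcut, post_relu=True)


def _bottleneck_block(name, c_in, mid, c_out, stride, rng):
    main = nn.Sequential(
        *_conv_bn_relu(f"{name}.a", c_in, mid, 1, 1, 0, rng),
        *_conv_bn_relu(f"{name}.b", mid, mid, 3, stride, 1, rng),
        nn.Conv2d(f"{name}.c", mid, c_out, 1, 1, 0, rng, bias=False),
        nn.BatchNorm2d(f"{name}.c.bn", c_out))
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential(
            nn.Conv2d(f"{name}.sc", c_in, c_out, 1, stride, 0, rng, bias=False),
            nn.BatchNorm2d(f"{name}.sc.bn", c_out))
    return nn.Residual(main, shortcut, post_relu=True)


def _resnet(rng, n_classes, bottleneck):
    layers: list[nn.Module] = [
        *_conv_bn_relu("stem", 3, 16, 3, 2, 1, rng), nn.MaxPool2d()]  # -> 56
    if bottleneck:
        specs = [("b1", 16, 8, 32, 1), ("b2", 32, 16, 64, 2),
                 ("b3", 64, 32, 128, 2), ("b4", 128, 64, 256, 2)]
        for name, c_in, mid, c_out, s in specs:
            layers.append(_bottleneck_block(name, c_in, mid, c_out, s, rng))
        feat = 256
    else:
        specs = [("b1", 16, 16, 1), ("b2", 16, 32, 2),
                 ("b3", 32, 64, 2), ("b4", 64, 128, 2)]
        for name, c_in, c_out, s in specs:
            layers.append(_basic_block(name, c_in, c_out, s, rng))
        feat = 128
    layers += [nn.GlobalAvgPool(), nn.Linear("fc", feat, n_classes, rng)]
    return nn.Sequential(*layers)


def _inverted_residual(name, c_in, c_exp, c_out, stride, rng):
    """1x1 expand -> depthwise 3x3 -> 1x1 linear project, skip when shape-preserving."""
    main = nn.Sequential(
        *_conv_bn_relu(f"{name}.exp", c_in, c_exp, 1, 1, 0, rng),
        nn.DepthwiseConv2d(f"{name}.dw", c_exp, 3, stride, 1, rng),
        nn.BatchNorm2d(f"{name}.dw.bn", c_exp), nn.ReLU(),
        nn.Conv2d(f"{name}.proj", c_exp, c_out, 1, 1, 0, rng, bias=False),
        nn.BatchNorm2d(f"{name}.proj.bn", c_out))
    if stride == 1 and c_in == c_out:
        return nn.Residual(main, None, post_relu=False)
    return main


def _mobilenet_v3(rng, n_classes):
    layers: list[nn.Module] = [*_conv_bn_relu("stem", 3, 16, 3, 2, 1, rng)]  # 112
    specs = [("ir1", 16, 48, 24, 2), ("ir2", 24, 72, 32, 2),
             ("ir3", 32, 96, 64, 2), ("ir4", 64, 192, 64, 1),
             ("ir5", 64, 256, 96, 2)]  # -> 7
    for name, c_in, c_exp, c_out, s in specs:
        layers.append(_inverted_residual(name, c_in, c_exp, c_out, s, rng))
    layers += [*_conv_bn_relu("head", 96, 192, 1, 1, 0, rng),
               nn.GlobalAvgPool(), nn.Linear("fc", 192, n_classes, rng)]
    return nn.Sequential(*layers)


def _efficientnet_b0(rng, n_classes):
    layers: list[nn.Module] = [*_conv_bn_relu("stem", 3, 16, 3, 2, 1, rng)]  # 112
    specs = [("mb1", 16, 96, 24, 2), ("mb2", 24, 144, 40, 2),
             ("mb3", 40, 240, 80, 2), ("mb4", 80, 480, 80, 1),
             ("mb5", 80, 480, 112, 2)]  # -> 7
    for name, c_in, c_exp, c_out, s in specs:
        layers.append(_inverted_residual(name, c_in, c_exp, c_out, s, rng))
    layers += [*_conv_bn_relu("head", 112, 224, 1, 1, 0, rng),
               nn.GlobalAvgPool(), nn.Linear("fc", 224, n_classes, rng)]
    return nn.Sequential(*layers)


_BUILDERS = {
    "vgg11": lambda rng, n: _vgg(rng, n, convs_per_stage=1),
    "vgg16": lambda rng, n: _vgg(rng, n, convs_per_stage=2),
    "resnet18": lambda rng, n: _resnet(rng, n, bottleneck=False),
    "resnet50": lambda rng, n: _resnet(rng, n, bottleneck=True),
    "mobilenet_v3": _mobilenet_v3,
    "efficientnet_b0": _efficientnet_b0,
}


@dataclass
class GradeModel:
    """A six-class grader: network, architecture id, class order, history."""

    net: nn.Sequential
    arch: str
    n_classes: int = 6
    classes: tuple[str, ...] = GRADE_LABELS
    history: list = field(default_factory=list)


def build_classifier(arch: str, n_classes: int = 6,
                     pretrained_init: bool = False, seed: int = 0) -> GradeModel:
    """Instantiate one of the six architecture families with an n-way head."""
    if arch not in _BUILDERS:
        raise ValueError(f"unknown architecture {arch!r}; "
                         f"choose from {ARCHITECTURES}")
    if pretrained_init:
        raise ValueError(
            "pretrained_init is not supported: this package ships compact "
            "from-scratch architectures and no ImageNet weight zoo")
    rng = np.random.default_rng(seed)
    net = _BUILDERS[arch](rng, n_classes)
    classes = GRADE_LABELS[:n_classes] if n_classes <= 6 else tuple(
        str(i + 1) for i in range(n_classes))
    return GradeModel(net=net, arch=arch, n_classes=n_classes, classes=classes)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _normalize_batch(images_u8: np.ndarray) -> np.ndarray:
    """(n, 224, 224, 3) uint8 -> ImageNet-normalized (n, 3, 224, 224) float32."""
    x = images_u8.astype(np.float32) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _stack(data: list[LabeledImage], classes) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([item.image for item in data])
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        y = np.array([lookup[item.label] for item in data], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc} not among model classes {classes}") from exc
    return images, y


def _forward_eval(net: nn.Sequential, images_u8: np.ndarray,
                  batch_size: int = 32) -> np.ndarray:
    logits = []
    for start in range(0, len(images_u8), batch_size):
        xb = _normalize_batch(images_u8[start:start + batch_size])
        logits.append(net.forward(xb, train=False))
    return np.concatenate(logits, axis=0)


def train_classifier(model: GradeModel, train: list[LabeledImage],
                     val: list[LabeledImage],
                     config: TrainConfig = TrainConfig()) -> GradeModel:
    """Train with cross-entropy/Adam; keep the best-validation-accuracy weights.

    Appends one history record per epoch (train/val loss and accuracy, lr).
    Deterministic given ``config.seed``.
    """
    if not train:
        raise ValueError("training set must not be empty")
    if not val:
        raise ValueError("validation set must not be empty")
    xtr, ytr = _stack(train, model.classes)
    xva, yva = _stack(val, model.classes)
    opt = nn.Adam(model.net.params(), lr=config.learning_rate)
    sched = nn.ReduceLROnPlateau(opt, patience=config.scheduler_patience,
                                 factor=config.scheduler_factor)
    rng = np.random.default_rng(config.seed)
    best_acc, best_state = -1.0, None
    history = []
    for epoch in range(config.epochs):
        losses, hits, seen = [], 0, 0
        for idx in nn.iterate_minibatches(len(xtr), config.batch_size, rng):
            xb = _normalize_batch(xtr[idx])
            yb = ytr[idx]
            opt.zero_grad()
            logits = model.net.forward(xb, train=True)
            loss, grad = nn.cross_entropy_loss(logits, yb)
            model.net.backward(grad)
            opt.step()
            losses.append(loss * len(yb))
            hits += int((logits.argmax(axis=1) == yb).sum())
            seen += len(yb)
        val_logits = _forward_eval(model.net, xva)
        val_loss, _ = nn.cross_entropy_loss(val_logits, yva)
        val_acc = float((val_logits.argmax(axis=1) == yva).mean())
        sched.step(val_loss)
        history.append({"epoch": epoch, "train_loss": float(np.sum(losses) / seen),
                        "train_acc": hits / seen, "val_loss": float(val_loss),
                        "val_acc": val_acc, "lr": opt.lr})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = {k: v.copy() for k, v in nn.state_dict(model.net).items()}
    if best_state is not None:
        nn.load_state_dict(model.net, best_state)
    model.history = model.history + history
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Accuracy plus macro-averaged precision/recall/F1 and the confusion matrix
    (rows = true labels, cols = predicted, in ``classes`` order)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict
    confusion: list
    n: int
    classes: tuple[str, ...]
    warning: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def metrics_from_confusion(cm: np.ndarray, classes) -> MetricsReport:
    """Macro metrics computed from a confusion matrix (rows true, cols pred)."""
    cm = np.asarray(cm, dtype=np.int64)
    classes = tuple(classes)
    n = int(cm.sum())
    if n == 0:
        raise ValueError("empty confusion matrix")
    # expand counts back into label vectors so the arithmetic matches the
    # canonical scikit-learn definitions exactly
    true_idx, pred_idx = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            true_idx.extend([i] * cm[i, j])
            pred_idx.extend([j] * cm[i, j])
    labels = list(range(len(classes)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            true_idx, pred_idx, labels=labels, average=None, zero_division=0)
    accuracy = float(np.trace(cm) / n)
    absent = [classes[i] for i in labels
              if cm[i, :].sum() == 0 and cm[:, i].sum() == 0]
    warning = None
    if absent:
        warning = (f"classes absent from truth and predictions contribute 0 "
                   f"to macro averages: {absent}")
        warnings.warn(warning, UserWarning, stacklevel=2)
    per_class = {c: {"precision": float(prec[i]), "recall": float(rec[i]),
                     "f1": float(f1[i])} for i, c in enumerate(classes)}
    return MetricsReport(accuracy=accuracy, precision=float(prec.mean()),
                         recall=float(rec.mean()), f1=float(f1.mean()),
                         per_class=per_class, confusion=cm.tolist(), n=n,
                         classes=classes, warning=warning)


def evaluate(model: GradeModel, test: list[LabeledImage]) -> MetricsReport:
    """Macro-averaged metrics of the grader on a labeled test set."""
    if not test:
        raise ValueError("test set must not be empty")
    x, y = _stack(test, model.classes)
    logits = _forward_eval(model.net, x)
    preds = logits.argmax(axis=1)
    cm = _sk_confusion(y, preds, labels=list(range(len(model.classes))))
    return metrics_from_confusion(cm, model.classes)


def predict_grade(model: GradeModel, tensor: np.ndarray) -> tuple[int, np.ndarray]:
    """Predict an NC grade for one normalized input tensor.

    Returns (grade as int 1..6, softmax probability vector); ties in the
    argmax break toward the lowest grade.
    """
    logits = model.net.forward(np.asarray(tensor, dtype=np.float32)[None], train=False)[0]
    probs = nn.softmax(logits[None])[0]
    idx = int(np.argmax(probs))  # first maximum -> lowest grade on ties
    return int(model.classes[idx]), probs


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    k: int
    train_accuracies: list
    val_accuracies: list
    mean_train_accuracy: float
    mean_val_accuracy: float
    gap: float
    gap_sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def stratified_fold_indices(labels: list[str], k: int, seed: int = 0) -> list[np.ndarray]:
    """Disjoint covering folds; per-class sizes by the largest-remainder rule."""
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    by_class: dict[str, list[int]] = {}
    for i, lbl in enumerate(labels):
        by_class.setdefault(lbl, []).append(i)
    for lbl in sorted(by_class):
        idx = np.array(by_class[lbl])
        idx = idx[rng.permutation(len(idx))]
        counts = largest_remainder(len(idx), [1.0 / k] * k)
        start = 0
        for f, cnt in zip(folds, counts):
            f.extend(int(j) for j in idx[start:start + cnt])
            start += cnt
    return [np.array(sorted(f)) for f in folds]


def gap_statistics(train_accs, val_accs) -> tuple[float, float, float, float]:
    """(mean train, mean val, gap, sd of per-fold train-val differences)."""
    tr = np.asarray(train_accs, dtype=np.float64)
    va = np.asarray(val_accs, dtype=np.float64)
    diffs = tr - va
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return float(tr.mean()), float(va.mean()), float(tr.mean() - va.mean()), sd


def cross_validate(data: list[LabeledImage], arch: str,
                   config: TrainConfig = TrainConfig(), k: int = 10) -> CvReport:
    """Stratified k-fold CV; the train-vs-validation accuracy gap flags overfit."""
    labels = [item.label for item in data]
    folds = stratified_fold_indices(labels, k, seed=config.seed)
    train_accs, val_accs = [], []
    for fold_no, fold in enumerate(folds):
        val_items = [data[i] for i in fold]
        mask = np.ones(len(data), dtype=bool)
        mask[fold] = False
        train_items = [item for item, keep in zip(data, mask) if keep]
        model = build_classifier(arch, seed=config.seed + fold_no)
        train_classifier(model, train_items, val_items, config)
        train_accs.append(evaluate(model, train_items).accuracy)
        val_accs.append(evaluate(model, val_items).accuracy)
    mean_tr, mean_va, gap, sd = gap_statistics(train_accs, val_accs)
    return CvReport(k=k, train_accuracies=train_accs, val_accuracies=val_accs,
                    mean_train_accuracy=mean_tr, mean_val_accuracy=mean_va,
                    gap=gap, gap_sd=sd)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_grader(model: GradeModel, stem) -> tuple[Path, Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez(stem.with_suffix(".npz"), **nn.state_dict(model.net))
    sidecar = {"arch": model.arch, "n_classes": model.n_classes,
               "classes": list(model.classes)}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return stem.with_suffix(".npz"), stem.with_suffix(".json")


def load_grader(stem) -> GradeModel:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    model = build_classifier(sidecar["arch"], n_classes=sidecar["n_classes"])
    model = GradeModel(net=model.net, arch=model.arch,
                       n_classes=model.n_classes,
                       classes=tuple(sidecar["classes"]))
    with np.load(stem.with_suffix(".npz")) as data:
        nn.load_state_dict(model.net, dict(data))
    return model
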