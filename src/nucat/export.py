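"""Model export and conversion-parity analysis.

The deployment story of the two-stage pipeline requires the trained
classifiers to leave their training runtime and be re-executed elsewhere, and
the interesting scientific question is how much the metrics degrade along the
way. This module provides:

* ``export_model`` — serialize a trained network to a portable compute-graph
  format: a JSON manifest listing the ops (conv2d, conv_transpose2d,
  depthwise_conv2d, batchnorm2d, relu, sigmoid, maxpool2, global_avg_pool,
  flatten, linear, residual) plus an NPZ weights file. The optional
  ``precision="float16"`` leg stores weights at half precision, the lossy
  analogue of a mobile-format conversion.
* ``load_exported`` — an *independent* interpreter that re-executes the graph
  with a different numerical route (sliding-window views + einsum in float64,
  transposed convolution as zero-stuffed correlation) from the training
  engine's im2col/matmul float32 path. Agreement between the two is therefore
  a meaningful parity check, not a tautology.
* ``parity_report`` — evaluate the native network and every exported format on
  one identical probe set with identical preprocessing, reporting per-format
  metrics, max-absolute logit deviation from native, and accuracy deltas.

The report can *exhibit* conversion degradation (e.g. under float16 weights);
it does not promise to prevent it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .grading import (GradeModel, MetricsReport, _normalize_batch, _stack,
                      metrics_from_confusion)

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_model(model, stem, precision: str = "float32",
                 meta: dict | None = None) -> Path:
    """Write ``<stem>.graph.json`` + ``<stem>.weights.npz`` for a network.

    ``model`` may be a GradeModel or a bare Sequential. ``precision`` is
    "float32" (faithful) or "float16" (lossy mobile-style leg).
    """
    if precision not in ("float32", "float16"):
        raise ValueError(f"unsupported precision {precision!r}")
    net = model.net if isinstance(model, GradeModel) else model
    ops = net.to_ops()
    weights = nn.state_dict(net)
    if precision == "float16":
        weights = {k: v.astype(np.float16) for k, v in weights.items()}
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": FORMAT_VERSION, "precision": precision,
                "input_shape": [1, 3, 224, 224], "ops": ops,
                "weights_file": stem.name + ".weights.npz",
                "meta": meta or {}}
    if isinstance(model, GradeModel):
        manifest["meta"].setdefault("arch", model.arch)
        manifest["meta"].setdefault("classes", list(model.classes))
        manifest["n_outputs"] = model.n_classes
    graph_path = Path(str(stem) + ".graph.json")
    graph_path.write_text(json.dumps(manifest, indent=2))
    np.savez(Path(str(stem) + ".weights.npz"), **weights)
    return graph_path


def validate_graph(manifest: dict, weights: dict) -> None:
    """Structural validation: known ops only, every referenced weight present."""
    known = {"conv2d", "conv_transpose2d", "depthwise_conv2d", "batchnorm2d",
             "relu", "sigmoid", "maxpool2", "global_avg_pool", "flatten",
             "linear", "residual"}

    def check(ops):
        for op in ops:
            if op["op"] not in known:
                raise ValueError(f"unsupported operator {op['op']!r}")
            for key in ("weight", "bias", "gamma", "beta", "mean", "var"):
                if key in op and op[key] is not None and op[key] not in weights:
                    raise ValueError(f"missing weight array {op[key]!r}")
            if op["op"] == "residual":
                check(op["main"])
                if op["shortcut"]:
                    check(op["shortcut"])

    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError("unknown graph format version")
    check(manifest["ops"])


# ---------------------------------------------------------------------------
# independent interpreter
# ---------------------------------------------------------------------------

def _i_conv2d(x, w, b, k, s, p):
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    y = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
    if b is not None:
        y = y + b[None, :, None, None]
    return y


def _i_conv_transpose2d(x, w, b, k, s, p):
    # zero-stuff the input, then run a stride-1 correlation with the
    # spatially flipped, axis-swapped kernel — the textbook equivalence
    n, c, h, wd = x.shape
    up = np.zeros((n, c, (h - 1) * s + 1, (wd - 1) * s + 1), dtype=x.dtype)
    up[:, :, ::s, ::s] = x
    wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_out, c_in, k, k)
    return _i_conv2d(up, wflip, b, k, 1, k - 1 - p)


def _i_depthwise(x, w, b, k, s, p):
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    y = np.einsum("nchwij,cij->nchw", win, w, optimize=True)
    return y + b[None, :, None, None]


class ExportedModel:
    """Graph interpreter over the portable export format (inference only)."""

    def __init__(self, manifest: dict, weights: dict[str, np.ndarray]):
        validate_graph(manifest, weights)
        self.manifest = manifest
        self.weights = {k: v.astype(np.float64) for k, v in weights.items()}
        self.precision = manifest["precision"]

    def _run_ops(self, ops, x):
        w = self.weights
        for op in ops:
            kind = op["op"]
            if kind == "conv2d":
                weight = w[op["weight"]].reshape(op["c_out"], op["c_in"],
                                                 op["k"], op["k"])
                x = _i_conv2d(x, weight, w.get(op.get("bias")),
                              op["k"], op["stride"], op["pad"])
            elif kind == "conv_transpose2d":
                weight = w[op["weight"]].reshape(op["c_in"], op["c_out"],
                                                 op["k"], op["k"])
                x = _i_conv_transpose2d(x, weight, w[op["bias"]],
                                        op["k"], op["stride"], op["pad"])
            elif kind == "depthwise_conv2d":
                x = _i_depthwise(x, w[op["weight"]], w[op["bias"]],
                                 op["k"], op["stride"], op["pad"])
            elif kind == "batchnorm2d":
                scale = w[op["gamma"]] / np.sqrt(w[op["var"]] + op["eps"])
                shift = w[op["beta"]] - w[op["mean"]] * scale
                x = x * scale[None, :, None, None] + shift[None, :, None, None]
            elif kind == "relu":
                x = np.maximum(x, 0)
            elif kind == "sigmoid":
                x = 1.0 / (1.0 + np.exp(-x))
            elif kind == "maxpool2":
                n, c, h, wd = x.shape
                x = x.reshape(n, c, h // 2, 2, wd // 2, 2).max(axis=(3, 5))
            elif kind == "global_avg_pool":
                x = x.mean(axis=(2, 3))
            elif kind == "flatten":
                x = x.reshape(x.shape[0], -1)
            elif kind == "linear":
                x = x @ w[op["weight"]] + w[op["bias"]]
            elif kind == "residual":
                y = self._run_ops(op["main"], x)
                s = self._run_ops(op["shortcut"], x) if op["shortcut"] else x
                x = y + s
                if op["post_relu"]:
                    x = np.maximum(x, 0)
        return x

    def run(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        expected = tuple(self.manifest["input_shape"][1:])
        if batch.ndim != 4 or batch.shape[1:] != expected:
            raise ValueError(
                f"input signature mismatch: expected (n, {expected[0]}, "
                f"{expected[1]}, {expected[2]}), got {batch.shape}")
        return self._run_ops(self.manifest["ops"], batch)


def load_exported(stem) -> ExportedModel:
    stem = Path(stem)
    graph_path = stem if stem.name.endswith(".graph.json") \
        else Path(str(stem) + ".graph.json")
    manifest = json.loads(graph_path.read_text())
    weights_path = graph_path.parent / manifest["weights_file"]
    with np.load(weights_path) as data:
        weights = dict(data)
    return ExportedModel(manifest, weights)


# ---------------------------------------------------------------------------
# parity analysis
# ---------------------------------------------------------------------------

@dataclass
class ParityReport:
    """Per-format metrics and deviation from the native model on one probe set."""

    reports: dict            # format name -> MetricsReport
    max_abs_logit_dev: dict  # format name -> float (native excluded: 0.0)
    accuracy_delta: dict     # format name -> format accuracy - native accuracy
    n_probes: int

    def to_dict(self) -> dict:
        return {"reports": {k: v.to_dict() for k, v in self.reports.items()},
                "max_abs_logit_dev": self.max_abs_logit_dev,
                "accuracy_delta": self.accuracy_delta,
                "n_probes": self.n_probes}

    def to_csv(self, path) -> Path:
        """Table-shaped CSV: one row per format with the four headline metrics."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["network", "accuracy", "precision", "recall",
                             "f1", "max_abs_logit_dev", "accuracy_delta"])
            for name, rep in self.reports.items():
                writer.writerow([name, f"{rep.accuracy:.4f}",
                                 f"{rep.precision:.4f}", f"{rep.recall:.4f}",
                                 f"{rep.f1:.4f}",
                                 f"{self.max_abs_logit_dev[name]:.3e}",
                                 f"{self.accuracy_delta[name]:+.4f}"])
        return path


def _report_from_logits(logits: np.ndarray, y: np.ndarray,
                        classes) -> MetricsReport:
    preds = logits.argmax(axis=1)
    k = len(classes)
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, preds):
        cm[t, p] += 1
    return metrics_from_confusion(cm, classes)


def parity_report(native: GradeModel, exported: dict, probe_set) -> ParityReport:
    """Evaluate native + every exported format on the identical probe set.

    ``exported`` maps format names to export stems/paths or ExportedModel
    instances. Deltas are format accuracy minus native accuracy.
    """
    if not probe_set:
        raise ValueError("probe set must not be empty")
    images, y = _stack(list(probe_set), native.classes)
    x = _normalize_batch(images)
    native_logits = native.net.forward(x, train=False)
    reports = {"native": _report_from_logits(native_logits, y, native.classes)}
    devs = {"native": 0.0}
    deltas = {"native": 0.0}
    for name, handle in exported.items():
        em = handle if isinstance(handle, ExportedModel) else load_exported(handle)
        logits = em.run(x)
        if logits.shape != native_logits.shape:
            raise ValueError(
                f"{name}: output signature mismatch "
                f"({logits.shape} vs {native_logits.shape})")
        reports[name] = _report_from_logits(logits, y, native.classes)
        devs[name] = float(np.max(np.abs(logits - native_logits)))
        deltas[name] = reports[name].accuracy - reports["native"].accuracy
    return ParityReport(reports=reports, max_abs_logit_dev=devs,
                        accuracy_delta=deltas, n_probes=len(y))


def max_logit_deviation(native: GradeModel, exported: ExportedModel,
                        probe_set) -> float:
    """Max-abs difference between native and exported logits on the probes."""
    images, _ = _stack(list(probe_set), native.classes)
    x = _normalize_batch(images)
    native_logits = native.net.forward(x, train=False)
    return float(np.max(np.abs(exported.run(x) - native_logits)))
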