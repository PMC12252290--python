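# nucat — two-stage nuclear-cataract detection and LOCS III grading

`nucat` is a tested library + CLI for analyzing slit-lamp pupil images for
nuclear cataract (NC). It reproduces, at desk scale, a two-stage mobile
screening pipeline:

1. **One-class gate.** There is no public slit-lamp dataset of healthy
   eyes, so cataract/non-cataract is decided by *reversed* anomaly
   detection: a convolutional autoencoder (CAE; four stride-2 3×3
   convolutions + ReLU, mirrored by four transposed convolutions + ReLU) is
   trained **only on cataract images**, treated as the "normal" class. For
   an input x with reconstruction x̂, the decision statistic is the mean
   squared reconstruction error MSE(x) = mean((x − x̂)²) on the [0,1]
   intensity scale. A threshold τ is calibrated as a percentile of the
   training-error distribution (default: 99th, with the 1st percentile
   available as the strictest gate), and the image is labeled CATARACT iff
   MSE(x) ≤ τ. Pseudophakic (IOL, artificial-lens) eyes serve as the
   non-cataract class at evaluation.
2. **Six-grade classifier.** Gated images receive an NC grade 1–6 on the
   LOCS III scale from one of six compact CNN families (`vgg11`, `vgg16`,
   `resnet18`, `resnet50`, `mobilenet_v3`, `efficientnet_b0`), trained with
   cross-entropy, Adam, and a reduce-on-plateau schedule on stratified
   80/10/10 splits, and reported with accuracy and macro precision/recall/F1.

Because the clinical database cannot be redistributed, the package includes
a deterministic **slit-lamp phantom generator** (grade-dependent yellow-brown
nuclear opacity vs. dark glinting IOL pupils) that makes every stage testable
end to end, and an **export module** that serializes trained models to a
portable compute-graph format, re-executes them with an independent
interpreter, and quantifies conversion parity (including a lossy float16
leg), mirroring the accuracy loss that mobile-format conversion can cause.

An optional loader ingests real data from a `path,label` manifest CSV
(labels `1`–`6` or `IOL`; RGBA images are routed through alpha-mask ROI
extraction automatically).

## Worked example

```sh
# 1. render a phantom dataset: 20 images per grade + 20 IOL
nucat make-phantoms --out ds --n-per-class 20 --labels 1,2,3,4,5,6,IOL --seed 7

# 2. train the one-class gate on the cataract-grade images
nucat train-gate --manifest ds/manifest.csv --out models/gate --epochs 8 --seed 7

# 3. train a six-grade classifier
nucat train-grader --manifest ds/manifest.csv --out models/r18 \
    --arch resnet18 --epochs 10 --seed 7

# 4. two-stage inference on one image
nucat infer ds/00012_6.png --gate-model models/gate --grade-model models/r18
```

Step 2 prints the calibrated threshold:

```json
{"threshold": 0.007255906679588868, "percentile": 99.0, "n_train": 120}
```

meaning 99% of cataract-class training images reconstruct with MSE at or
below 0.00726, which becomes the acceptance region of the gate. Step 3
prints the held-out metrics, here
`{"arch": "resnet18", "test_accuracy": 0.9166666666666666, "test_f1":
0.9111111111111111}` (phantom grades are deliberately learnable; clinical
accuracy would be lower). Step 4 prints the two-stage decision for the
grade-6 phantom:

```json
{
  "stage1": {"label": "CATARACT", "error": 0.007059663941647277},
  "stage2": {"grade": 6, "probabilities": [0.0054, 0.0170, 0.0016, 0.0054,
                                           0.0258, 0.9448]},
  "input_id": "ds/00012_6.png", ...
}
```

The reconstruction error 0.00706 falls below τ, so the image is gated as
CATARACT and graded: the classifier puts 94.5% of the probability mass on
grade 6. Running the same command on `ds/00000_IOL.png` yields stage 1 only
— error 0.0160 > τ, label NON-CATARACT, `"stage2": null` — grading never
runs on non-cataract images.

A full experiment (split manifests, gate + grader training, evaluation
reports, export parity, JSON-lines log) runs from one pinned-seed config:

```sh
nucat run --config experiment.yaml --out-dir run1
```

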