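"""Shared fixtures: small phantom datasets and quickly trained models.

The heavyweight end-to-end models are session-scoped so the pipeline,
export and two-stage contract tests can share one training run.
"""

import numpy as np
import pytest

from nucat import gate, grading, phantoms, preprocess


@pytest.fixture(scope="session")
def grade_phantoms_small():
    """60 grade phantoms (10 per grade) at default generator parameters."""
    return phantoms.generate_dataset(10, labels=phantoms.GRADE_LABELS, seed=42)


@pytest.fixture(scope="session")
def iol_phantoms_small():
    return phantoms.generate_dataset(10, labels=[phantoms.IOL_LABEL], seed=43)


@pytest.fixture(scope="session")
def small_gate_model(grade_phantoms_small):
    """CAE gate trained briefly on the small grade-phantom set (P=99)."""
    tensors = [preprocess.normalize_for_model(d.image)
               for d in grade_phantoms_small]
    cfg = gate.CaeConfig(epochs=12, learning_rate=2e-3, seed=7)
    return gate.train_gate(tensors, cfg, percentile=99.0)


@pytest.fixture(scope="session")
def small_grade_model(grade_phantoms_small):
    """resnet18 grader trained briefly on the small grade-phantom set."""
    train, val, _ = grading.stratified_split(
        grade_phantoms_small, grading.SplitSpec(seed=7))
    model = grading.build_classifier("resnet18", seed=7)
    cfg = grading.TrainConfig(epochs=4, learning_rate=1e-3, batch_size=16, seed=7)
    return grading.train_classifier(model, train, val, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
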