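"""One-class gate: reconstruction error, percentile threshold, binary decisions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucat import gate, phantoms, preprocess
from nucat.gate import (CATARACT, NON_CATARACT, BinaryReport, CaeConfig,
                        GateModel, binary_report_from_confusion,
                        calibrate_gate, calibrate_threshold, classify_binary,
                        evaluate_gate, reconstruction_error, train_cae)


class _OffsetNet:
    """Stand-in reconstruction model: returns input + offset (no learning)."""

    def __init__(self, offset=0.0):
        self.offset = offset

    def forward(self, x, train=False):
        return x + self.offset


def _tensor(seed=0):
    img = phantoms.generate_eye_phantom(
        phantoms.PhantomSpec(label="3", seed=seed)).image
    return preprocess.normalize_for_model(img)


class TestReconstructionError:
    def test_perfect_reconstruction_is_zero(self):
        assert reconstruction_error(_OffsetNet(0.0), _tensor()) == 0.0

    def test_constant_offset_gives_squared_offset(self):
        # reconstruction = input + 0.1 everywhere -> MSE = 0.01
        err = reconstruction_error(_OffsetNet(0.1), _tensor())
        assert err == pytest.approx(0.01, rel=1e-4)

    def test_invariant_to_channel_permutation(self, rng):
        # the mean over channels/pixels ignores channel order when the same
        # permutation is applied to input and reconstruction
        from nucat import nn
        x = rng.random((3, 8, 8)).astype(np.float32)
        recon = rng.random((3, 8, 8)).astype(np.float32)
        perm = [2, 0, 1]
        loss_a, _ = nn.mse_loss(recon, x)
        loss_b, _ = nn.mse_loss(recon[perm], x[perm])
        assert loss_a == pytest.approx(loss_b, rel=1e-12)


class TestCalibrateThreshold:
    def test_boundary_percentiles(self):
        errors = np.arange(1, 101, dtype=float)
        assert calibrate_threshold(errors, 0) == 1.0
        assert calibrate_threshold(errors, 100) == 100.0

    def test_first_percentile_linear_interpolation(self):
        # sorted order statistics 1..100: position 0.99 -> 1 + 0.99*(2-1)
        assert calibrate_threshold(np.arange(1, 101), 1) == pytest.approx(1.99)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([], 50)

    @given(st.lists(st.floats(0, 1e3, allow_nan=False), min_size=1, max_size=50),
           st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_matches_sort_interpolate_oracle_and_monotone(self, errs, p, q):
        """tau equals the hand-rolled sorted linear interpolation and is
        monotone non-decreasing in the percentile."""
        s = np.sort(np.asarray(errs, dtype=float))
        pos = (len(s) - 1) * p / 100.0
        lo = int(np.floor(pos))
        hi = min(lo + 1, len(s) - 1)
        oracle = s[lo] + (pos - lo) * (s[hi] - s[lo])
        tau_p = calibrate_threshold(errs, p)
        assert tau_p == pytest.approx(oracle, abs=1e-9)
        lo_p, hi_p = sorted((p, q))
        assert calibrate_threshold(errs, lo_p) <= calibrate_threshold(errs, hi_p) + 1e-12


class TestTrainCae:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_cae([], CaeConfig(epochs=1))

    def test_loss_decreases_on_repeated_image(self):
        """Overfitting 8 copies of one phantom drives the loss down."""
        t = _tensor(3)
        _, errors, history = train_cae([t] * 8, CaeConfig(epochs=20, seed=1))
        assert history[-1] < history[0]
        assert (errors >= 0).all()

    def test_same_seed_identical_weights(self):
        tensors = [_tensor(s) for s in range(4)]
        net1, err1, _ = train_cae(tensors, CaeConfig(epochs=2, seed=5))
        net2, err2, _ = train_cae(tensors, CaeConfig(epochs=2, seed=5))
        from nucat import nn
        s1, s2 = nn.state_dict(net1), nn.state_dict(net2)
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        assert np.array_equal(err1, err2)

    def test_shape_mismatch_rejected(self):
        bad = np.zeros((3, 100, 100), np.float32)
        with pytest.raises(ValueError):
            train_cae([bad], CaeConfig(epochs=1))


class TestClassifyBinary:
    def _model(self, tau):
        return GateModel(net=_OffsetNet(0.05), config=CaeConfig(),
                         threshold=tau, percentile=99.0)

    def test_error_equal_tau_is_cataract(self):
        t = _tensor()
        err = reconstruction_error(_OffsetNet(0.05), t)
        decision = classify_binary(self._model(err), t)
        assert decision.label == CATARACT

    def test_error_above_tau_is_non_cataract(self):
        t = _tensor()
        err = reconstruction_error(_OffsetNet(0.05), t)
        decision = classify_binary(self._model(err - 1e-6), t)
        assert decision.label == NON_CATARACT

    def test_zero_error_always_cataract(self):
        model = GateModel(net=_OffsetNet(0.0), config=CaeConfig(),
                          threshold=0.0, percentile=99.0)
        assert classify_binary(model, _tensor()).label == CATARACT

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            GateModel(net=_OffsetNet(), config=CaeConfig(), threshold=1.0,
                      percentile=99.0, direction="sideways")


class TestEvaluateGate:
    def test_toy_confusion_accuracy(self):
        report = binary_report_from_confusion(np.array([[8, 2], [3, 7]]))
        assert report.accuracy == pytest.approx(0.75)
        assert report.sensitivity == pytest.approx(0.8)
        assert report.specificity == pytest.approx(0.7)

    def test_label_inversion_complements_accuracy(self):
        cm = np.array([[8, 2], [3, 7]])
        inv = cm[::-1, :]  # swap true rows: every decision flips correctness
        a = binary_report_from_confusion(cm).accuracy
        b = binary_report_from_confusion(inv).accuracy
        assert a + b == pytest.approx(1.0)

    def test_perfect_predictions(self):
        report = binary_report_from_confusion(np.array([[5, 0], [0, 5]]))
        assert report.accuracy == 1.0

    def test_single_class_input_warns(self):
        model = GateModel(net=_OffsetNet(0.0), config=CaeConfig(),
                          threshold=1.0, percentile=99.0)
        t = _tensor()
        report = evaluate_gate(model, [t, t], [CATARACT, CATARACT])
        assert report.warning is not None
        assert report.confusion[1] == [0, 0]


def test_gate_save_load_roundtrip(tmp_path, small_gate_model):
    gate.save_gate(small_gate_model, tmp_path / "gate")
    loaded = gate.load_gate(tmp_path / "gate")
    assert loaded.threshold == small_gate_model.threshold
    assert loaded.percentile == small_gate_model.percentile
    t = _tensor(11)
    assert reconstruction_error(loaded.net, t) == pytest.approx(
        reconstruction_error(small_gate_model.net, t), rel=1e-7)
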