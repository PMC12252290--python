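"""Grading: splits, augmentation expansion, the zoo, metrics, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucat import grading, nn, phantoms, preprocess
from nucat.grading import (ARCHITECTURES, SplitSpec, TrainConfig,
                           build_classifier, cross_validate, evaluate,
                           expand_with_augmentation, gap_statistics,
                           largest_remainder, metrics_from_confusion,
                           predict_grade, stratified_fold_indices,
                           stratified_split, train_classifier)
from nucat.preprocess import AugmentationSpec


def _items(class_sizes: dict[str, int], seed=0) -> list[phantoms.LabeledImage]:
    img = np.zeros((224, 224, 3), np.uint8)
    out = []
    for label, n in class_sizes.items():
        for i in range(n):
            out.append(phantoms.LabeledImage(image=img, label=label,
                                             source_id=f"{label}-{i}"))
    return out


def _brute_force_largest_remainder(total, fractions):
    quotas = [total * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    while sum(counts) < total:
        best, best_rem = None, -1.0
        for i, (q, c) in enumerate(zip(quotas, counts)):
            rem = q - c
            if rem > best_rem + 1e-12:
                best, best_rem = i, rem
        counts[best] += 1
    return counts


class TestStratifiedSplit:
    def test_proportional_allocation_example(self):
        data = _items({"1": 30, "2": 20, "3": 10})
        train, val, test = stratified_split(data, SplitSpec(seed=1))
        for subset, expect in ((train, {"1": 24, "2": 16, "3": 8}),
                               (val, {"1": 3, "2": 2, "3": 1}),
                               (test, {"1": 3, "2": 2, "3": 1})):
            for label, n in expect.items():
                assert sum(d.label == label for d in subset) == n

    def test_union_is_input_multiset(self):
        data = _items({"1": 7, "4": 5, "6": 3})
        train, val, test = stratified_split(data, SplitSpec(seed=2))
        got = sorted(d.source_id for s in (train, val, test) for d in s)
        assert got == sorted(d.source_id for d in data)

    def test_singleton_class_goes_to_train(self):
        data = _items({"1": 10, "5": 1})
        train, _, _ = stratified_split(data, SplitSpec(seed=3))
        assert any(d.label == "5" for d in train)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))

    def test_deterministic_given_seed(self):
        data = _items({"1": 13, "2": 9})
        a = stratified_split(data, SplitSpec(seed=8))
        b = stratified_split(data, SplitSpec(seed=8))
        for sa, sb in zip(a, b):
            assert [d.source_id for d in sa] == [d.source_id for d in sb]

    @given(st.integers(0, 200), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_allocation_matches_brute_force_oracle(self, total, seed):
        r = np.random.default_rng(seed)
        fracs = r.dirichlet([2.0, 1.0, 1.0])
        got = largest_remainder(total, fracs)
        assert got == _brute_force_largest_remainder(total, fracs)
        assert sum(got) == total


class TestAugmentationExpansion:
    def test_multiplier_one_is_identity(self):
        data = _items({"1": 4})
        assert expand_with_augmentation(data, AugmentationSpec(), 1) == data

    def test_expansion_counts(self):
        data = _items({"1": 134, "2": 134})  # 268 originals
        out = expand_with_augmentation(data, AugmentationSpec(seed=1), 4)
        assert len(out) == 1072

    def test_labels_preserved_and_deterministic(self):
        data = [phantoms.generate_eye_phantom(
            phantoms.PhantomSpec(label="2", seed=s)) for s in range(3)]
        a = expand_with_augmentation(data, AugmentationSpec(seed=2), 3)
        b = expand_with_augmentation(data, AugmentationSpec(seed=2), 3)
        assert all(x.label == "2" for x in a)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            expand_with_augmentation(_items({"1": 2}), AugmentationSpec(), 0)


class TestArchitectureZoo:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_forward_gives_six_finite_logits(self, arch, rng):
        model = build_classifier(arch, seed=1)
        x = rng.normal(size=(1, 3, 224, 224)).astype(np.float32)
        logits = model.net.forward(x)
        assert logits.shape == (1, 6)
        assert np.isfinite(logits).all()
        probs = nn.softmax(logits)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_classifier("alexnet")

    def test_pretrained_init_unsupported(self):
        with pytest.raises(ValueError, match="pretrained_init"):
            build_classifier("resnet18", pretrained_init=True)


class TestTrainClassifier:
    def test_learns_above_chance_and_history_contract(self):
        data = phantoms.generate_dataset(6, labels=phantoms.GRADE_LABELS,
                                         seed=17)
        train, val = data[:30], data[30:]
        model = build_classifier("resnet18", seed=17)
        cfg = TrainConfig(epochs=3, learning_rate=1e-3, batch_size=8, seed=17)
        train_classifier(model, train, val, cfg)
        assert len(model.history) == 3
        assert model.history[-1]["train_acc"] > 1 / 6
        lrs = [h["lr"] for h in model.history]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_empty_train_set_rejected(self):
        model = build_classifier("resnet18")
        with pytest.raises(ValueError):
            train_classifier(model, [], _items({"1": 1}), TrainConfig(epochs=1))


class TestMetrics:
    def test_perfect_predictions_all_ones(self):
        cm = np.diag([4, 3, 2, 1, 2, 3])
        rep = metrics_from_confusion(cm, grading.GRADE_LABELS)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_toy_binary_confusion_hand_values(self):
        """[[8,2],[3,7]]: accuracy 0.75; macro F1 = (0.7619 + 0.7368)/2."""
        rep = metrics_from_confusion(np.array([[8, 2], [3, 7]]), ("a", "b"))
        assert rep.accuracy == pytest.approx(0.75)
        # independent hand arithmetic for the oracle
        p0, r0 = 8 / 11, 8 / 10
        p1, r1 = 7 / 9, 7 / 10
        f0 = 2 * p0 * r0 / (p0 + r0)
        f1 = 2 * p1 * r1 / (p1 + r1)
        assert rep.f1 == pytest.approx((f0 + f1) / 2, abs=1e-6)
        assert rep.f1 == pytest.approx(0.7494, abs=5e-4)

    def test_accuracy_equals_trace_over_n(self, rng):
        cm = rng.integers(0, 20, (6, 6))
        cm[0, 0] += 1  # non-empty
        rep = metrics_from_confusion(cm, grading.GRADE_LABELS)
        assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        assert rep.n == cm.sum()

    def test_absent_class_contributes_zero_with_warning(self):
        cm = np.zeros((6, 6), int)
        cm[0, 0] = 5
        cm[1, 1] = 5
        with pytest.warns(UserWarning, match="absent"):
            rep = metrics_from_confusion(cm, grading.GRADE_LABELS)
        assert rep.per_class["6"]["f1"] == 0.0
        assert rep.precision == pytest.approx(2 / 6)


class TestPredictGrade:
    def test_probabilities_sum_to_one(self, small_grade_model):
        t = preprocess.normalize_for_model(phantoms.generate_eye_phantom(
            phantoms.PhantomSpec(label="4", seed=50)).image)
        grade, probs = predict_grade(small_grade_model, t)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert grade == int(small_grade_model.classes[np.argmax(probs)])

    def test_equal_logits_tie_breaks_to_grade_one(self):
        model = build_classifier("resnet18", seed=0)
        # zero the head so every logit is the (zero) bias -> 6-way tie
        fc = model.net.modules[-1]
        fc.w.value[...] = 0
        fc.b.value[...] = 0
        t = np.zeros((3, 224, 224), np.float32)
        grade, probs = predict_grade(model, t)
        assert grade == 1
        assert np.allclose(probs, 1 / 6, atol=1e-6)


class TestCrossValidation:
    def test_fold_sizes_and_partition(self):
        labels = ["1"] * 50 + ["2"] * 50
        folds = stratified_fold_indices(labels, k=10, seed=1)
        assert all(len(f) == 10 for f in folds)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(100))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_fold_indices(["1"] * 5, k=10)

    def test_gap_arithmetic_matches_hand_computation(self):
        tr = [0.98, 0.95, 0.97]
        va = [0.90, 0.88, 0.95]
        mean_tr, mean_va, gap, sd = gap_statistics(tr, va)
        diffs = [0.08, 0.07, 0.02]
        assert mean_tr == pytest.approx(np.mean(tr))
        assert mean_va == pytest.approx(np.mean(va))
        assert gap == pytest.approx(np.mean(tr) - np.mean(va))
        assert sd == pytest.approx(np.std(diffs, ddof=1))

    def test_cross_validate_end_to_end_tiny(self):
        data = phantoms.generate_dataset(4, labels=("1", "6"), seed=23)
        cfg = TrainConfig(epochs=1, learning_rate=1e-3, batch_size=4, seed=23)
        report = cross_validate(data, "resnet18", cfg, k=2)
        assert report.k == 2
        assert len(report.val_accuracies) == 2
        assert report.gap == pytest.approx(
            report.mean_train_accuracy - report.mean_val_accuracy)


def test_grader_save_load_roundtrip(tmp_path, small_grade_model, rng):
    grading.save_grader(small_grade_model, tmp_path / "m")
    loaded = grading.load_grader(tmp_path / "m")
    x = rng.normal(size=(2, 3, 224, 224)).astype(np.float32)
    assert np.array_equal(small_grade_model.net.forward(x),
                          loaded.net.forward(x))
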