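"""Focal loss, the training loop and one-vs-rest evaluation metrics."""

import numpy as np
import pytest

import dsmgrade as d
from dsmgrade.train_eval import focal_loss_grad, metrics_from_predictions


def tiny_model(num_classes=3, seed=0):
    cfg = d.DVGGConfig(
        stack_widths=(4, 8), input_size=16, num_classes=num_classes, se_ratio=2, seed=seed
    )
    return d.build_dvgg(cfg)


def toy_data(n=24, num_classes=3, seed=0, size=16):
    """Classes separable by mean intensity alone."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for k in range(num_classes):
        base = -0.8 + 1.6 * k / (num_classes - 1)
        for _ in range(n // num_classes):
            xs.append(base + 0.05 * rng.normal(size=(3, size, size)))
            ys.append(k)
    return np.clip(np.stack(xs), -1, 1), np.array(ys)


class TestFocalLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert d.focal_loss(probs, [0, 1, 2], gamma=2.0) == 0.0

    def test_half_probability_analytic(self):
        probs = np.array([[0.5, 0.5]])
        assert d.focal_loss(probs, [0], gamma=2.0) == pytest.approx(0.25 * np.log(2))

    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(32, 6))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, 6, size=32)
        ce = -np.mean(np.log(probs[np.arange(32), labels]))
        assert d.focal_loss(probs, labels, gamma=0.0) == pytest.approx(ce, abs=1e-7)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            d.focal_loss(np.array([[0.4, 0.4]]), [0])

    @pytest.mark.parametrize("gamma", [0.0, 2.0])
    def test_gradient_matches_finite_differences(self, gamma):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(5, 4))
        labels = rng.integers(0, 4, size=5)
        loss, grad = focal_loss_grad(logits, labels, gamma)
        eps = 1e-6
        for i in range(5):
            for j in range(4):
                bumped = logits.copy()
                bumped[i, j] += eps
                lp, _ = focal_loss_grad(bumped, labels, gamma)
                bumped[i, j] -= 2 * eps
                lm, _ = focal_loss_grad(bumped, labels, gamma)
                assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestTrain:
    def test_overfits_separable_toy_data(self):
        xs, ys = toy_data(n=33, seed=2)
        model = tiny_model(seed=1)
        cfg = d.TrainConfig(learning_rate=2e-3, epochs=30, batch_size=16, seed=0)
        d.train(model, (xs, ys), (xs, ys), cfg)
        report = d.evaluate(model, xs, ys)
        assert report.overall_accuracy == 1.0

    def test_identical_seeds_identical_history(self):
        xs, ys = toy_data(n=18, seed=3)
        cfg = d.TrainConfig(learning_rate=1e-3, epochs=3, batch_size=8, seed=5)
        res_a = d.train(tiny_model(seed=2), (xs, ys), (xs, ys), cfg)
        res_b = d.train(tiny_model(seed=2), (xs, ys), (xs, ys), cfg)
        assert np.array_equal(res_a.history["train_loss"], res_b.history["train_loss"])

    def test_zero_learning_rate_freezes_loss(self):
        xs, ys = toy_data(n=16, num_classes=2, seed=4)
        model = tiny_model(num_classes=2, seed=0)
        cfg = d.TrainConfig(learning_rate=0.0, epochs=3, batch_size=8, seed=0, shuffle=False)
        res = d.train(model, (xs, ys), (xs, ys), cfg)
        losses = res.history["train_loss"].to_numpy()
        assert np.allclose(losses, losses[0], atol=1e-10)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            d.train(tiny_model(), (np.zeros((0, 3, 16, 16)), np.zeros(0)), (None, None))

    def test_loss_mostly_non_increasing_on_separable_data(self, tiny_run):
        _, result, _, _ = tiny_run
        losses = result.history["train_loss"].to_numpy()
        drops = (np.diff(losses) <= 1e-9).mean()
        assert drops >= 0.9


class TestEvaluate:
    def test_perfect_predictions(self):
        report = metrics_from_predictions([0, 1, 2, 3, 4, 5], [0, 1, 2, 3, 4, 5], list("ABCDEF"))
        assert report.overall_accuracy == 1.0
        for stats in report.per_class.values():
            assert stats["P"] == stats["R"] == stats["S"] == stats["F1"] == 1.0
        assert list(report.averaged.values()) == pytest.approx([1.0] * 4)

    def test_single_class_collapse_two_class_toy(self):
        y_true = [0] * 5 + [1] * 5
        report = metrics_from_predictions(y_true, [0] * 10, ["a", "b"])
        assert report.overall_accuracy == 0.5
        assert report.per_class["a"]["R"] == 1.0
        assert report.per_class["b"]["R"] == 0.0
        assert report.undefined_precision == ["b"]
        assert report.per_class["b"]["P"] == 0.0

    def test_counts_partition_and_support_identity(self):
        rng = np.random.default_rng(6)
        y_true = rng.integers(0, 3, size=300)
        y_pred = rng.integers(0, 3, size=300)
        report = metrics_from_predictions(y_true, y_pred, [0, 1, 2])
        for c, stats in report.per_class.items():
            assert stats["TP"] + stats["TN"] + stats["FP"] + stats["FN"] == 300
            assert stats["TP"] + stats["FN"] == (y_true == c).sum()
        assert report.overall_accuracy == pytest.approx((y_true == y_pred).mean())

    def test_matches_sklearn_oracle(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        y_true = rng.integers(0, 3, size=300)
        y_pred = rng.integers(0, 3, size=300)
        report = metrics_from_predictions(y_true, y_pred, [0, 1, 2])
        assert report.averaged["precision"] == pytest.approx(
            sk.precision_score(y_true, y_pred, average="weighted")
        )
        assert report.averaged["recall"] == pytest.approx(
            sk.recall_score(y_true, y_pred, average="weighted")
        )
        assert report.averaged["f1"] == pytest.approx(
            sk.f1_score(y_true, y_pred, average="weighted")
        )
        assert report.macro["f1"] == pytest.approx(sk.f1_score(y_true, y_pred, average="macro"))
        for c in (0, 1, 2):
            assert report.per_class[c]["P"] == pytest.approx(
                sk.precision_score(y_true, y_pred, labels=[c], average="macro", zero_division=0)
            )


class TestPredict:
    def test_single_class_overfit_predicts_that_class(self, tmp_path):
        params = d.DEFAULT_CLASS_TABLE["grade-A"]
        xs, paths = [], []
        from dataclasses import replace
        from PIL import Image

        for k in range(8):
            img, _ = d.generate_image(replace(params, seed=100 + k, image_size=48))
            path = tmp_path / f"a_{k}.png"
            Image.fromarray(img).save(path)
            paths.append(path)
            # train on the same segmented crops inference will see
            crop_img, _, _ = d.segment_mushroom(img, d.OOAConfig(seed=0))
            xs.append(d.normalize_for_model(d.resize_bicubic(crop_img, 16)).transpose(2, 0, 1))
        xs = np.stack(xs)
        ys = np.zeros(len(xs), dtype=np.intp)
        model = tiny_model(num_classes=3, seed=0)
        cfg = d.TrainConfig(learning_rate=2e-3, epochs=40, batch_size=8, seed=0)
        d.train(model, (xs, ys), (xs, ys), cfg)
        results = d.predict(model, paths[:2], label_names=["grade-A", "grade-B", "grade-C"],
                            seg_config=d.OOAConfig(seed=0))
        for res in results:
            assert res["label"] == "grade-A"
            total = sum(res["probabilities"].values())
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_unreadable_file_reports_error_and_continues(self, tmp_path):
        bad = tmp_path / "nope.png"
        bad.write_text("not an image")
        model = tiny_model()
        results = d.predict(model, [bad], segment=False)
        assert "error" in results[0]

    def test_identical_image_identical_output(self, tmp_path):
        from PIL import Image

        img, _ = d.generate_image(d.SyntheticGradeParams(seed=5, image_size=48))
        path = tmp_path / "x.png"
        Image.fromarray(img).save(path)
        model = tiny_model()
        a = d.predict(model, [path, path], seg_config=d.OOAConfig(seed=1))
        assert a[0]["probabilities"] == a[1]["probabilities"]
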