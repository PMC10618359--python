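"""Shared fixtures: seeded synthetic suites and one scaled-down training run."""

from __future__ import annotations

import numpy as np
import pytest

import dsmgrade as d


def square_iou(a, b) -> float:
    """Intersection-over-union of two SquareROIs."""
    iw = max(0, min(a.x0 + a.side, b.x0 + b.side) - max(a.x0, b.x0))
    ih = max(0, min(a.y0 + a.side, b.y0 + b.side) - max(a.y0, b.y0))
    inter = iw * ih
    return inter / (a.side**2 + b.side**2 - inter)


@pytest.fixture(scope="session")
def bimodal_suite():
    """200 seeded synthetic bimodal images with their gray versions."""
    suite = []
    for s in range(200):
        params = d.SyntheticGradeParams(seed=s, crack_density=0.3, speckle_count=2)
        img, truth = d.generate_image(params)
        suite.append((img, d.to_grayscale(img), truth, params))
    return suite


@pytest.fixture(scope="session")
def iou_suite():
    """ROI-vs-ground-truth IoU over 50 seeded speckled images."""
    vals = []
    for s in range(50):
        params = d.SyntheticGradeParams(seed=1000 + s, crack_density=0.5, speckle_count=3)
        img, truth = d.generate_image(params)
        _, roi, _ = d.segment_mushroom(img, d.OOAConfig(seed=s))
        vals.append(square_iou(roi, truth.bounding_square))
    return np.asarray(vals)


@pytest.fixture(scope="session")
def tiny_run():
    """The scaled-down end-to-end run: 3 classes × 60 images, 10 epochs.

    Returns (model, train_result, holdout report, label names).
    """
    samples, manifest = d.generate_dataset(60, seed=7, image_size=64)
    labels = sorted(manifest["label"].unique())
    index = {l: i for i, l in enumerate(labels)}
    xs = np.stack(
        [d.normalize_for_model(d.resize_bicubic(img, 32)).transpose(2, 0, 1) for img, _ in samples]
    )
    ys = np.array([index[t.label] for _, t in samples])
    manifest = d.split_dataset(manifest, 0.7, seed=7)
    tr = (manifest["split"] == "train").to_numpy()
    cfg = d.DVGGConfig(stack_widths=(8, 16, 32), num_classes=3, se_ratio=4, input_size=32, seed=0)
    model = d.build_dvgg(cfg)
    result = d.train(
        model,
        (xs[tr], ys[tr]),
        (xs[~tr], ys[~tr]),
        d.TrainConfig(learning_rate=1e-3, epochs=10, seed=0),
    )
    report = d.evaluate(model, xs[~tr], ys[~tr], labels)
    return model, result, report, labels
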