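"""Architecture: BN math, channel attention, residual stacks, parameter counts."""

import numpy as np
import pytest

import dsmgrade as d
from dsmgrade import nn
from dsmgrade.model import DVGGConfig, StackSpec, build_stack


def expected_parameter_count(config: DVGGConfig) -> int:
    """Independent closed-form sum over the architecture description."""
    total = 0
    cin = 3
    for w in config.stack_widths:
        convs = [(cin, w, 3), (w, w, 3)]
        if config.use_residual:
            convs.append((cin, w, 1))
        for ci, co, k in convs:
            total += k * k * ci * co
            total += 2 * co if config.use_batchnorm else co  # BN γ/β or conv bias
        if config.use_se:
            hidden = w // config.se_ratio
            total += w * hidden + hidden + hidden * w + w
        cin = w
    head_in = config.stack_widths[-1]
    if not config.use_gap_head:
        head_in *= config.gap_spatial**2
    return total + head_in * config.num_classes + config.num_classes


class TestBatchNorm:
    def test_two_point_batch_standardized(self):
        bn = nn.BatchNorm2d(1, eps=1e-12)
        x = np.array([2.0, 4.0]).reshape(2, 1, 1, 1)
        out = bn.forward(x, train=True).ravel()
        assert out == pytest.approx([-1.0, 1.0], abs=1e-5)

    def test_gamma_beta_shift_scale(self):
        bn = nn.BatchNorm2d(1, eps=1e-12)
        bn.gamma.value[:] = 3.0
        bn.beta.value[:] = 5.0
        rng = np.random.default_rng(0)
        x = rng.normal(size=(64, 1, 1, 1))
        out = bn.forward(x, train=True)
        assert out.mean() == pytest.approx(5.0, abs=1e-6)
        assert out.std() == pytest.approx(3.0, abs=1e-4)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(2.0, 3.0, size=(64, 4, 3, 3))
        bn = nn.BatchNorm2d(4)
        out = bn.forward(x, train=True)
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)  # two-pass, biased
        expected = (x - mu) / np.sqrt(var + bn.eps)
        assert np.allclose(out, expected, atol=1e-6)
        # train-mode output is standardized per channel within ε tolerance
        assert np.allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-5)
        assert np.allclose(out.var(axis=(0, 2, 3)), 1.0, atol=1e-5)

    def test_small_batch_rejected_in_train_mode(self):
        with pytest.raises(ValueError):
            nn.BatchNorm2d(1).forward(np.zeros((1, 1, 2, 2)), train=True)


class TestSqueezeExcite:
    def test_squeeze_constant_and_half_half(self):
        fm = np.full((4, 4, 2), 3.0)
        assert d.se_squeeze(fm) == pytest.approx([3.0, 3.0])
        half = np.zeros((2, 4, 1))
        half[:, 2:, 0] = 8.0  # mean 4, max 8 → midpoint 6
        assert d.se_squeeze(half) == pytest.approx([6.0])

    def test_squeeze_matches_mean_max_oracle(self):
        rng = np.random.default_rng(0)
        fm = rng.normal(size=(7, 7, 512))
        expected = (fm.mean(axis=(0, 1)) + fm.max(axis=(0, 1))) / 2.0
        assert np.allclose(d.se_squeeze(fm), expected)

    def test_excite_zero_weights_give_half(self):
        z = np.ones(8)
        s = d.se_excite(z, np.zeros((2, 8)), np.zeros(2), np.zeros((8, 2)), np.zeros(8))
        assert s == pytest.approx(np.full(8, 0.5))

    def test_excite_saturation_and_oracle(self):
        z = np.array([1.0])
        # pre-sigmoid value of 6 in the only channel
        s = d.se_excite(z, np.array([[1.0]]), np.zeros(1), np.array([[6.0]]), np.zeros(1))
        assert s[0] == pytest.approx(1.0 / (1.0 + np.exp(-6.0)))
        rng = np.random.default_rng(5)
        w1, b1 = rng.normal(size=(4, 16)), rng.normal(size=4)
        w2, b2 = rng.normal(size=(16, 4)), rng.normal(size=16)
        z = rng.normal(size=16)
        hand = 1.0 / (1.0 + np.exp(-(w2 @ np.minimum(np.maximum(w1 @ z + b1, 0), 6) + b2)))
        assert np.allclose(d.se_excite(z, w1, b1, w2, b2), hand)
        assert ((hand > 0) & (hand < 1)).all()

    def test_rescale(self):
        rng = np.random.default_rng(1)
        fm = rng.normal(size=(5, 6, 3))
        s = rng.random(3)
        assert np.allclose(d.se_rescale(fm, s), fm * s)
        assert np.array_equal(d.se_rescale(fm, np.ones(3)), fm)
        assert not d.se_rescale(fm, np.zeros(3)).any()

    def test_se_layer_weights_in_open_interval_and_shape_kept(self):
        rng = np.random.default_rng(2)
        block = nn.SEBlock(8, 2, rng=rng)
        x = rng.normal(size=(3, 8, 5, 5))
        out = block.forward(x)
        assert out.shape == x.shape
        s = block._cache[-1]
        assert ((s > 0) & (s < 1)).all()


class TestStack:
    def test_spatial_size_preserved(self):
        stack = build_stack(StackSpec(3, 32), seed=0)
        out = stack.forward(np.zeros((2, 3, 32, 32)), train=False)
        assert out.shape == (2, 32, 32, 32)

    def test_zeroed_main_path_computes_shortcut_only(self):
        stack = build_stack(StackSpec(3, 8), seed=1)
        stack.conv1.weight.value[:] = 0.0
        stack.conv2.weight.value[:] = 0.0
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 6, 6))
        out = stack.forward(x, train=False)  # eval: BN uses init running stats
        sc = stack.bn_sc.forward(stack.shortcut.forward(x), train=False)
        assert np.allclose(out, np.maximum(sc, 0.0))

    @pytest.mark.parametrize("use_bn,use_res", [(True, True), (False, False), (True, False)])
    def test_parameter_count_closed_form(self, use_bn, use_res):
        spec = StackSpec(3, 32, use_batchnorm=use_bn, use_residual=use_res)
        stack = build_stack(spec)
        convs = 864 + 9216 + (96 if use_res else 0)
        n_convs = 3 if use_res else 2
        extras = (2 * 32 * n_convs) if use_bn else (32 * n_convs)
        assert d.count_parameters(stack) == convs + extras


class TestDVGG:
    def test_softmax_rows_and_gap_geometry(self):
        model = d.build_dvgg(DVGGConfig(stack_widths=(8, 16), input_size=16, num_classes=6, se_ratio=4))
        rng = np.random.default_rng(0)
        probs = model.predict_proba(rng.normal(size=(2, 3, 16, 16)))
        assert probs.shape == (2, 6)
        assert probs.sum(axis=1) == pytest.approx([1.0, 1.0], abs=1e-6)
        assert model._gap_input_shape == (2, 16, 4, 4)

    def test_full_architecture_reaches_gap_as_7x7x512(self):
        model = d.build_dvgg()
        x = np.zeros((1, 3, 224, 224))
        logits = model.forward(x, train=False)
        assert model._gap_input_shape == (1, 512, 7, 7)
        assert logits.shape == (1, 6)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            DVGGConfig(input_size=100)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"use_residual": False, "use_batchnorm": False},
            {"use_se": False},
            {"stack_widths": (8, 16, 32), "input_size": 32, "num_classes": 3, "se_ratio": 4},
        ],
    )
    def test_count_matches_closed_form_oracle(self, kwargs):
        config = DVGGConfig(**kwargs)
        assert d.count_parameters(d.build_dvgg(config)) == expected_parameter_count(config)

    def test_published_parameter_totals(self):
        """Full network: 4.94×10⁶; residual+BN ablation: 4.76×10⁶ (two-decimal
        rounding in millions)."""
        full = d.count_parameters(d.build_dvgg())
        assert round(full / 1e6, 2) == 4.94
        ablation = d.count_parameters(
            d.build_dvgg(DVGGConfig(use_residual=False, use_batchnorm=False))
        )
        assert round(ablation / 1e6, 2) == 4.76

    def test_bare_head_count(self):
        assert d.count_parameters(nn.Linear(512, 6)) == 3078

    def test_backward_matches_finite_differences(self):
        """The hand-derived backward pass of the whole network (conv, BN, SE,
        pool, GAP, linear, focal loss) agrees with central differences."""
        from dsmgrade.train_eval import focal_loss_grad

        rng = np.random.default_rng(0)
        cfg = DVGGConfig(stack_widths=(4, 8), num_classes=3, se_ratio=2, input_size=8, seed=1)
        model = d.build_dvgg(cfg)
        x = rng.normal(size=(4, 3, 8, 8))
        y = np.array([0, 1, 2, 1])
        model.zero_grad()
        loss, dz = focal_loss_grad(model.forward(x, train=True), y, 2.0)
        model.backward(dz)

        def loss_at():
            return focal_loss_grad(model.forward(x, train=True), y, 2.0)[0]

        eps = 1e-6
        for p in model.params():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_at()
                flat[i] = old - eps
                lm = loss_at()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert grad[i] == pytest.approx(num, abs=1e-5, rel=1e-4)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = DVGGConfig(stack_widths=(4, 8), input_size=8, num_classes=3, se_ratio=2, seed=3)
        model = d.build_dvgg(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 8, 8))
        before = model.predict_proba(x)
        d.save_checkpoint(model, tmp_path / "ckpt")
        restored = d.load_checkpoint(tmp_path / "ckpt")
        assert restored.config == cfg
        assert np.allclose(restored.predict_proba(x), before)
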