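"""The translation GAN: loss contracts, gradients, training, inference."""

import numpy as np
import pytest

from virtualstain import gan, metrics, phantom
from virtualstain.imaging import ImagePatch, RegisteredPair, RGBImage, StainState
from virtualstain.nn import Tensor, avg_pool2, bce_with_logits, conv2d, upsample2


def _finite_diff(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        up = f()
        flat[i] = orig - eps
        down = f()
        flat[i] = orig
        gflat[i] = (up - down) / (2 * eps)
    return g


class TestAutogradGradients:
    """Analytic gradients agree with central finite differences."""

    def test_conv2d_gradients(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 5, 5)).astype(np.float32),
                   requires_grad=True)
        w = Tensor(rng.standard_normal((3, 2, 3, 3)).astype(np.float32),
                   requires_grad=True)
        b = Tensor(rng.standard_normal(3).astype(np.float32),
                   requires_grad=True)

        def loss_value():
            return float((conv2d(x, w, b, 3) * scale).sum().data)

        scale = Tensor(rng.standard_normal((1, 3, 5, 5)).astype(np.float32))
        loss = (conv2d(x, w, b, 3) * scale).sum()
        loss.backward()
        for t in (x, w, b):
            num = _finite_diff(loss_value, t.data)
            np.testing.assert_allclose(t.grad, num, rtol=1e-2, atol=1e-3)

    def test_pool_and_upsample_gradients(self, rng):
        x = Tensor(rng.standard_normal((1, 1, 4, 4)).astype(np.float32),
                   requires_grad=True)
        scale = Tensor(rng.standard_normal((1, 1, 4, 4)).astype(np.float32))

        def value():
            return float((upsample2(avg_pool2(x)) * scale).sum().data)

        loss = (upsample2(avg_pool2(x)) * scale).sum()
        loss.backward()
        num = _finite_diff(value, x.data)
        np.testing.assert_allclose(x.grad, num, rtol=1e-2, atol=1e-3)

    def test_bce_with_logits_gradient(self, rng):
        z = Tensor(rng.standard_normal((2, 1, 3, 3)).astype(np.float32),
                   requires_grad=True)

        def value():
            return float(bce_with_logits(z, 1.0).data)

        bce_with_logits(z, 1.0).backward()
        num = _finite_diff(value, z.data)
        np.testing.assert_allclose(z.grad, num, rtol=1e-2, atol=1e-4)

    def test_pcc_loss_gradient(self, rng):
        p = Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32),
                   requires_grad=True)
        t = np.asarray(rng.standard_normal((1, 3, 4, 4)), dtype=np.float32)

        def value():
            return float(gan.pcc_loss(p, t).data)

        gan.pcc_loss(p, t).backward()
        num = _finite_diff(value, p.data)
        np.testing.assert_allclose(p.grad, num, rtol=1e-2, atol=1e-4)


class TestPCCLoss:
    def test_identical_nonconstant_is_zero(self, rng):
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        assert float(gan.pcc_loss(x, x).data) == pytest.approx(0.0, abs=1e-5)

    def test_negative_image_is_two(self, rng):
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        inv = x.max() - x
        assert float(gan.pcc_loss(inv, x).data) == pytest.approx(2.0, abs=1e-5)

    def test_independent_random_batches_near_one(self):
        rng = np.random.default_rng(0)
        vals = [
            float(
                gan.pcc_loss(
                    rng.random((1, 3, 64, 64), dtype=np.float32),
                    rng.random((1, 3, 64, 64), dtype=np.float32),
                ).data
            )
            for _ in range(100)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_invariant_to_common_positive_affine_rescaling(self, rng):
        a = rng.random((1, 3, 8, 8)).astype(np.float32)
        b = rng.random((1, 3, 8, 8)).astype(np.float32)
        base = float(gan.pcc_loss(a, b).data)
        scaled = float(gan.pcc_loss(2.5 * a + 0.3, 2.5 * b + 0.3).data)
        assert scaled == pytest.approx(base, abs=1e-5)

    def test_zero_variance_convention(self, rng, caplog):
        flat = np.full((1, 3, 8, 8), 0.5, dtype=np.float32)
        noisy = rng.random((1, 3, 8, 8)).astype(np.float32)
        with caplog.at_level("WARNING"):
            val = float(gan.pcc_loss(noisy, flat).data)
        assert val == pytest.approx(1.0, abs=1e-4)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_range_bounds(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            v = float(
                gan.pcc_loss(
                    r.random((1, 3, 8, 8), dtype=np.float32),
                    r.random((1, 3, 8, 8), dtype=np.float32),
                ).data
            )
            assert 0.0 <= v <= 2.0


class TestGeneratorLoss:
    def test_identical_prediction_leaves_only_adversarial_term(self, rng):
        x = rng.random((1, 3, 8, 8)).astype(np.float32)
        cfg = gan.LossConfig(lambda_adv=1.0, lambda_l1=100.0, lambda_pcc=10.0)
        total = float(gan.generator_loss(0.37, x, x, cfg).data)
        assert total == pytest.approx(0.37, abs=1e-4)

    def test_lambda_pcc_zero_reproduces_pix2pix_objective(self, rng):
        p = rng.random((2, 3, 8, 8)).astype(np.float32)
        t = rng.random((2, 3, 8, 8)).astype(np.float32)
        cfg = gan.LossConfig(lambda_adv=1.0, lambda_l1=100.0, lambda_pcc=0.0)
        got = float(gan.generator_loss(0.5, p, t, cfg).data)
        baseline = 0.5 + 100.0 * float(np.mean(np.abs(p - t)))
        assert got == pytest.approx(baseline, rel=1e-6)

    def test_hand_computed_tiny_example(self):
        """2x2x3 example evaluated with independent plain-numpy formulas."""
        p = np.arange(12, dtype=np.float32).reshape(1, 3, 2, 2) / 12.0
        t = np.array(
            [0.1, 0.9, 0.3, 0.2, 0.8, 0.4, 0.5, 0.7, 0.6, 0.0, 1.0, 0.5],
            dtype=np.float32,
        ).reshape(1, 3, 2, 2)
        mae = float(np.mean(np.abs(p - t)))
        r = float(np.corrcoef(p.ravel(), t.ravel())[0, 1])
        cfg = gan.LossConfig(lambda_adv=2.0, lambda_l1=3.0, lambda_pcc=5.0)
        expected = 2.0 * 0.25 + 3.0 * mae + 5.0 * (1.0 - r)
        got = float(gan.generator_loss(0.25, p, t, cfg).data)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_decomposition_matches_component_sum(self, rng):
        p = rng.random((2, 3, 8, 8)).astype(np.float32)
        t = rng.random((2, 3, 8, 8)).astype(np.float32)
        cfg = gan.LossConfig(lambda_adv=1.5, lambda_l1=7.0, lambda_pcc=2.0)
        total = float(gan.generator_loss(0.9, p, t, cfg).data)
        parts = (
            1.5 * 0.9
            + 7.0 * float(gan.mae_loss(p, t).data)
            + 2.0 * float(gan.pcc_loss(p, t).data)
        )
        assert total == pytest.approx(parts, rel=1e-6)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            gan.LossConfig(lambda_l1=-1.0)


def _identity_pairs(n, size=32, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        px = rng.integers(0, 256, (size, size, 3), dtype=np.uint8)
        src = ImagePatch(px, slide_id=f"p{i}", stain_state=StainState.NONSTAINED)
        tgt = ImagePatch(px.copy(), slide_id=f"p{i}",
                         stain_state=StainState.DYE_STAINED)
        pairs.append(RegisteredPair(src, tgt))
    return pairs


class TestTraining:
    def test_loss_decreases_over_epochs(self, noise_free_palette):
        pairs = phantom.make_training_set(24, seed=1, shape=(64, 64),
                                          palette=noise_free_palette)
        cfg = gan.TrainingConfig(direction="stain", epochs=4, batch_size=8,
                                 seed=1, patch_size=64)
        model = gan.train(pairs, cfg)
        assert model.history[-1]["total"] < model.history[0]["total"]

    def test_same_seed_identical_history(self, noise_free_palette):
        pairs = phantom.make_training_set(8, seed=2, shape=(64, 64),
                                          palette=noise_free_palette)
        cfg = gan.TrainingConfig(direction="stain", epochs=2, batch_size=4,
                                 seed=9, patch_size=64)
        h1 = gan.train(pairs, cfg).history
        h2 = gan.train(pairs, cfg).history
        assert h1 == h2

    def test_identity_mapping_is_learnable(self):
        pairs = _identity_pairs(20, size=32)
        cfg = gan.TrainingConfig(direction="stain", epochs=12, batch_size=4,
                                 seed=3, patch_size=32, lr_generator=5e-3)
        model = gan.train(pairs, cfg)
        held_out = _identity_pairs(5, size=32, seed=100)
        ssims = [
            metrics.ssim(gan.apply(model, RGBImage(p.source.pixels)),
                         RGBImage(p.source.pixels))
            for p in held_out
        ]
        assert np.mean(ssims) > 0.9

    def test_empty_and_mixed_inputs_rejected(self, noise_free_palette):
        with pytest.raises(ValueError):
            gan.train([], gan.TrainingConfig())
        p64 = phantom.make_training_set(2, seed=0, shape=(64, 64),
                                        palette=noise_free_palette)
        p128 = phantom.make_training_set(2, seed=0, shape=(128, 128),
                                         palette=noise_free_palette)
        with pytest.raises(ValueError, match="mixed"):
            gan.train(p64 + p128, gan.TrainingConfig(patch_size=64))


class TestApply:
    def test_output_shape_and_state(self, tiny_model, rng):
        img = RGBImage(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))
        out = gan.apply(tiny_model, img)
        assert out.pixels.shape == (32, 32, 3)
        assert out.stain_state == StainState.COMP_STAINED

    def test_untrained_model_valid_and_in_range(self, rng):
        model = gan._build_model(
            gan.GeneratorSpec(depth=2, base_channels=8, convs_per_level=1),
            gan.TrainingConfig(patch_size=32),
            gan.LossConfig(),
        )
        img = RGBImage(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))
        out = gan.apply(model, img)
        assert out.pixels.dtype == np.uint8
        assert out.pixels.shape == img.pixels.shape

    def test_large_image_processed_via_tiling(self, tiny_model, rng):
        img = RGBImage(rng.integers(0, 256, (70, 50, 3), dtype=np.uint8))
        out = gan.apply(tiny_model, img)
        assert out.pixels.shape == (70, 50, 3)

    def test_destain_tags_comp_destained(self, noise_free_palette):
        pairs = phantom.make_training_set(8, seed=4, shape=(64, 64),
                                          palette=noise_free_palette)
        cfg = gan.TrainingConfig(direction="destain", epochs=1, batch_size=4,
                                 seed=4, patch_size=64)
        model = gan.train(pairs, cfg)
        out = gan.apply(model, RGBImage(pairs[0].target.pixels))
        assert out.stain_state == StainState.COMP_DESTAINED


class TestSerialization:
    def test_save_load_bit_identical_inference(self, tiny_model, tmp_path, rng):
        img = RGBImage(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))
        before = gan.apply(tiny_model, img).pixels
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = gan.TrainedModel.load(path)
        after = gan.apply(loaded, img).pixels
        assert np.array_equal(before, after)
        assert loaded.history == tiny_model.history

    def test_tracked_layer_count_19_for_canonical_spec(self):
        assert gan.GeneratorSpec().tracked_layer_count == 19
        assert gan.GeneratorSpec(depth=2, convs_per_level=1).tracked_layer_count == 7
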