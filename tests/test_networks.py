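"""Structural audits, shape contracts, determinism and gradient flow of the
correction networks, plus checkpoint fingerprinting."""

import numpy as np
import pytest

from tococonet.nn import (
    DCCN,
    Adam,
    DccnConfig,
    MBlock,
    NetworkConfig,
    ReduceLROnPlateau,
    TococoNet,
    UBlock,
    audit_architecture,
    correct_image,
    load_checkpoint,
    save_checkpoint,
)
from tococonet.nn.layers import (
    BatchNorm2d,
    BilinearUpsample2x,
    Conv2d,
    MaxPool2x2,
    set_default_dtype,
)
from tococonet.training import mse_loss

TINY = NetworkConfig(
    ublock_mid_filters=4,
    ublock_out_channels=6,
    mblock_filters=4,
    mblock_out_channels=6,
    head_filters=6,
)


@pytest.fixture()
def f64():
    set_default_dtype(np.float64)
    yield
    set_default_dtype(np.float32)


class TestAudit:
    def test_tococonet_has_26_conv_layers(self):
        counts = audit_architecture(TococoNet(seed=0))
        assert counts["conv_layers"] == 26

    def test_reduced_variant_keeps_the_budget(self):
        assert audit_architecture(TococoNet(NetworkConfig.reduced(), seed=0))["conv_layers"] == 26

    def test_dccn_five_convs_no_pool_no_bn(self):
        counts = audit_architecture(DCCN(seed=0))
        assert counts == {"conv_layers": 5, "pooling": 0, "batch_norm": 0}

    def test_wrong_budget_raises_with_count(self):
        with pytest.raises(ValueError, match="26"):
            TococoNet(NetworkConfig(total_conv_layers=25), seed=0)


class TestBlocks:
    def test_ublock_preserves_spatial_size(self, rng):
        blk = UBlock(3, 4, 6, rng)
        for size in (8, 160):
            out = blk(np.zeros((1, size, size, 3), dtype=np.float32))
            assert out.shape == (1, size, size, 6)

    def test_ublock_rejects_indivisible_input(self, rng):
        blk = UBlock(3, 4, 6, rng)
        with pytest.raises(ValueError, match="divisible by 4"):
            blk(np.zeros((1, 10, 10, 3), dtype=np.float32))

    def test_ublock_deepest_level_is_quarter_resolution(self, rng):
        blk = UBlock(3, 4, 6, rng)
        x = np.zeros((1, 16, 16, 3), dtype=np.float32)
        blk(x)
        assert blk.pool2._in_shape[1:3] == (8, 8)  # after one pooling
        # pooled once more → deepest maps at 4×4 = input/4

    def test_mblock_constant_resolution_and_conv_count(self, rng):
        blk = MBlock(5, 4, 6, rng)
        out = blk(np.zeros((2, 12, 20, 5), dtype=np.float32))
        assert out.shape == (2, 12, 20, 6)
        assert sum(isinstance(m, Conv2d) for m in blk.submodules()) == 8

    def test_mblock_zero_weights_give_zero_prefusion_features(self, rng):
        blk = MBlock(3, 4, 6, rng)
        for conv in blk.convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = np.random.default_rng(0).random((1, 8, 8, 3)).astype(np.float32)
        h = x
        for conv, relu in zip(blk.convs, blk.relus[:7]):
            h = relu(conv(h))
        assert np.all(h == 0.0)


class TestForwardContracts:
    @pytest.mark.parametrize("size", [(160, 160), (320, 320), (64, 96)])
    def test_image_to_image_shape(self, size):
        net = TococoNet(TINY, seed=0)
        x = np.zeros((1, *size, 3), dtype=np.float32)
        assert net.forward(x, train=False).shape == (1, *size, 3)

    def test_dccn_patch_shape(self):
        net = DCCN(DccnConfig(hidden_filters=8), seed=0)
        x = np.zeros((2, 40, 40, 3), dtype=np.float32)
        assert net.forward(x, train=False).shape == (2, 40, 40, 3)

    def test_dccn_zero_adjustments_match_zeroed_extra_weights(self, rng):
        net = DCCN(DccnConfig(hidden_filters=8), seed=0)
        x = rng.random((1, 16, 16, 3)).astype(np.float32)
        base = net.forward(x, train=False, adjustments=(0.0, 0.0, 0.0))
        # zero the weights feeding the three adjustment planes: same output
        w = net.convs[0].weight.data.reshape(net.convs[0].out_channels, 9, 6)
        w[:, :, 3:] = 0.0
        assert np.allclose(net.forward(x, train=False, adjustments=(0.3, -0.2, 0.9)), base)

    def test_forward_is_deterministic(self, rng):
        net = TococoNet(TINY, seed=3)
        x = rng.random((2, 16, 16, 3)).astype(np.float32)
        a = net.forward(x.copy(), train=False)
        b = net.forward(x.copy(), train=False)
        assert np.array_equal(a, b)

    def test_same_seed_same_initialization(self):
        p1 = TococoNet(TINY, seed=5).parameters()
        p2 = TococoNet(TINY, seed=5).parameters()
        assert all(np.array_equal(a.data, b.data) for a, b in zip(p1, p2))


class TestGradients:
    def _check(self, model, x, y, rng, n_checks=8, eps=1e-6):
        pred = model.forward(x, train=True)
        for p in model.parameters():
            p.zero_grad()
        model.backward((2.0 / pred.size) * (pred - y))
        for p in rng.choice(model.parameters(), size=n_checks, replace=False):
            flat = p.data.ravel()
            i = int(rng.integers(flat.size))
            old = flat[i]
            flat[i] = old + eps
            lp = mse_loss(model.forward(x, train=True), y)
            flat[i] = old - eps
            lm = mse_loss(model.forward(x, train=True), y)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[i]
            assert abs(num - ana) <= 1e-5 * max(1.0, abs(num) + abs(ana)), p.name

    def test_tococonet_matches_finite_differences(self, f64, rng):
        net = TococoNet(TINY, seed=2)
        x, y = rng.random((2, 8, 8, 3)), rng.random((2, 8, 8, 3))
        self._check(net, x, y, rng)

    def test_dccn_matches_finite_differences(self, f64, rng):
        net = DCCN(DccnConfig(hidden_filters=6), seed=2)
        x, y = rng.random((2, 8, 8, 3)), rng.random((2, 8, 8, 3))
        self._check(net, x, y, rng)

    def test_one_adam_step_decreases_loss(self, rng):
        net = TococoNet(TINY, seed=1)
        x = rng.random((4, 8, 8, 3)).astype(np.float32)
        y = (x * 0.7).astype(np.float32)
        opt = Adam(net.parameters(), lr=1e-3)
        pred = net.forward(x, train=True)
        before = mse_loss(pred, y)
        opt.zero_grad()
        net.backward(((2.0 / pred.size) * (pred - y)).astype(np.float32))
        opt.step()
        after = mse_loss(net.forward(x, train=True), y)
        assert after < before


class TestLayerGradients:
    """Finite-difference checks for the individual layer primitives."""

    @pytest.mark.parametrize(
        "layer_factory,channels",
        [
            (lambda rng: Conv2d(3, 5, 3, rng), 3),
            (lambda rng: Conv2d(4, 2, 1, rng), 4),
            (lambda rng: BatchNorm2d(3), 3),
            (lambda rng: MaxPool2x2(), 3),
            (lambda rng: BilinearUpsample2x(), 3),
        ],
    )
    def test_input_gradient(self, f64, rng, layer_factory, channels):
        layer = layer_factory(rng)
        x = rng.random((2, 4, 4, channels))
        target_shape = layer(x).shape
        w = rng.random(target_shape)  # random linear functional of the output
        layer(x)
        gx = layer.backward(w)
        eps = 1e-6
        for _ in range(5):
            idx = tuple(rng.integers(s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (np.sum(layer(xp) * w) - np.sum(layer(xm) * w)) / (2 * eps)
            layer(x)
            layer.backward(w)
            assert num == pytest.approx(gx[idx], abs=1e-5, rel=1e-4)


class TestCorrectImage:
    def test_untrained_output_valid_uint8(self, small_scene):
        out = correct_image(TococoNet(TINY, seed=0), small_scene)
        assert out.shape == small_scene.shape and out.dtype == np.uint8

    def test_pad_and_crop_for_odd_sizes(self, small_scene):
        img = small_scene[:157, :153]
        out = correct_image(TococoNet(TINY, seed=0), img)
        assert out.shape == img.shape

    def test_nonfinite_parameters_rejected(self, small_scene):
        net = TococoNet(TINY, seed=0)
        net.parameters()[0].data[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            correct_image(net, small_scene)


class TestCheckpoints:
    def test_roundtrip_restores_output(self, tmp_path, rng):
        net = TococoNet(TINY, seed=4)
        x = rng.random((1, 16, 16, 3)).astype(np.float32)
        ref = net.forward(x, train=False)
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        other = TococoNet(TINY, seed=9)
        load_checkpoint(other, path)
        assert np.allclose(other.forward(x, train=False), ref)

    def test_fingerprint_mismatch_refused(self, tmp_path):
        net = TococoNet(TINY, seed=0)
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        with pytest.raises(ValueError, match="fingerprint"):
            load_checkpoint(DCCN(DccnConfig(hidden_filters=6), seed=0), path)


class TestScheduler:
    def test_lr_halves_only_after_patience_exhausted(self):
        net = TococoNet(TINY, seed=0)
        opt = Adam(net.parameters(), lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=3)
        sched.step(1.0)
        lrs = []
        for _ in range(7):
            sched.step(1.0)  # no improvement
            lrs.append(opt.lr)
        assert lrs == [1.0, 1.0, 0.5, 0.5, 0.5, 0.25, 0.25]

    def test_improvement_resets_patience(self):
        net = TococoNet(TINY, seed=0)
        opt = Adam(net.parameters(), lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2)
        for v in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
            sched.step(v)
        assert opt.lr == 1.0
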