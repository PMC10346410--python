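import numpy as np
import pytest

from branchmorph import model as M
from branchmorph import nn

from conftest import SMALL_UNET, make_training_scenes


class TestSEOps:
    def test_squeeze_of_constant_channels(self):
        u = np.stack([np.full((4, 5), 3.0), np.full((4, 5), -1.5)])
        np.testing.assert_allclose(M.se_squeeze(u), [3.0, -1.5])

    def test_squeeze_hand_sum(self):
        u = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert M.se_squeeze(u)[0] == pytest.approx(2.5)

    def test_squeeze_zero_map(self):
        assert (M.se_squeeze(np.zeros((3, 2, 2))) == 0).all()

    def test_squeeze_rejects_bad_input(self):
        with pytest.raises(ValueError):
            M.se_squeeze(np.zeros((0, 2, 2)))
        with pytest.raises(ValueError):
            M.se_squeeze(np.array([[[np.inf]]]))

    def test_excite_zero_weights_give_half(self):
        s = M.se_excite(np.array([1.0, -2.0]), np.zeros((2, 2)), np.zeros((2, 2)))
        np.testing.assert_allclose(s, [0.5, 0.5])

    def test_excite_identity_weights_zero_input(self):
        s = M.se_excite(np.zeros(2), np.eye(2), np.eye(2))
        np.testing.assert_allclose(s, [0.5, 0.5])

    def test_excite_bounded_open_unit_interval(self, rng):
        # strict bounds hold wherever the sigmoid is not saturated past
        # float precision
        s = M.se_excite(rng.standard_normal(8),
                        rng.standard_normal((4, 8)), rng.standard_normal((8, 4)))
        assert ((s > 0) & (s < 1)).all()

    def test_excite_shape_mismatch(self):
        with pytest.raises(ValueError):
            M.se_excite(np.zeros(3), np.zeros((2, 2)), np.zeros((2, 2)))

    def test_scale_identity_zero_and_linear(self, rng):
        u = rng.standard_normal((3, 4, 4))
        np.testing.assert_array_equal(M.se_scale(u, np.ones(3)), u)
        assert (M.se_scale(u, np.zeros(3)) == 0).all()
        s = np.array([0.5, 1.0, 1.0])
        np.testing.assert_allclose(M.se_scale(u, s)[0], 0.5 * u[0])

    def test_scale_length_mismatch(self):
        with pytest.raises(ValueError):
            M.se_scale(np.zeros((3, 2, 2)), np.ones(4))


class TestRAM:
    def test_variance_pool_of_constant_channel_is_zero(self, rng):
        block = M.RAMBlock(2, 3, rng)
        # pin conv1 so the gated feature map is constant per channel
        block.conv1.weight.value[...] = 0
        block.conv1.bias.value[...] = [2.0, 0.5]
        x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
        block.forward(x)
        _, f, g, _ = block._cache
        assert f.var(axis=(2, 3)).max() == 0.0
        assert ((g > 0) & (g < 1)).all()

    def test_zero_weights_pass_through(self, rng):
        block = M.RAMBlock(3, 3, rng)
        for p in block.parameters():
            p.value[...] = 0
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(block.forward(x), x)

    def test_attention_gate_in_unit_interval(self, rng):
        block = M.RAMBlock(3, 3, rng)
        x = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        block.forward(x)
        g = block._cache[2]
        # sigmoid-gated, so bounded in [0, 1] and strictly inside wherever
        # float32 has not saturated
        assert ((g >= 0) & (g <= 1)).all()
        assert 0 < g.mean() < 1

    def test_rejects_non_finite(self, rng):
        block = M.RAMBlock(1, 3, rng)
        with pytest.raises(ValueError):
            block.forward(np.array([[[[np.nan]]]]))

    def test_ram_forward_single_map(self, rng):
        y = M.ram_forward(rng.standard_normal((2, 8, 8)).astype(np.float32),
                          rng=np.random.default_rng(0))
        assert y.shape == (2, 8, 8)


class TestArchitecture:
    def test_forward_shape_and_softmax_normalization(self):
        net = M.build_model(SMALL_UNET, seed=0)
        x = np.random.default_rng(0).random((1, 3, 64, 64)).astype(np.float32)
        probs = net.forward(x)
        assert probs.shape == (1, 3, 64, 64)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_output_matches_input_for_non_multiple_of_16(self):
        net = M.build_model(SMALL_UNET, seed=0)
        x = np.random.default_rng(0).random((1, 3, 70, 90)).astype(np.float32)
        assert net.forward(x).shape == (1, 3, 70, 90)

    def test_predicted_labels_in_range(self):
        net = M.build_model(SMALL_UNET, seed=1)
        img = np.random.default_rng(1).integers(0, 255, (48, 48, 3), dtype=np.uint8)
        mask = M.predict_mask(net, img)
        assert mask.shape == (48, 48)
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_indivisible_se_reduction_rejected(self):
        with pytest.raises(ValueError):
            M.build_model(M.UNetConfig(base_channels=8, se_reduction=3))

    def test_se_sites_count(self):
        net = M.build_model(SMALL_UNET, seed=0)
        encoder_sites = sum(se is not None for se in net.enc_se)
        decoder_sites = (net.bottleneck_se is not None) + sum(
            se is not None for se in net.dec_se
        )
        assert encoder_sites == 4 and decoder_sites == 5
        assert net.ram is not None

    def test_vgg_backbone_has_thirteen_convs(self):
        net = M.build_model(SMALL_UNET, seed=0)
        assert sum(len(b) for b in net.enc_blocks) == 13
        assert [len(b) for b in net.enc_blocks] == [2, 2, 3, 3, 3]

    def test_se_identity_limit(self):
        """Saturating every SE gate to 1 reproduces the forced-identity
        network output exactly."""
        x = np.random.default_rng(2).random((1, 3, 32, 32)).astype(np.float32)
        net = M.build_model(SMALL_UNET, seed=3)
        ses = [se for se in net.enc_se if se is not None]
        ses += [net.bottleneck_se] + list(net.dec_se)
        for se in ses:
            se.force_identity = True
        ref_out = net.forward(x)
        for se in ses:
            se.force_identity = False
            se.fc2.weight.value[...] = 0
            se.fc2.bias.value[...] = 50.0  # sigmoid(50) rounds to 1 in float32
        np.testing.assert_array_equal(net.forward(x), ref_out)


class TestTraining:
    def test_loss_decreases_when_overfitting(self):
        pairs = make_training_scenes(8, size=64, seed0=100)
        net = M.build_model(SMALL_UNET, seed=0)
        tc = M.TrainConfig(lr0=1e-3, batch_size=4, epochs=30, freeze_epochs=0, seed=0)
        history = M.train(net, pairs, tc)
        assert len(history) == 30
        assert history[-1] < history[0]

    def test_freeze_phase_keeps_encoder_fixed(self):
        pairs = make_training_scenes(2, size=64, seed0=200)
        net = M.build_model(SMALL_UNET, seed=0)
        before = [p.value.copy() for p in net.encoder_parameters()]
        dec_before = net.head.weight.value.copy()
        M.train(net, pairs, M.TrainConfig(lr0=1e-3, batch_size=2, epochs=2,
                                          freeze_epochs=2, seed=0))
        for p, b in zip(net.encoder_parameters(), before):
            np.testing.assert_array_equal(p.value, b)
        assert not np.array_equal(net.head.weight.value, dec_before)

    def test_unfreeze_phase_updates_encoder(self):
        pairs = make_training_scenes(2, size=64, seed0=200)
        net = M.build_model(SMALL_UNET, seed=0)
        before = [p.value.copy() for p in net.encoder_parameters()]
        M.train(net, pairs, M.TrainConfig(lr0=1e-3, batch_size=2, epochs=2,
                                          freeze_epochs=1, seed=0))
        assert any(
            not np.array_equal(p.value, b)
            for p, b in zip(net.encoder_parameters(), before)
        )

    def test_training_is_deterministic(self):
        pairs = make_training_scenes(2, size=64, seed0=300)
        histories = []
        for _ in range(2):
            net = M.build_model(SMALL_UNET, seed=5)
            histories.append(
                M.train(net, pairs, M.TrainConfig(lr0=1e-3, batch_size=1,
                                                  epochs=3, freeze_epochs=0, seed=5))
            )
        assert histories[0] == histories[1]

    def test_cosine_schedule_endpoints(self):
        tc = M.TrainConfig(lr0=1e-4, epochs=300, freeze_epochs=150)
        assert tc.lr_at(0) == pytest.approx(1e-4)
        assert tc.lr_at(150) == pytest.approx(0.5e-4)
        assert tc.lr_at(300) == pytest.approx(0.0, abs=1e-20)

    def test_invalid_inputs_rejected(self):
        net = M.build_model(SMALL_UNET, seed=0)
        with pytest.raises(ValueError):
            M.train(net, [])
        img = np.zeros((64, 64, 3), np.uint8)
        with pytest.raises(ValueError):
            M.train(net, [(img, np.full((64, 64), 7))])
        with pytest.raises(ValueError):
            M.TrainConfig(epochs=10, freeze_epochs=20)


class TestInference:
    def test_batch_order_preserved(self):
        net = M.build_model(SMALL_UNET, seed=0)
        rng = np.random.default_rng(0)
        imgs = rng.integers(0, 255, (3, 48, 48, 3), dtype=np.uint8)
        batch = M.predict_mask(net, imgs)
        singles = np.stack([M.predict_mask(net, im) for im in imgs])
        np.testing.assert_array_equal(batch, singles)

    def test_wrong_channel_count_rejected(self):
        net = M.build_model(SMALL_UNET, seed=0)
        with pytest.raises(ValueError):
            M.predict_mask(net, np.zeros((32, 32, 1), np.uint8))

    def test_checkpoint_roundtrip(self, tmp_path):
        net = M.build_model(SMALL_UNET, seed=4)
        img = np.random.default_rng(0).integers(0, 255, (48, 48, 3), dtype=np.uint8)
        ref_mask = M.predict_mask(net, img)
        path = tmp_path / "weights.npz"
        M.save_checkpoint(net, path)
        loaded = M.load_checkpoint(path)
        np.testing.assert_array_equal(M.predict_mask(loaded, img), ref_mask)
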