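import numpy as np
import pytest

from kernelct import CTVolume, LabelVolume, NetworkConfig, build_model, predict_volume
from kernelct.csftu_net import CBAM, ChannelAttention, SEBlock, SpatialAttention, predict_slices
from kernelct.nn import Tensor, no_grad

from oracles import channelwise_mean_max_oracle, spatial_max_oracle, spatial_mean_oracle

RNG_SEED = 99


def _rng():
    return np.random.default_rng(RNG_SEED)


class TestNetworkConfig:
    def test_filter_doubling_and_cap(self):
        cfg = NetworkConfig()
        assert cfg.filters_per_level == [64, 128, 256, 512, 1024]
        capped = NetworkConfig(cap_filters=512)
        assert capped.filters_per_level == [64, 128, 256, 512, 512]

    def test_five_levels_mean_four_downsamplings(self):
        assert NetworkConfig(levels=5).downsample_factor == 16

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError, match="does not divide"):
            NetworkConfig(base_filters=24, cbam_reduction_r=16)

    def test_spatial_kernel_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            NetworkConfig(spatial_kernel=6)


class TestChannelAttention:
    def test_pooling_matches_brute_force(self):
        f = _rng().normal(0, 1, (1, 4, 5, 6)).astype(np.float32)
        t = Tensor(f)
        avg = t.mean(axis=(2, 3)).numpy()[0]
        mx = t.max(axis=3).max(axis=2).numpy()[0]
        np.testing.assert_allclose(avg, spatial_mean_oracle(f[0].tolist()), rtol=1e-5)
        np.testing.assert_allclose(mx, spatial_max_oracle(f[0].tolist()), rtol=1e-5)

    def test_constant_map_makes_avg_equal_max(self):
        block = ChannelAttention(4, r=2, rng=_rng())
        f = np.broadcast_to(np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1), (1, 4, 3, 3)).copy()
        with no_grad():
            weights = block(Tensor(f)).numpy()
        # avg == max, so Mc = sigmoid(2*MLP(pool))
        pooled = Tensor(f).mean(axis=(2, 3))
        with no_grad():
            expected = (block.fc2(block.fc1(pooled).relu()) * 2.0).sigmoid().numpy()
        np.testing.assert_allclose(weights, expected, rtol=1e-5)

    def test_zero_input_zero_bias_gives_half(self):
        block = ChannelAttention(8, r=4, rng=_rng())
        with no_grad():
            w = block(Tensor(np.zeros((1, 8, 5, 5), dtype=np.float32))).numpy()
        np.testing.assert_array_equal(w, np.full((1, 8), 0.5))

    def test_weights_in_open_unit_interval(self):
        # moderate feature scale: float32 sigmoid saturates to exactly 0/1
        # for very large magnitudes, so probe the regime BN-normalized
        # features actually occupy
        block = ChannelAttention(8, r=4, rng=_rng())
        f = _rng().normal(0, 1, (2, 8, 6, 6)).astype(np.float32)
        with no_grad():
            w = block(Tensor(f)).numpy()
        assert (w > 0).all() and (w < 1).all()


class TestSpatialAttention:
    def test_channel_reduction_matches_brute_force(self):
        f = _rng().normal(0, 1, (1, 3, 4, 4)).astype(np.float32)
        t = Tensor(f)
        mean, mx = channelwise_mean_max_oracle(f[0].tolist())
        np.testing.assert_allclose(t.mean(axis=1).numpy()[0], mean, rtol=1e-5)
        np.testing.assert_allclose(t.max(axis=1).numpy()[0], mx, rtol=1e-5)

    def test_single_channel_mean_equals_max(self):
        f = _rng().normal(0, 1, (1, 1, 5, 5)).astype(np.float32)
        t = Tensor(f)
        np.testing.assert_allclose(t.mean(axis=1).numpy(), t.max(axis=1).numpy())

    def test_zero_input_zero_bias_gives_half_everywhere(self):
        block = SpatialAttention(7, rng=_rng())
        with no_grad():
            w = block(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))).numpy()
        np.testing.assert_array_equal(w, np.full((1, 1, 8, 8), 0.5))

    def test_weights_in_open_unit_interval(self):
        block = SpatialAttention(7, rng=_rng())
        f = _rng().normal(0, 3, (1, 4, 8, 8)).astype(np.float32)
        with no_grad():
            w = block(Tensor(f)).numpy()
        assert (w > 0).all() and (w < 1).all()


class TestCBAM:
    def test_matches_two_loop_reimplementation(self):
        block = CBAM(2, r=2, spatial_kernel=3, rng=_rng())
        f = _rng().normal(0, 1, (1, 2, 4, 4)).astype(np.float32)
        with no_grad():
            out = block(Tensor(f)).numpy()
            mc = block.channel(Tensor(f)).numpy()[0]
            fw = f * mc.reshape(1, 2, 1, 1)
            ms = block.spatial(Tensor(fw.astype(np.float32))).numpy()[0, 0]
        expected = np.empty_like(f)
        for c in range(2):          # literal elementwise Eq-style product
            for i in range(4):
                for j in range(4):
                    expected[0, c, i, j] = f[0, c, i, j] * mc[c] * ms[i, j]
        np.testing.assert_allclose(out, expected, rtol=1e-5)

    def test_saturated_attention_is_identity(self):
        block = CBAM(2, r=2, spatial_kernel=3, rng=_rng())
        # force both attentions to saturate at ~1 with huge positive biases
        block.channel.fc2.bias.data[:] = 1e3
        block.spatial.conv.bias.data[:] = 1e3
        f = _rng().normal(0, 1, (1, 2, 4, 4)).astype(np.float32)
        with no_grad():
            np.testing.assert_allclose(block(Tensor(f)).numpy(), f, rtol=1e-5)

    def test_contraction_on_nonnegative_input(self):
        block = CBAM(4, r=2, spatial_kernel=3, rng=_rng())
        f = np.abs(_rng().normal(0, 1, (1, 4, 5, 5))).astype(np.float32)
        with no_grad():
            out = block(Tensor(f)).numpy()
        assert (out <= f + 1e-7).all() and out.shape == f.shape


class TestSEBlock:
    def test_squeeze_matches_brute_force_mean(self):
        f = _rng().normal(0, 1, (1, 3, 5, 5)).astype(np.float32)
        z = Tensor(f).mean(axis=(2, 3)).numpy()[0]
        np.testing.assert_allclose(z, spatial_mean_oracle(f[0].tolist()), rtol=1e-5)

    def test_constant_channel_squeezes_to_its_value(self):
        f = np.full((1, 2, 4, 4), 7.0, dtype=np.float32)
        np.testing.assert_allclose(Tensor(f).mean(axis=(2, 3)).numpy(), [[7.0, 7.0]])

    def test_zero_input_zero_bias_halves_then_zeroes(self):
        block = SEBlock(4, r=2, rng=_rng())
        zero = np.zeros((1, 4, 3, 3), dtype=np.float32)
        with no_grad():
            s = block.fc2(block.fc1(Tensor(np.zeros((1, 4), dtype=np.float32))).relu()).sigmoid()
            out = block(Tensor(zero)).numpy()
        np.testing.assert_array_equal(s.numpy(), np.full((1, 4), 0.5))
        np.testing.assert_array_equal(out, zero)

    def test_shape_preserved_and_gate_in_unit_interval(self):
        block = SEBlock(4, r=2, rng=_rng())
        f = _rng().normal(0, 2, (2, 4, 6, 7)).astype(np.float32)
        with no_grad():
            out = block(Tensor(f)).numpy()
        assert out.shape == f.shape
        ratio = out[f != 0] / f[f != 0]
        assert (ratio > 0).all() and (ratio < 1).all()


class TestBuiltModel:
    def test_standard_input_maps_to_three_class_logits(self):
        model = build_model(NetworkConfig(levels=3, base_filters=8, seed=0, cbam_reduction_r=4, se_reduction_r=4)).eval()
        with no_grad():
            out = model(Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert out.shape == (1, 3, 64, 64)

    def test_indivisible_input_rejected_with_clear_message(self):
        model = build_model(NetworkConfig(levels=3, base_filters=8, seed=0, cbam_reduction_r=4, se_reduction_r=4))
        with pytest.raises(ValueError, match="divisible by 4"):
            model(Tensor(np.zeros((1, 1, 50, 50), dtype=np.float32)))

    def test_same_seed_builds_identical_parameters(self):
        cfg = dict(levels=3, base_filters=8, seed=5, cbam_reduction_r=4, se_reduction_r=4)
        a = build_model(NetworkConfig(**cfg))
        b = build_model(NetworkConfig(**cfg))
        assert a.parameter_checksum() == b.parameter_checksum()
        c = build_model(NetworkConfig(levels=3, base_filters=8, seed=6, cbam_reduction_r=4, se_reduction_r=4))
        assert a.parameter_checksum() != c.parameter_checksum()

    def test_ablation_flags_remove_attention_blocks(self):
        from kernelct.csftu_net import _Identity
        plain = build_model(NetworkConfig(levels=3, base_filters=8, seed=0, cbam_reduction_r=4,
                                          se_reduction_r=4, use_cbam=False, use_se=False))
        assert not any(isinstance(m, (CBAM, SEBlock)) for m in plain.modules())
        assert any(isinstance(m, _Identity) for m in plain.modules())
        full = build_model(NetworkConfig(levels=3, base_filters=8, seed=0, cbam_reduction_r=4, se_reduction_r=4))
        assert any(isinstance(m, CBAM) for m in full.modules())
        assert any(isinstance(m, SEBlock) for m in full.modules())


class TestPredictVolume:
    @pytest.fixture(scope="class")
    @staticmethod
    def model():
        return build_model(NetworkConfig(levels=3, base_filters=8, seed=1, cbam_reduction_r=4, se_reduction_r=4)).eval()

    def test_slice_count_and_geometry_preserved(self, model):
        vol = CTVolume(np.random.default_rng(0).integers(0, 256, (4, 64, 64)).astype(np.uint8))
        labels = predict_volume(model, vol)
        assert isinstance(labels, LabelVolume)
        assert labels.shape == (4, 64, 64)

    def test_outputs_are_class_codes(self, model):
        vol = CTVolume(np.random.default_rng(1).integers(0, 256, (2, 64, 64)).astype(np.uint8))
        labels = predict_volume(model, vol)
        assert set(np.unique(labels.data)) <= {0, 1, 2}

    def test_argmax_agrees_with_brute_force_over_logits(self, model):
        img = np.random.default_rng(2).random((1, 64, 64), dtype=np.float32)
        pred = predict_slices(model, img)
        with no_grad():
            logits = model(Tensor(img[:, None])).numpy()[0]
        for i in range(0, 64, 7):       # sample of positions, explicit 3-way max
            for j in range(0, 64, 7):
                best, arg = -np.inf, -1
                for k in range(3):
                    if logits[k, i, j] > best:
                        best, arg = logits[k, i, j], k
                assert pred[0, i, j] == arg

    def test_inference_deterministic(self, model):
        img = np.random.default_rng(3).random((2, 64, 64), dtype=np.float32)
        np.testing.assert_array_equal(predict_slices(model, img), predict_slices(model, img))
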