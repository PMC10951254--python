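"""SE-RegUNet architecture: encoder pyramid, SE gating, decoder, heads."""
import numpy as np
import pytest

import angioseg as ag
from angioseg import nn
from angioseg.architecture import ConfigError, DecodeBlock
from angioseg.nn import functional as F


class TestRegNetDesignSpace:
    def test_quantized_linear_rule_reproduces_regnety_16gf(self):
        widths, depths = ag.generate_regnet_widths(106.23, 200, 2.48, 18,
                                                   group_width=112)
        assert widths == [224, 448, 1232, 3024]
        assert depths == [2, 4, 11, 1]

    def test_encoder_spec_registered(self):
        spec = ag.ENCODER_SPECS["regnety_16gf"]
        assert spec.widths == (224, 448, 1232, 3024)
        assert spec.group_width == 112

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ag.generate_regnet_widths(-1.0, 24, 2.0, 10)


class TestEncoder:
    def test_pyramid_strides_and_halving(self, tiny_seg_config):
        enc = ag.build_encoder(tiny_seg_config)
        x = nn.Tensor(np.random.default_rng(0).random((1, 3, 64, 64), np.float32))
        with nn.no_grad():
            feats = enc(x)
        sizes = [f.shape[2] for f in feats]
        assert sizes == [32, 16, 8, 4, 2]        # strides 2,4,8,16,32
        with nn.no_grad():
            feats2 = enc(nn.Tensor(np.zeros((1, 3, 128, 128), np.float32)))
        assert [f.shape[2] for f in feats2] == [2 * s for s in sizes]

    def test_deepest_map_is_input_over_32_for_4gf(self):
        enc = ag.build_encoder(ag.SegModelConfig(backbone="regnetz_4gf"))
        probe = F.Probe((1, 3, 512, 512))
        feats = enc(probe)
        assert feats[-1].shape == (1, ag.ENCODER_SPECS["regnetz_4gf"].widths[-1], 16, 16)

    def test_unknown_backbone_raises(self):
        with pytest.raises(ConfigError):
            ag.build_encoder(ag.SegModelConfig(backbone="resnet50"))


class TestSEBlock:
    def test_zero_input_gives_zero_output(self):
        se = ag.se_block(8, reduction=4, rng=np.random.default_rng(0))
        out = se(nn.Tensor(np.zeros((2, 8, 4, 4), np.float32)))
        assert np.all(out.numpy() == 0)

    def test_gates_strictly_inside_unit_interval(self, rng):
        se = ag.se_block(8, reduction=4, rng=rng)
        x = np.abs(rng.normal(size=(1, 8, 4, 4))).astype(np.float32)
        out = se(nn.Tensor(x)).numpy()
        gates = out.sum(axis=(2, 3)) / x.sum(axis=(2, 3))
        assert np.all(gates > 0) and np.all(gates < 1)

    def test_hand_computed_four_channel_chain(self):
        se = ag.se_block(4, reduction=2, rng=np.random.default_rng(0))
        w1 = np.array([[0.1, -0.2, 0.3, 0.0], [0.0, 0.5, -0.1, 0.2]], np.float32)
        w2 = np.array([[0.4, -0.3], [0.2, 0.1], [-0.5, 0.6], [0.3, 0.3]], np.float32)
        se.fc1.weight.data, se.fc2.weight.data = w1, w2
        se.fc1.bias.data[:] = 0
        se.fc2.bias.data[:] = 0
        x = np.arange(16, dtype=np.float32).reshape(1, 4, 2, 2)
        out = se(nn.Tensor(x)).numpy()
        pooled = x.mean(axis=(2, 3))[0]
        h = np.maximum(w1 @ pooled, 0)
        gate = 1 / (1 + np.exp(-(w2 @ h)))
        expected = x * gate.reshape(1, 4, 1, 1)
        np.testing.assert_allclose(out, expected, rtol=1e-5)


class TestDecodeBlock:
    def _block(self):
        return DecodeBlock(8, 4, 6, se_reduction=2, rng=np.random.default_rng(1))

    def test_output_shape_contract(self):
        blk = self._block()
        x = nn.Tensor(np.random.default_rng(0).random((1, 8, 4, 4), np.float32))
        skip = nn.Tensor(np.random.default_rng(1).random((1, 4, 8, 8), np.float32))
        with nn.no_grad():
            out = blk(x, skip)
        assert out.shape == (1, 6, 8, 8)

    def test_mismatched_spatial_dims_raise(self):
        blk = self._block()
        x = nn.Tensor(np.zeros((1, 8, 4, 4), np.float32))
        skip = nn.Tensor(np.zeros((1, 4, 9, 9), np.float32))
        with pytest.raises(ValueError, match="decode_block"):
            blk(x, skip)

    def test_gradient_reaches_both_inputs(self):
        blk = self._block()
        rng = np.random.default_rng(2)
        x = nn.Tensor(rng.random((1, 8, 4, 4)).astype(np.float32), requires_grad=True)
        skip = nn.Tensor(rng.random((1, 4, 8, 8)).astype(np.float32), requires_grad=True)
        blk(x, skip).sum().backward()
        assert x.grad is not None and np.any(x.grad != 0)
        assert skip.grad is not None and np.any(skip.grad != 0)

    def test_gate_to_one_limit_recovers_plain_unet_block(self):
        blk = self._block()
        blk.se.fc2.bias.data[:] = 1e6      # sigmoid -> 1: SE becomes identity
        rng = np.random.default_rng(3)
        x = nn.Tensor(rng.random((1, 8, 4, 4)).astype(np.float32))
        skip = nn.Tensor(rng.random((1, 4, 8, 8)).astype(np.float32))
        blk.eval()
        with nn.no_grad():
            gated = blk(x, skip).numpy()
            up = F.upsample_bilinear2x(x)
            plain = blk.conv2(blk.conv1(nn.concat([up, skip], axis=1))).numpy()
        np.testing.assert_allclose(gated, plain, rtol=1e-5)


class TestFullModels:
    def test_softmax_simplex_everywhere(self, tiny_seg_config, rng):
        model = ag.build_se_regunet(tiny_seg_config)
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        with nn.no_grad():
            p = model(nn.Tensor(x)).numpy()
        assert p.shape == (2, 2, 64, 64)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert p.min() >= 0

    def test_indivisible_input_raises_named_constraint(self, tiny_seg_config):
        model = ag.build_se_regunet(tiny_seg_config)
        with pytest.raises(ValueError, match="divisible by 32"):
            model(nn.Tensor(np.zeros((1, 3, 60, 60), np.float32)))

    def test_classifier_probability_and_eval_determinism(self, rng):
        clf = ag.build_classifier(ag.SegModelConfig(backbone="tiny_z"))
        clf.eval()
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        with nn.no_grad():
            p1 = clf(nn.Tensor(x)).numpy().item()
            p2 = clf(nn.Tensor(x)).numpy().item()
        assert 0.0 <= p1 <= 1.0 and p1 == p2


class TestComplexityProfile:
    def test_flops_scale_with_area_params_do_not(self, tiny_seg_config):
        model = ag.build_se_regunet(tiny_seg_config)
        r64 = ag.profile_complexity(model, 64)
        r128 = ag.profile_complexity(model, 128)
        assert r64.trainable_parameters == r128.trainable_parameters
        ratio = r128.flops / r64.flops
        assert 3.9 < ratio < 4.1      # conv trunk dominates; SE FCs are constant

    def test_probe_macs_equal_instrumented_conv_arithmetic(self):
        # two stacked convs: closed-form MAC total
        m = nn.Sequential(nn.Conv2d(3, 5, 3, padding=1, bias=False),
                          nn.Conv2d(5, 2, 1, bias=False))
        rep = ag.profile_complexity(m, 16, in_channels=3)
        assert rep.trainable_parameters == 3 * 5 * 9 + 5 * 2
        assert rep.flops == 3 * 5 * 9 * 256 + 5 * 2 * 256
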