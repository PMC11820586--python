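"""Network blocks against scalar-loop oracles, plus architecture contracts."""

import numpy as np
import pytest

from fecgnet.nn.autograd import Tensor
from fecgnet.r2wnet import (
    AttentionGate,
    AttentionR2WNet,
    NetworkConfig,
    RRCBlock,
    count_parameters,
    fuse_subtract_tanh,
    load_checkpoint,
    save_checkpoint,
)
from conftest import attention_gate_naive, rrc_naive

TINY = NetworkConfig(depth=3, width_multiplier=1 / 16)


def _zeroed(block: RRCBlock) -> RRCBlock:
    for p in block.parameters():
        p.data[:] = 0.0
    return block


class TestRRCBlock:
    def test_zero_weights_is_identity(self, rng):
        block = _zeroed(RRCBlock(4, 4, 3, T=2, rng=rng, activation="relu"))
        x = rng.normal(size=(2, 4, 16))
        np.testing.assert_array_equal(block(Tensor(x)).data, x)

    def test_t0_reduces_to_plain_residual_conv(self, rng):
        block = RRCBlock(3, 3, 3, T=2, rng=rng, activation="relu")
        x = Tensor(rng.normal(size=(1, 3, 12)))
        manual = block._residual_input(x).data + block.act(
            block.conv_f(x)).data
        np.testing.assert_allclose(block(x, T=0).data, manual, atol=1e-12)

    @pytest.mark.parametrize("T", [1, 2, 3])
    def test_matches_scalar_loop_oracle(self, rng, T):
        """Unrolled recurrence equals an element-by-element re-computation."""
        C, L = 3, 14
        block = RRCBlock(C, C, 3, T=T, rng=rng, activation="relu")
        x = rng.normal(size=(1, C, L))
        expected = rrc_naive(
            x[0],
            block.conv_f.weight.data, block.conv_f.bias.data,
            block.conv_r.weight.data, block.conv_r.bias.data,
            T, lambda v: np.maximum(v, 0.0))
        np.testing.assert_allclose(block(Tensor(x)).data[0], expected,
                                   atol=1e-6)

    def test_channel_projection_applied_when_needed(self, rng):
        block = RRCBlock(2, 5, 3, T=1, rng=rng)
        out = block(Tensor(rng.normal(size=(1, 2, 8))))
        assert out.shape == (1, 5, 8)
        assert block.proj is not None

    def test_unknown_block_type_rejected(self, rng):
        with pytest.raises(ValueError, match="block type"):
            RRCBlock(2, 2, 3, T=1, rng=rng, block_type="dense")


class TestAttentionGate:
    def test_matches_scalar_loop_oracle(self, rng):
        C, L = 4, 16
        gate = AttentionGate(C, C, rng)
        u = rng.normal(size=(1, C, L))
        g = rng.normal(size=(1, C, L))
        expected = attention_gate_naive(
            u[0], g[0],
            gate.w_u.weight.data, gate.w_g.weight.data, gate.w_g.bias.data,
            gate.psi.weight.data, gate.psi.bias.data)
        np.testing.assert_allclose(gate(Tensor(u), Tensor(g)).data[0],
                                   expected, atol=1e-6)

    def test_gate_closes_in_negative_sigmoid_limit(self, rng):
        gate = AttentionGate(3, 3, rng)
        gate.psi.bias.data[:] = -50.0
        u = Tensor(rng.normal(size=(1, 3, 8)))
        out = gate(u, Tensor(rng.normal(size=(1, 3, 8))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_gate_opens_in_positive_sigmoid_limit(self, rng):
        gate = AttentionGate(3, 3, rng)
        gate.psi.bias.data[:] = 50.0
        u_arr = rng.normal(size=(1, 3, 8))
        out = gate(Tensor(u_arr), Tensor(rng.normal(size=(1, 3, 8))))
        np.testing.assert_allclose(out.data, u_arr, atol=1e-9)

    def test_coefficients_bounded(self, rng):
        gate = AttentionGate(4, 4, rng)
        alpha = gate.coefficients(Tensor(10 * rng.normal(size=(2, 4, 16))),
                                  Tensor(10 * rng.normal(size=(2, 4, 16))))
        assert np.all(alpha >= 0.0) and np.all(alpha <= 1.0)

    def test_length_mismatch_rejected(self, rng):
        gate = AttentionGate(2, 2, rng)
        with pytest.raises(ValueError, match="length"):
            gate(Tensor(np.zeros((1, 2, 8))), Tensor(np.zeros((1, 2, 4))))


class TestFusion:
    def test_identical_features_fuse_to_zero(self, rng):
        f = [Tensor(rng.normal(size=(1, 4, 8)))]
        fused = fuse_subtract_tanh(f, f, fusion_levels=[0])
        np.testing.assert_array_equal(fused[0].data, 0.0)

    def test_zero_maternal_gives_tanh_of_fetal(self, rng):
        x = rng.normal(size=(1, 4, 8))
        fused = fuse_subtract_tanh([Tensor(x)], [Tensor(np.zeros_like(x))], [0])
        np.testing.assert_allclose(fused[0].data, np.tanh(x), atol=1e-12)

    def test_fused_levels_bounded_by_tanh(self, rng):
        f = [Tensor(3 * rng.normal(size=(1, 2, 8)))]
        m = [Tensor(3 * rng.normal(size=(1, 2, 8)))]
        fused = fuse_subtract_tanh(f, m, [0])
        assert np.abs(fused[0].data).max() < 1.0

    def test_non_fused_levels_pass_through(self, rng):
        f = [Tensor(rng.normal(size=(1, 2, 8))) for _ in range(2)]
        m = [Tensor(rng.normal(size=(1, 2, 8))) for _ in range(2)]
        fused = fuse_subtract_tanh(f, m, fusion_levels=[1])
        assert fused[0] is f[0]


class TestArchitecture:
    def test_encoder_level_shapes(self):
        model = AttentionR2WNet(NetworkConfig(width_multiplier=1 / 8), seed=0)
        feats = model.enc_fetal(Tensor(np.zeros((1, 1, 1024))))
        assert [f.shape for f in feats] == [
            (1, 8, 1024), (1, 16, 512), (1, 32, 256), (1, 64, 128),
            (1, 128, 64)]

    def test_width_multiplier_scales_channels(self):
        cfg = NetworkConfig(width_multiplier=1 / 8)
        assert cfg.resolved_channels() == (8, 16, 32, 64, 128)

    def test_forward_preserves_shape_and_is_deterministic(self, rng):
        model = AttentionR2WNet(TINY, seed=7)
        x = rng.normal(size=(2, 1024))
        f1, m1 = model.forward(x)
        f2, m2 = model.forward(x)
        assert f1.shape == m1.shape == (2, 1, 1024)
        np.testing.assert_array_equal(f1.data, f2.data)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_fully_convolutional_in_time(self, rng):
        model = AttentionR2WNet(TINY, seed=7)
        f, m = model.forward(rng.normal(size=(1, 2048)))
        assert f.shape == (1, 1, 2048)

    def test_bad_length_rejected(self):
        model = AttentionR2WNet(TINY, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1022)))

    def test_all_parameters_receive_gradient(self, rng):
        """No dead subgraph: every parameter gets a nonzero gradient."""
        model = AttentionR2WNet(TINY, seed=1)
        f, m = model.forward(rng.normal(size=(2, 1024)))
        tgt = rng.normal(size=(2, 1, 1024))
        loss = (f - Tensor(tgt)).abs().mean() + (m - Tensor(tgt)).abs().mean()
        loss.backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_fusion_feeds_encoder_wiring_runs(self, rng):
        cfg = NetworkConfig(depth=3, width_multiplier=1 / 16,
                            fusion_feeds_encoder=True)
        f, m = AttentionR2WNet(cfg, seed=0).forward(rng.normal(size=(1, 1024)))
        assert f.shape == (1, 1, 1024)


class TestParameterCount:
    def test_same_config_same_count(self):
        a = count_parameters(AttentionR2WNet(TINY, seed=0))
        b = count_parameters(AttentionR2WNet(TINY, seed=99))
        assert a == b

    def test_width_monotonicity(self):
        wide = count_parameters(AttentionR2WNet(
            NetworkConfig(depth=3, width_multiplier=1 / 8), seed=0))
        narrow = count_parameters(AttentionR2WNet(TINY, seed=0))
        assert narrow < wide

    def test_depth_monotonicity(self):
        d4 = count_parameters(AttentionR2WNet(
            NetworkConfig(depth=4, width_multiplier=1 / 16), seed=0))
        d5 = count_parameters(AttentionR2WNet(
            NetworkConfig(depth=5, width_multiplier=1 / 16), seed=0))
        assert d4 < d5


class TestCheckpoints:
    def test_round_trip(self, tmp_path, rng):
        model = AttentionR2WNet(TINY, seed=3)
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        x = rng.normal(size=(1, 1024))
        np.testing.assert_array_equal(model.forward(x)[0].data,
                                      loaded.forward(x)[0].data)

    def test_architecture_mismatch_detected(self, tmp_path):
        model = AttentionR2WNet(TINY, seed=3)
        d = save_checkpoint(model, tmp_path / "ckpt")
        other = NetworkConfig(depth=4, width_multiplier=1 / 16)
        import json
        from dataclasses import asdict
        (d / "config.json").write_text(json.dumps(asdict(other)))
        with pytest.raises(ValueError, match="mismatch"):
            load_checkpoint(d)
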