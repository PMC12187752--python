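import math

import numpy as np
import pytest

from kcrnet.network import (
    BatchNorm1d,
    ChannelAttention,
    Conv1d,
    DenseBlock,
    KcrModel,
    ModelConfig,
    Transition,
    stage_shapes,
    summarize,
)


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def scalar_attention_oracle(f, att):
    """Per-channel scalar recomputation of the attention weights with explicit
    loops, independent of the vectorized implementation."""
    N, C, L = f.shape
    w1, b1 = att.w1.value, att.b1.value
    w2, b2 = att.w2.value, att.b2.value
    H = w1.shape[0]
    mc = np.zeros((N, C))
    mr = np.zeros((N, C))
    for n in range(N):
        avg = [sum(f[n, c, l] for l in range(L)) / L for c in range(C)]
        mx = [max(f[n, c, l] for l in range(L)) for c in range(C)]

        def fnn(v):
            h = [max(0.0, sum(w1[j, c] * v[c] for c in range(C)) + b1[j]) for j in range(H)]
            return [sum(w2[c, j] * h[j] for j in range(H)) + b2[c] for c in range(C)]

        fa, fm = fnn(avg), fnn(mx)
        for c in range(C):
            mc[n, c] = _sigmoid(fa[c] + fm[c])
            mr[n, c] = _sigmoid(avg[c] + mx[c])
    mrc = mc + mr if att.residual else mc
    if not att.residual:
        mr = np.zeros_like(mc)
    return mc, mr, mrc


class TestDenseBlock:
    def test_channel_arithmetic(self):
        rng = np.random.default_rng(0)
        blk = DenseBlock(80, 2, 32, 3, np.random.default_rng(0))
        x = rng.standard_normal((2, 80, 29))
        y = blk.forward(x, train=True)
        assert y.shape == (2, 144, 29)  # 80 + 2*32, length unchanged

    def test_zero_layers_is_identity(self):
        blk = DenseBlock(5, 0, 3, 3, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, 5, 7))
        assert np.array_equal(blk.forward(x, train=True), x)

    def test_matches_hand_composed_layers(self):
        """Layer-by-layer oracle: recompute BN->ReLU->Conv + concat with the
        same weights outside the DenseBlock class."""
        rng = np.random.default_rng(3)
        blk = DenseBlock(8, 2, 4, 3, np.random.default_rng(42))
        x = rng.standard_normal((2, 8, 10))
        y = blk.forward(x, train=False)

        feats = [x]
        for bn, _, conv in blk.layers:
            h = np.concatenate(feats, axis=1)
            inv = 1.0 / np.sqrt(bn.running_var + bn.eps)
            hn = bn.gamma.value[None, :, None] * (h - bn.running_mean[None, :, None]) \
                * inv[None, :, None] + bn.beta.value[None, :, None]
            hr = np.maximum(hn, 0.0)
            # direct convolution sum
            k = conv.kernel_size
            pad = k // 2
            hp = np.pad(hr, ((0, 0), (0, 0), (pad, pad)))
            N, C, L = hr.shape
            co = conv.weight.value.shape[0]
            out = np.zeros((N, co, L))
            for n in range(N):
                for o in range(co):
                    for l in range(L):
                        out[n, o, l] = conv.bias.value[o] + np.sum(
                            conv.weight.value[o] * hp[n, :, l : l + k]
                        )
            feats.append(out)
        oracle = np.concatenate(feats, axis=1)
        assert np.allclose(y, oracle, atol=1e-10)

    def test_growth_rate_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(growth_rate=0)


class TestTransition:
    def test_compression_and_length(self):
        tr = Transition(144, 0.5, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, 144, 29))
        y = tr.forward(x, train=True)
        assert y.shape == (2, 72, 14)

    def test_compression_one_preserves_channels(self):
        tr = Transition(10, 1.0, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, 10, 8))
        assert tr.forward(x, train=True).shape == (2, 10, 4)

    def test_constant_preserved_with_identity_weights(self):
        """With BN set to identity (running stats 0/1 in eval mode) and the
        1x1 conv set to the identity map, pooling a constant gives the same
        constant."""
        tr = Transition(3, 1.0, np.random.default_rng(0))
        tr.conv.weight.value[...] = np.eye(3)[:, :, None]
        tr.conv.bias.value[...] = 0.0
        x = np.full((2, 3, 6), 1.75)
        y = tr.forward(x, train=False)
        assert np.allclose(y, 1.75)

    def test_length_below_two_rejected(self):
        tr = Transition(3, 1.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            tr.forward(np.zeros((2, 3, 1)), train=False)


class TestChannelAttention:
    def test_zero_input_zero_fnn_gives_half_half_one(self):
        att = ChannelAttention(4, 2, np.random.default_rng(0), residual=True)
        for p in att.parameters():
            p.value[...] = 0.0
        mc, mr, mrc = att.weights_of(np.zeros((3, 4, 8)))
        assert np.allclose(mc, 0.5) and np.allclose(mr, 0.5) and np.allclose(mrc, 1.0)

    def test_rcam_weight_ranges(self):
        att = ChannelAttention(6, 2, np.random.default_rng(1), residual=True)
        f = np.random.default_rng(2).standard_normal((4, 6, 9)) * 3
        mc, mr, mrc = att.weights_of(f)
        assert np.all((mc > 0) & (mc < 1))
        assert np.all((mr > 0) & (mr < 1))
        assert np.all((mrc > 0) & (mrc < 2))

    def test_rcam_matches_scalar_oracle(self):
        att = ChannelAttention(4, 2, np.random.default_rng(5), residual=True)
        f = np.random.default_rng(6).standard_normal((3, 4, 8))
        mc, mr, mrc = att.weights_of(f)
        omc, omr, omrc = scalar_attention_oracle(f, att)
        assert np.allclose(mc, omc, atol=1e-6)
        assert np.allclose(mr, omr, atol=1e-6)
        assert np.allclose(mrc, omrc, atol=1e-6)

    def test_forward_scales_channels(self):
        att = ChannelAttention(4, 2, np.random.default_rng(5), residual=True)
        f = np.random.default_rng(6).standard_normal((2, 4, 5))
        y = att.forward(f)
        _, _, mrc = att.weights_of(f)
        assert np.allclose(y, mrc[:, :, None] * f)
        assert y.shape == f.shape

    def test_zero_input_maps_to_zero_output(self):
        att = ChannelAttention(4, 2, np.random.default_rng(0), residual=True)
        assert np.allclose(att.forward(np.zeros((2, 4, 6))), 0.0)

    def test_cam_is_rcam_without_residual_term(self):
        """On identical weights and input, CAM's weights equal RCAM's mc."""
        rng_init = np.random.default_rng(9)
        rcam = ChannelAttention(4, 2, rng_init, residual=True)
        cam = ChannelAttention(4, 2, np.random.default_rng(0), residual=False)
        for pc, pr in zip(cam.parameters(), rcam.parameters()):
            pc.value[...] = pr.value
        f = np.random.default_rng(10).standard_normal((3, 4, 7))
        mc_r, mr_r, mrc_r = rcam.weights_of(f)
        mc_c, mr_c, mrc_c = cam.weights_of(f)
        assert np.allclose(mc_c, mc_r)
        assert np.allclose(mr_c, 0.0)
        assert np.allclose(mrc_c, mrc_r - mr_r)
        assert np.all((mrc_c > 0) & (mrc_c < 1))

    def test_bottleneck_too_narrow(self):
        with pytest.raises(ValueError):
            ChannelAttention(4, 8, np.random.default_rng(0))


class TestModelForward:
    def test_softmax_rows_sum_to_one(self):
        model = KcrModel(ModelConfig(), seed=0)
        x = np.random.default_rng(0).standard_normal((2, 80, 29))
        p = model.forward(x)
        assert p.shape == (2, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p > 0) & (p < 1))

    def test_eval_mode_deterministic(self):
        model = KcrModel(ModelConfig(), seed=0)
        x = np.random.default_rng(0).standard_normal((3, 80, 29))
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_attention_variants_share_backbone(self):
        """Same seed => identical dense/transition stages; only the attention
        stage (and what follows) differs."""
        cfg_none = ModelConfig(attention="none")
        cfg_rcam = ModelConfig(attention="rcam")
        m0 = KcrModel(cfg_none, seed=4)
        m1 = KcrModel(cfg_rcam, seed=4)
        x = np.random.default_rng(5).standard_normal((2, 80, 29))

        def backbone(model):
            h = x
            for b, blk in enumerate(model.blocks):
                h = blk.forward(h, False)
                if b < len(model.transitions):
                    h = model.transitions[b].forward(h, False)
            return h

        h0, h1 = backbone(m0), backbone(m1)
        assert np.array_equal(h0, h1)
        assert not np.allclose(h1, m1.attention.forward(h1))

    def test_length_trace_via_stage_shapes(self):
        lengths = [l for name, _, l in stage_shapes(ModelConfig()) if "dense" in name]
        assert lengths == [29, 14, 7, 3]

    def test_shape_mismatch_rejected(self):
        model = KcrModel(ModelConfig(), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 80, 28)))

    def test_save_load_round_trip(self, tmp_path):
        cfg = ModelConfig(n_blocks=2, layers_per_block=1, growth_rate=4,
                          input_channels=8, input_length=12, reduction_ratio=2,
                          fc_sizes=[6])
        model = KcrModel(cfg, seed=1)
        x = np.random.default_rng(2).standard_normal((3, 8, 12))
        p1 = model.forward(x)
        model.save(tmp_path / "m.npz")
        back = KcrModel.load(tmp_path / "m.npz")
        assert np.array_equal(back.forward(x), p1)


class TestSummarize:
    def test_default_first_block(self):
        s = summarize(ModelConfig())
        assert s.stages[0] == ("input", 80, 29)
        assert s.stages[1] == ("dense_block_1", 144, 29)

    def test_single_block_has_no_transitions(self):
        s = summarize(ModelConfig(n_blocks=1))
        assert not any("transition" in name for name, _, _ in s.stages)

    def test_parameter_count_matches_closed_form(self):
        """Arithmetic oracle: sum the weight-tensor sizes stage by stage."""
        cfg = ModelConfig()
        s = summarize(cfg)
        expected = 0
        c, L = cfg.input_channels, cfg.input_length
        for b in range(cfg.n_blocks):
            for _ in range(cfg.layers_per_block):
                expected += 2 * c  # BN gamma/beta
                expected += cfg.growth_rate * c * cfg.kernel_size + cfg.growth_rate
                c += cfg.growth_rate
            if b < cfg.n_blocks - 1:
                expected += 2 * c  # transition BN
                c_out = int(np.ceil(cfg.compression * c))
                expected += c_out * c * 1 + c_out
                c = c_out
                L = L // 2
        hidden = c // cfg.reduction_ratio
        expected += hidden * c + hidden + c * hidden + c  # attention bottleneck
        n_in = c * L
        for w in cfg.fc_sizes:
            expected += w * n_in + w
            n_in = w
        expected += 2 * n_in + 2
        assert s.n_parameters == expected
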