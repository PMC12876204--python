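"""Model forward semantics: oracle equivalence and structural properties."""

import numpy as np
import pytest

from sksformer import nn
from sksformer.model import ModelConfig, SKSTransformer
from sksformer.nn import Tensor

from oracles import encoder_oracle, sea_oracle, sk_oracle


def normalized_batch(rng, b, t, d):
    x = rng.normal(size=(b, t, d)).astype(np.float32)
    return (x - x.mean((0, 1))) / x.std((0, 1))


class TestConfig:
    def test_divisibility_invariants(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=130, h=4)
        with pytest.raises(ValueError):
            ModelConfig(d_model=64, h=4, c_attn=5, kernel_set=(1, 3))
        with pytest.raises(ValueError):
            ModelConfig(kernel_set=(2, 4))
        with pytest.raises(ValueError):
            ModelConfig(K=1)

    def test_derived_defaults(self):
        cfg = ModelConfig(d_model=64, h=4)
        assert cfg.d_s == 16 and cfg.d_k == 16


class TestProjection:
    def test_zero_weights_give_zero_latents(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config)
        m.proj.weight.data[:] = 0
        m.proj.bias.data[:] = 0
        h0 = m.project_input(Tensor(np.ones((2, 8, 3), dtype=np.float32)))
        np.testing.assert_array_equal(h0.data, 0)

    def test_identity_projection_when_d_equals_width(self):
        cfg = ModelConfig(T=6, D=4, K=2, d_model=4, h=2, d_ff=8, c_attn=2,
                          d_s=2, kernel_set=(1,), conv_groups=1, dropout=0.0)
        m = SKSTransformer(cfg)
        m.proj.weight.data = np.eye(4, dtype=np.float32)
        m.proj.bias.data[:] = 0
        x = np.random.default_rng(0).normal(size=(3, 6, 4)).astype(np.float32)
        np.testing.assert_array_equal(m.project_input(Tensor(x)).data, x)

    def test_matches_triple_loop_matmul(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 8, 3)).astype(np.float32)
        h0 = m.project_input(Tensor(x)).data
        w, b = m.proj.weight.data, m.proj.bias.data
        ref = np.zeros_like(h0, dtype=float)
        for n in range(2):
            for t in range(8):
                for j in range(8):
                    ref[n, t, j] = b[j] + sum(x[n, t, d] * w[d, j]
                                              for d in range(3))
        np.testing.assert_allclose(h0, ref, atol=1e-6)

    def test_shape_mismatch_rejected(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config)
        with pytest.raises(ValueError):
            m.project_input(Tensor(np.zeros((2, 9, 3), dtype=np.float32)))


class TestEncoder:
    def test_matches_straight_line_oracle(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        rng = np.random.default_rng(2)
        h0 = rng.normal(size=(8, 8)).astype(np.float32)
        got = m.encoder_forward(Tensor(h0[None])).data[0]
        ref = encoder_oracle(h0.astype(float), m)
        np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_single_head_small_case_matches_oracle(self):
        cfg = ModelConfig(T=3, D=2, K=2, d_model=4, h=1, d_ff=8, c_attn=2,
                          d_s=2, kernel_set=(1,), conv_groups=1,
                          dropout=0.0, seed=11)
        m = SKSTransformer(cfg).eval()
        h0 = np.random.default_rng(3).normal(size=(3, 4)).astype(np.float32)
        got = m.encoder_forward(Tensor(h0[None])).data[0]
        np.testing.assert_allclose(got, encoder_oracle(h0.astype(float), m),
                                   atol=1e-5)

    def test_attention_rows_sum_to_one(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        x = normalized_batch(np.random.default_rng(4), 3, 8, 3)
        m(x)
        for layer in m.encoder:
            np.testing.assert_allclose(layer.mhsa.last_attention.sum(-1),
                                       1.0, atol=1e-6)

    def test_single_timestep_attention_returns_value(self):
        # with one key the softmax is exactly 1 and attention output == V
        cfg = ModelConfig(T=1, D=3, K=2, d_model=4, h=2, d_ff=8, c_attn=2,
                          d_s=2, kernel_set=(1,), conv_groups=1,
                          dropout=0.0, seed=5)
        m = SKSTransformer(cfg).eval()
        h0 = Tensor(np.random.default_rng(6).normal(size=(2, 1, 4))
                    .astype(np.float32))
        v = (h0 @ m.encoder[0].mhsa.wv.weight).data
        out, attn = nn.scaled_dot_attention(
            *(Tensor(z.reshape(2, 1, 2, 2).transpose(0, 2, 1, 3))
              for z in ((h0 @ m.encoder[0].mhsa.wq.weight).data,
                        (h0 @ m.encoder[0].mhsa.wk.weight).data, v)),
            scale=1.0)
        np.testing.assert_array_equal(attn, 1.0)
        np.testing.assert_allclose(
            out.data.transpose(0, 2, 1, 3).reshape(2, 1, 4), v, atol=1e-7)


class TestSelectiveKernel:
    def test_matches_straight_line_oracle(self):
        cfg = ModelConfig(T=8, D=3, K=3, d_model=4, h=2, d_ff=8, c_attn=2,
                          d_s=2, kernel_set=(1, 3, 5, 7), conv_groups=4,
                          dropout=0.0, seed=9)
        m = SKSTransformer(cfg)
        m.train()
        rng = np.random.default_rng(7)
        h1 = rng.normal(size=(8, 4)).astype(np.float32)
        got, _ = m.sk_forward(Tensor(h1[None]))
        ref = sk_oracle(h1.astype(float), m.sk, cfg.kernel_set, cfg.conv_groups)
        np.testing.assert_allclose(got.data[0], ref, atol=1e-5)

    def test_single_kernel_weight_is_one(self):
        cfg = ModelConfig(T=8, D=3, K=2, d_model=4, h=2, d_ff=8, c_attn=2,
                          d_s=2, kernel_set=(1,), conv_groups=1, dropout=0.0)
        m = SKSTransformer(cfg).eval()
        h1 = Tensor(np.random.default_rng(8).normal(size=(2, 8, 4))
                    .astype(np.float32))
        v_sk, inter = m.sk_forward(h1)
        np.testing.assert_array_equal(inter["alpha"], 1.0)
        np.testing.assert_allclose(v_sk.data, inter["branches"][0], atol=1e-7)

    def test_branch_weights_sum_to_one(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        h1 = Tensor(np.random.default_rng(9).normal(size=(5, 8, 8))
                    .astype(np.float32))
        _, inter = m.sk_forward(h1)
        np.testing.assert_allclose(inter["alpha"].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(inter["alpha"] > 0)


class TestSqueezeAxial:
    def test_matches_straight_line_oracle(self):
        # toy shape: c_attn=2, T=4, W=2 (d_model=4)
        cfg = ModelConfig(T=4, D=3, K=2, d_model=4, h=2, d_ff=8, c_attn=2,
                          d_s=2, kernel_set=(1,), conv_groups=1,
                          dropout=0.0, seed=13)
        m = SKSTransformer(cfg).eval()
        h1 = np.random.default_rng(10).normal(size=(4, 4)).astype(np.float32)
        got, _ = m.sea_forward(Tensor(h1[None]))
        ref = sea_oracle(h1.astype(float), m.sea)
        np.testing.assert_allclose(got.data[0], ref, atol=1e-5)

    def test_output_strictly_inside_unit_interval(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        h1 = Tensor((np.random.default_rng(11).normal(size=(3, 8, 8)) * 3)
                    .astype(np.float32))
        v_sea, _ = m.sea_forward(h1)
        assert np.all(v_sea.data > 0) and np.all(v_sea.data < 1)

    def test_single_row_attention_is_exactly_one(self):
        cfg = ModelConfig(T=1, D=3, K=2, d_model=4, h=2, d_ff=8, c_attn=2,
                          d_s=2, kernel_set=(1,), conv_groups=1, dropout=0.0)
        m = SKSTransformer(cfg).eval()
        h1 = Tensor(np.random.default_rng(12).normal(size=(2, 1, 4))
                    .astype(np.float32))
        _, inter = m.sea_forward(h1)
        np.testing.assert_array_equal(inter["A_row"], 1.0)

    def test_attention_rows_sum_to_one(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        h1 = Tensor(np.random.default_rng(13).normal(size=(2, 8, 8))
                    .astype(np.float32))
        _, inter = m.sea_forward(h1)
        np.testing.assert_allclose(inter["A_row"].sum(-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(inter["A_col"].sum(-1), 1.0, atol=1e-6)


class TestFusionAndHead:
    def test_gate_extremes_select_single_branch(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        rng = np.random.default_rng(14)
        v_sk = Tensor(rng.normal(size=(2, 8, 8)).astype(np.float32))
        v_sea = Tensor(rng.random(size=(2, 8, 8)).astype(np.float32))
        one = Tensor(np.ones((2, 1, 8), dtype=np.float32))
        zero = Tensor(np.zeros((2, 1, 8), dtype=np.float32))
        np.testing.assert_array_equal(m.gate_fuse(one, v_sk, v_sea).data, v_sk.data)
        np.testing.assert_array_equal(m.gate_fuse(zero, v_sk, v_sea).data, v_sea.data)

    def test_fused_lies_between_branches(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        x = normalized_batch(np.random.default_rng(15), 4, 8, 3)
        _, inter = m(x, return_intermediates=True)
        v_sk, _ = m.sk_forward(m.encoder_forward(m.project_input(Tensor(x))))
        v_sea, _ = m.sea_forward(m.encoder_forward(m.project_input(Tensor(x))))
        fused = inter["V_fused"]
        lo = np.minimum(v_sk.data, v_sea.data)
        hi = np.maximum(v_sk.data, v_sea.data)
        assert np.all(fused >= lo - 1e-6) and np.all(fused <= hi + 1e-6)
        assert np.all(inter["G"] >= 0) and np.all(inter["G"] <= 1)

    def test_no_gate_mode_is_fixed_average(self, tiny_model_config):
        cfg = tiny_model_config.replace(gate_mode="average")
        m = SKSTransformer(cfg).eval()
        x = normalized_batch(np.random.default_rng(16), 2, 8, 3)
        _, inter = m(x, return_intermediates=True)
        h1 = m.encoder_forward(m.project_input(Tensor(x)))
        v_sk, _ = m.sk_forward(h1)
        v_sea, _ = m.sea_forward(h1)
        np.testing.assert_allclose(inter["V_fused"],
                                   0.5 * v_sk.data + 0.5 * v_sea.data,
                                   atol=1e-6)

    def test_probabilities_sum_to_one_and_uniform_for_equal_logits(
            self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        x = normalized_batch(np.random.default_rng(17), 5, 8, 3)
        p = m.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p > 0)
        m.head.weight.data[:] = 0
        m.head.bias.data[:] = 3.7
        np.testing.assert_allclose(m.predict_proba(x), 1.0 / 3, atol=1e-6)

    def test_pooling_identity_on_time_constant_features(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        const = np.tile(np.arange(8, dtype=np.float32)[:, None], (1, 8))
        logits = m.classify(Tensor(const[None]))
        expected = np.arange(8, dtype=np.float32) @ m.head.weight.data \
            + m.head.bias.data
        np.testing.assert_allclose(logits.data[0], expected, atol=1e-5)


class TestForward:
    def test_path_equivalence_forced_gate_matches_single_branch(
            self, tiny_model_config):
        full = SKSTransformer(tiny_model_config).eval()
        x = normalized_batch(np.random.default_rng(18), 3, 8, 3)

        sk_only = SKSTransformer(tiny_model_config.replace(use_sea=False)).eval()
        sk_only.load_state_dict(full.state_dict(), strict=False)
        np.testing.assert_array_equal(full(x, force_gate=1.0).data,
                                      sk_only(x).data)

        sea_only = SKSTransformer(tiny_model_config.replace(use_sk=False)).eval()
        sea_only.load_state_dict(full.state_dict(), strict=False)
        np.testing.assert_array_equal(full(x, force_gate=0.0).data,
                                      sea_only(x).data)

    def test_deterministic_given_config_and_seed(self, tiny_model_config):
        x = normalized_batch(np.random.default_rng(19), 4, 8, 3)
        a = SKSTransformer(tiny_model_config).eval()(x).data
        b = SKSTransformer(tiny_model_config).eval()(x).data
        np.testing.assert_array_equal(a, b)
        m = SKSTransformer(tiny_model_config).eval()
        np.testing.assert_array_equal(m(x).data, m(x).data)

    def test_unnormalized_input_warns(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config).eval()
        with pytest.warns(UserWarning):
            m(np.full((2, 8, 3), 50.0, dtype=np.float32))

    def test_every_parameter_receives_gradient(self, tiny_model_config):
        m = SKSTransformer(tiny_model_config)
        m.train()
        rng = np.random.default_rng(20)
        x = normalized_batch(rng, 8, 8, 3)
        y = rng.integers(0, 3, size=8)
        touched = {name: False for name, _ in m.named_parameters()}
        opt = nn.Adam(m.parameters(), lr=1e-3)
        for _ in range(3):
            loss = nn.cross_entropy(m(x), y)
            opt.zero_grad()
            loss.backward()
            for name, p in m.named_parameters():
                if p.grad is not None and np.any(p.grad != 0):
                    touched[name] = True
            opt.step()
        dead = [n for n, ok in touched.items() if not ok]
        assert not dead, f"parameters with no gradient signal: {dead}"

    def test_overfits_small_linearly_separable_set(self):
        # capacity sanity: 32 windows with class-dependent mean offsets
        rng = np.random.default_rng(21)
        t_len, k = 16, 4
        offsets = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]],
                           dtype=float)
        x = np.concatenate([
            rng.normal(0, 0.3, size=(8, t_len, 3)) + offsets[c]
            for c in range(k)]).astype(np.float32)
        y = np.repeat(np.arange(k), 8)
        cfg = ModelConfig(T=t_len, D=3, K=k, d_model=8, h=2, d_ff=16,
                          c_attn=4, d_s=4, kernel_set=(1, 3), conv_groups=2,
                          dropout=0.0, seed=2)
        from sksformer.train_eval import TrainConfig, train_model
        tc = TrainConfig(epochs=200, batch_size=32, learning_rate=1e-3,
                         patience=200, val_fraction=0.0, seed=2)
        m, log = train_model(x, y, cfg, tc)
        assert log[-1]["train_accuracy"] >= 0.99
        # loss trends downward overall
        first = np.mean([e["train_loss"] for e in log[:10]])
        last = np.mean([e["train_loss"] for e in log[-10:]])
        assert last < first
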