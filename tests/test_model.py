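"""Encoder mechanics: shapes, attention arithmetic, maps, determinism."""

import numpy as np
import pytest

from rnaembed.autodiff import Tensor
from rnaembed.model import (
    ModelConfig,
    attention_map,
    init_params,
    load_checkpoint,
    save_checkpoint,
    tokenize,
    transformer_forward,
)
from rnaembed.seqio import RnaSequence


class TestTokenize:
    def test_fixed_vocabulary_order(self):
        np.testing.assert_array_equal(tokenize(RnaSequence("x", "ACGU")), [0, 1, 2, 3])

    def test_length_bound(self):
        cfg = ModelConfig(D=8, n_layers=1, H=1, ffn_dim=8, max_len=440)
        seq = RnaSequence("x", "A" * 441)
        with pytest.raises(ValueError):
            tokenize(seq, cfg)


class TestForward:
    def test_embedding_is_n_by_120_at_default_width(self):
        cfg = ModelConfig(n_layers=1, H=2)  # D stays at the 120 default
        params = init_params(cfg, np.random.default_rng(0))
        z, _ = transformer_forward(tokenize(RnaSequence("x", "ACGUA")), params, cfg)
        assert z.data.shape == (5, 120)

    def test_single_key_softmax_passes_value_through(self):
        # one token, one head, V and output projections set to identity:
        # the softmax over a single key is 1, so the attention output row
        # equals the input row exactly
        cfg = ModelConfig(
            D=4, n_layers=1, H=1, ffn_dim=4, use_residual=False, use_layernorm=False
        )
        params = init_params(cfg, np.random.default_rng(0))
        params["l0.Wv0"] = Tensor(np.eye(4), requires_grad=True)
        params["l0.Wo"] = Tensor(np.eye(4), requires_grad=True)
        params["l0.bo"] = Tensor(np.zeros(4), requires_grad=True)
        tokens = np.array([2])
        x = params["tok"].data[2] + params["pos"].data[0]
        _, attns = transformer_forward(tokens, params, cfg, collect_attention=True)
        np.testing.assert_allclose(attns[0][0], [[1.0]])
        head_out = attns[0][0] @ (x[None, :] @ params["l0.Wv0"].data)
        c = head_out @ params["l0.Wo"].data
        np.testing.assert_allclose(c[0], x, atol=1e-12)

    def test_layer_matches_independent_step_by_step_computation(self):
        # n=2, one head, residual/normalisation off: reproduce the layer
        # output with an explicit Q/K/V, softmax, concat, W^O, FFN chain
        cfg = ModelConfig(
            D=3, n_layers=1, H=1, ffn_dim=5, activation="tanh",
            use_residual=False, use_layernorm=False,
        )
        rng = np.random.default_rng(5)
        params = init_params(cfg, rng)
        for k in params:
            if k.startswith("l0.b") or k == "mlm_b":
                params[k] = Tensor(rng.normal(size=params[k].data.shape), requires_grad=True)
        tokens = np.array([0, 3])
        z, _ = transformer_forward(tokens, params, cfg)

        g = lambda k: params[k].data
        x = g("tok")[tokens] + g("pos")[:2]
        q, k_, v = x @ g("l0.Wq0"), x @ g("l0.Wk0"), x @ g("l0.Wv0")
        s = q @ k_.T / np.sqrt(3)
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        c = (a @ v) @ g("l0.Wo") + g("l0.bo")
        f = np.tanh(c @ g("l0.W1") + g("l0.b1")) @ g("l0.W2") + g("l0.b2")
        np.testing.assert_allclose(z.data, f, rtol=1e-12)

    def test_deterministic_given_params(self, tiny_config, tiny_params):
        tokens = tokenize(RnaSequence("x", "ACGUACGU"))
        z1, _ = transformer_forward(tokens, tiny_params, tiny_config)
        z2, _ = transformer_forward(tokens, tiny_params, tiny_config)
        np.testing.assert_array_equal(z1.data, z2.data)

    def test_outputs_finite_for_random_inputs(self, tiny_config, rng):
        for trial in range(5):
            params = init_params(tiny_config, np.random.default_rng(trial))
            n = int(rng.integers(1, 50))
            tokens = rng.integers(0, 4, size=n)
            z, _ = transformer_forward(tokens, params, tiny_config)
            assert np.isfinite(z.data).all()

    def test_position_table_carries_all_position_information(self):
        # with the position table zeroed, equal tokens at different
        # positions produce identical embedding rows
        cfg = ModelConfig(D=8, n_layers=1, H=2, ffn_dim=16)
        params = init_params(cfg, np.random.default_rng(3))
        params["pos"] = Tensor(np.zeros_like(params["pos"].data), requires_grad=True)
        z, _ = transformer_forward(tokenize(RnaSequence("x", "ACGA")), params, cfg)
        np.testing.assert_allclose(z.data[0], z.data[3], atol=1e-10)

    def test_shape_mismatch_rejected(self, tiny_config):
        cfg_small = ModelConfig(D=8, n_layers=1, H=1, ffn_dim=8)
        params = init_params(cfg_small, np.random.default_rng(0))
        with pytest.raises(ValueError):
            transformer_forward(np.array([0, 1]), params, tiny_config)


class TestAttentionMap:
    def test_uniform_when_all_rows_identical(self):
        cfg = ModelConfig(D=6, n_layers=1, H=3, ffn_dim=6)
        params = init_params(cfg, np.random.default_rng(0))
        # identical token vectors and zero positions: logits constant
        tok = params["tok"].data.copy()
        tok[:] = tok[0]
        from rnaembed.autodiff import Tensor

        params["tok"] = Tensor(tok, requires_grad=True)
        params["pos"] = Tensor(np.zeros_like(params["pos"].data), requires_grad=True)
        m = attention_map(np.array([0, 1, 2, 3, 0]), params, cfg)
        np.testing.assert_allclose(m, 3.0, atol=1e-9)

    def test_total_mass_is_n_times_heads(self, tiny_config, tiny_params, rng):
        for n in (1, 7, 23):
            tokens = rng.integers(0, 4, size=n)
            for layer in (1, tiny_config.n_layers):
                m = attention_map(tokens, tiny_params, tiny_config, layer=layer)
                assert m.min() >= 0
                assert abs(m.sum() - n * tiny_config.H) < 1e-6

    def test_dominant_key_attracts_mass(self):
        # make key 2's projection large so every query attends to it
        cfg = ModelConfig(D=4, n_layers=1, H=1, ffn_dim=4)
        params = init_params(cfg, np.random.default_rng(2))
        tok = np.zeros((6, 4))
        tok[0] = [0.1, 0, 0, 0]
        tok[1] = [5.0, 0, 0, 0]  # token C at position 2 will dominate
        params["tok"] = Tensor(tok, requires_grad=True)
        params["pos"] = Tensor(np.zeros_like(params["pos"].data), requires_grad=True)
        params["l0.Wq0"] = Tensor(np.eye(4), requires_grad=True)
        params["l0.Wk0"] = Tensor(np.eye(4), requires_grad=True)
        tokens = np.array([0, 1, 0])
        m = attention_map(tokens, params, cfg)
        # brute-force the same softmax
        x = tok[tokens]
        s = (x @ x.T) / 2.0
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(m, a.sum(axis=0), atol=1e-12)
        assert m[1] > m[0] and m[1] > m[2]

    def test_invalid_layer_rejected(self, tiny_config, tiny_params):
        with pytest.raises(ValueError):
            attention_map(np.array([0]), tiny_params, tiny_config, layer=9)


def test_checkpoint_round_trip(tmp_path, tiny_config, tiny_params):
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny_params, tiny_config)
    params, config = load_checkpoint(path)
    assert config == tiny_config
    for k, p in tiny_params.items():
        np.testing.assert_array_equal(params[k].data, p.data)
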