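"""Patch embedding, encoder, cross-attention and forward-pass contracts."""

import numpy as np
import pytest

from gaitphase.autodiff import Tensor
from gaitphase.preprocess import cartesian_to_phase
from gaitphase.transformer import (
    ModelConfig,
    cross_attend,
    encode_channel,
    encoder_layer,
    forward,
    forward_batch,
    init_params,
    multi_head_attention,
    patch_embed,
)

from oracles import multi_head_attention_loops


class TestPatchEmbed:
    def test_output_has_patches_plus_token_rows(self):
        cfg = ModelConfig(n_channels=2, window_len=100, patch_len=10,
                          embed_dim=16, n_heads=2, n_layers=1)
        params = init_params(cfg, seed=0)
        out = patch_embed(np.zeros(100), 0, params)
        assert out.shape == (11, 16)

    def test_zero_projection_leaves_token_and_positions(self, tiny_config):
        params = init_params(tiny_config, seed=1)
        params.patch_proj_w.data[:] = 0.0
        params.patch_proj_b.data[:] = 0.0
        params.pos_table.data[:] = 0.0
        out = patch_embed(np.zeros(tiny_config.window_len), 1, params)
        assert np.allclose(out[0], params.channel_tokens.data[1])
        assert np.allclose(out[1:], 0.0)

    def test_projection_matches_independent_matmul(self, tiny_config, rng):
        params = init_params(tiny_config, seed=2)
        x = rng.standard_normal(tiny_config.window_len)
        out = patch_embed(x, 0, params)
        patches = x.reshape(tiny_config.n_patches, tiny_config.patch_len)
        expect = np.einsum("sp,pd->sd", patches, params.patch_proj_w.data) \
            + params.patch_proj_b.data
        resid = out[1:] - params.pos_table.data[1:] - expect
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_wrong_length_rejected(self, tiny_params, tiny_config):
        with pytest.raises(ValueError):
            patch_embed(np.zeros(tiny_config.window_len + 1), 0, tiny_params)


class TestEncoderLayer:
    def test_single_position_attention_is_one(self):
        cfg = ModelConfig(n_channels=1, window_len=4, patch_len=4,
                          embed_dim=8, n_heads=2, n_layers=1, dropout=0.0)
        params = init_params(cfg, seed=0)
        _, attn = encoder_layer(np.random.default_rng(0).standard_normal((1, 8)),
                                params.layers[0], cfg, capture_attention=True)
        assert np.allclose(attn, 1.0)

    def test_identical_rows_give_uniform_attention(self, tiny_config, rng):
        params = init_params(tiny_config, seed=3)
        row = rng.standard_normal(tiny_config.embed_dim)
        x = np.tile(row, (5, 1))
        _, attn = encoder_layer(x, params.layers[0], tiny_config,
                                capture_attention=True)
        assert np.allclose(attn, 1.0 / 5.0, atol=1e-12)

    @pytest.mark.parametrize("scale_by_full_d", [False, True])
    def test_self_attention_matches_loop_oracle(self, scale_by_full_d, rng):
        cfg = ModelConfig(n_channels=1, window_len=4, patch_len=4, embed_dim=8,
                          n_heads=2, n_layers=1, dropout=0.0,
                          scale_by_full_d=scale_by_full_d)
        params = init_params(cfg, seed=4)
        x = rng.standard_normal((5, 8))
        layer = params.layers[0]
        out, attn = multi_head_attention(Tensor(x), Tensor(x), layer, cfg)
        o_out, o_attn = multi_head_attention_loops(
            x, x, layer["W_Q"].data, layer["W_K"].data, layer["W_V"].data,
            layer["W_O"].data, layer["b_O"].data, cfg.n_heads, cfg.attn_scale)
        assert np.allclose(out.data, o_out, atol=1e-6)
        assert np.allclose(attn.data, o_attn, atol=1e-6)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_non_finite_input_raises(self, tiny_config, tiny_params):
        x = np.full((4, tiny_config.embed_dim), 1e300)
        with pytest.raises(FloatingPointError):
            encoder_layer(x, tiny_params.layers[0], tiny_config)


class TestEncodeChannel:
    def test_zero_layers_is_identity_on_token(self, rng):
        cfg = ModelConfig(n_channels=1, window_len=4, patch_len=2, embed_dim=8,
                          n_heads=2, n_layers=0)
        params = init_params(cfg, seed=0)
        emb = rng.standard_normal((3, 8))
        assert np.allclose(encode_channel(emb, params), emb[0])

    def test_returns_embed_dim_vector(self, tiny_config, tiny_params, rng):
        emb = rng.standard_normal((tiny_config.seq_len, tiny_config.embed_dim))
        out = encode_channel(emb, tiny_params)
        assert out.shape == (tiny_config.embed_dim,)


class TestCrossAttend:
    def test_single_channel_weight_is_one(self, tiny_config, rng):
        params = init_params(tiny_config, seed=5)
        _, w = cross_attend(rng.standard_normal((1, tiny_config.embed_dim)),
                            params)
        assert np.allclose(w, 1.0)

    def test_identical_tokens_uniform_weights(self, tiny_config, rng):
        params = init_params(tiny_config, seed=6)
        tok = np.tile(rng.standard_normal(tiny_config.embed_dim), (3, 1))
        _, w = cross_attend(tok, params)
        assert np.allclose(w, 1.0 / 3.0, atol=1e-12)

    def test_matches_loop_oracle(self, tiny_config, rng):
        params = init_params(tiny_config, seed=7)
        toks = rng.standard_normal((3, tiny_config.embed_dim))
        feat, w = cross_attend(toks, params)
        c = params.cross
        o_out, o_attn = multi_head_attention_loops(
            params.global_token.data, toks, c["W_Q"].data, c["W_K"].data,
            c["W_V"].data, c["W_O"].data, c["b_O"].data,
            tiny_config.n_heads, tiny_config.attn_scale)
        assert np.allclose(feat, o_out[0], atol=1e-6)
        assert np.allclose(w, o_attn[:, 0, :], atol=1e-6)

    def test_empty_tokens_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            cross_attend(np.empty((0, 8)), tiny_params)


class TestForward:
    def test_deterministic_in_eval_mode(self, tiny_config, rng):
        params = init_params(tiny_config, seed=8)
        w = rng.standard_normal((tiny_config.n_channels, tiny_config.window_len))
        t1 = forward(w, params)
        t2 = forward(w, params)
        assert np.array_equal(t1.y_pred, t2.y_pred)

    def test_attention_rows_stochastic(self, tiny_config, rng):
        params = init_params(tiny_config, seed=9)
        w = rng.standard_normal((tiny_config.n_channels, tiny_config.window_len))
        t = forward(w, params, capture_attention=True)
        assert np.all(t.cross_attention >= 0)
        assert np.allclose(t.cross_attention.sum(-1), 1.0, atol=1e-6)
        assert np.all(t.encoder_attention >= 0)
        assert np.allclose(t.encoder_attention.sum(-1), 1.0, atol=1e-6)

    def test_decoded_phase_in_range(self, tiny_config, rng):
        params = init_params(tiny_config, seed=10)
        for _ in range(20):
            w = rng.standard_normal(
                (tiny_config.n_channels, tiny_config.window_len)) * 10
            p = cartesian_to_phase(forward(w, params).y_pred)
            assert 0.0 <= p < 100.0

    def test_shape_mismatch_rejected(self, tiny_config, tiny_params):
        with pytest.raises(ValueError):
            forward(np.zeros((tiny_config.n_channels, 7)), tiny_params)

    def test_channel_permutation_equivariance(self, rng):
        """Permuting channels together with their tokens permutes the
        cross-attention weights and leaves the prediction unchanged."""
        cfg = ModelConfig(n_channels=4, window_len=20, patch_len=5,
                          embed_dim=8, n_heads=2, n_layers=1, dropout=0.0)
        params = init_params(cfg, seed=11)
        w = rng.standard_normal((4, 20))
        perm = np.array([2, 0, 3, 1])
        t0 = forward(w, params)
        params.channel_tokens.data = params.channel_tokens.data[perm]
        t1 = forward(w[perm], params)
        assert np.allclose(t1.y_pred, t0.y_pred, atol=1e-9)
        assert np.allclose(t1.cross_attention, t0.cross_attention[:, perm],
                           atol=1e-9)

    def test_reduces_to_linear_map_without_layers(self, rng):
        """With no encoder layers and an identity-like head, the channel
        token path is a fixed linear function of the patches."""
        cfg = ModelConfig(n_channels=2, window_len=10, patch_len=5,
                          embed_dim=4, n_heads=1, n_layers=0, dropout=0.0,
                          head_hidden_dims=())
        params = init_params(cfg, seed=12)
        w1 = rng.standard_normal((2, 10))
        w2 = rng.standard_normal((2, 10))
        for a in (0.0, 0.5, 2.0):
            # token row 0 is input-independent => cross-attention tokens are
            # constant; prediction must be identical for any input
            ya = forward(a * w1 + (1 - a) * w2, params).y_pred
            yb = forward(w1, params).y_pred
            assert np.allclose(ya, yb, atol=1e-12)

    def test_batch_matches_single(self, tiny_config, rng):
        params = init_params(tiny_config, seed=13)
        X = rng.standard_normal((3, tiny_config.n_channels,
                                 tiny_config.window_len))
        y, _ = forward_batch(Tensor(X), params)
        for i in range(3):
            assert np.allclose(forward(X[i], params).y_pred, y.data[i],
                               atol=1e-12)


def test_config_validation():
    with pytest.raises(ValueError, match="divide"):
        ModelConfig(window_len=100, patch_len=7)
    with pytest.raises(ValueError, match="n_heads"):
        ModelConfig(embed_dim=10, n_heads=4)
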