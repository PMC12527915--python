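import math

import numpy as np
import pytest

from drivergraph import (
    DirectedGeneGraph,
    ModelConfig,
    encode_cell,
    init_cmm_params,
    load_checkpoint,
    save_checkpoint,
)
from drivergraph.cmm_encoder import (
    TokenBatch,
    build_token_batch,
    encode_token_batch,
    encoder_forward,
)
from drivergraph.data_core import ValidationError
from drivergraph.gene_graph import make_variant
from drivergraph.synthetic_data import generate_graph
from drivergraph import _nn


@pytest.fixture
def small_graph(rng):
    return generate_graph(20, 0.08, 3)


@pytest.fixture
def small_rows(rng):
    rows = rng.integers(0, 4, size=(3, 20))
    rows[rows.sum(axis=1) == 0, 0] = 1
    rows[0, 6:] = 0  # ragged: cell 0 has few tokens
    if rows[0].sum() == 0:
        rows[0, 0] = 2
    return rows


class TestModelConfig:
    def test_head_dim_constraint(self):
        cfg = ModelConfig(H=256, n_heads=8)
        assert cfg.D * cfg.n_heads == 2 * cfg.H
        with pytest.raises(ValidationError):
            ModelConfig(H=10, n_heads=7)

    def test_reserved_buckets_are_distinct(self, tiny_config):
        c = tiny_config
        assert c.cls_dist_bucket != c.unreachable_bucket
        assert c.cls_dist_bucket < c.n_dist_buckets
        assert c.cls_deg_bucket < c.n_deg_buckets


class TestTokenBatch:
    def test_token_count_is_cls_plus_nonzero(self, tiny_config, small_graph):
        row = np.zeros(20, dtype=int)
        row[[2, 5, 9]] = 1
        tb = build_token_batch(row, small_graph, tiny_config, training=False)
        assert int(tb.mask[0].sum()) == 4  # CLS + 3 genes
        assert tb.tokens[0, 0] == 20  # reserved CLS index

    def test_ragged_batch_padding(self, tiny_config, small_graph, small_rows):
        tb = build_token_batch(small_rows, small_graph, tiny_config, training=False)
        n_tokens = tb.mask.sum(axis=1)
        assert tb.tokens.shape[1] == n_tokens.max()
        assert (~tb.mask[np.argmin(n_tokens), int(n_tokens.min()):]).all()

    def test_cls_uses_reserved_feature_buckets(self, tiny_config, small_graph, small_rows):
        tb = build_token_batch(small_rows, small_graph, tiny_config, training=False)
        assert (tb.deg_in[:, 0] == tiny_config.cls_deg_bucket).all()
        assert (tb.dist[:, 0, :] == tiny_config.cls_dist_bucket).all()
        assert (tb.dist[:, :, 0] == tiny_config.cls_dist_bucket).all()


class TestEncoder:
    def test_output_length_is_coordinate_dim_default(self, small_graph):
        cfg = ModelConfig()  # defaults: 6 layers, H=256, 2048-d coordinate
        params = init_cmm_params(20, cfg, 0)
        row = np.zeros(20, dtype=int)
        row[[1, 4, 7]] = 2
        crd = encode_cell(row, small_graph, params, cfg)
        assert crd.values.shape == (2048,)
        assert np.isfinite(crd.values).all()

    def test_deterministic_at_inference(self, tiny_config, small_graph, small_rows):
        params = init_cmm_params(20, tiny_config, 1)
        a = encode_cell(small_rows[1], small_graph, params, tiny_config)
        b = encode_cell(small_rows[1], small_graph, params, tiny_config)
        np.testing.assert_array_equal(a.values, b.values)

    def test_permutation_invariance(self, tiny_config, small_graph, small_rows, rng):
        """Coordinates must not depend on the token order."""
        params = init_cmm_params(20, tiny_config, 1)
        tb = build_token_batch(small_rows[1:2], small_graph, tiny_config)
        base = encode_token_batch(params, tiny_config, tb)
        n = int(tb.mask[0].sum())
        perm = np.concatenate([[0], 1 + rng.permutation(n - 1)])
        tb2 = TokenBatch(
            tokens=tb.tokens[:, perm],
            expr=tb.expr[:, perm],
            mask=tb.mask[:, perm],
            deg_in=tb.deg_in[:, perm],
            deg_out=tb.deg_out[:, perm],
            dist=tb.dist[:, perm][:, :, perm],
        )
        out = encode_token_batch(params, tiny_config, tb2)
        rel = np.linalg.norm(out - base) / np.linalg.norm(base)
        assert rel < 1e-10

    def test_padding_does_not_change_real_outputs(self, tiny_config, small_graph, small_rows):
        params = init_cmm_params(20, tiny_config, 1)
        tb1 = build_token_batch(small_rows[0:1], small_graph, tiny_config)
        alone = encode_token_batch(params, tiny_config, tb1)
        tb_all = build_token_batch(small_rows, small_graph, tiny_config)
        padded = encode_token_batch(params, tiny_config, tb_all)[0:1]
        assert np.abs(padded - alone).max() < 1e-6

    def test_attention_rows_sum_to_one(self, tiny_config, small_graph, small_rows):
        """Softmax over unmasked positions is a distribution."""
        params = init_cmm_params(20, tiny_config, 1)
        tb = build_token_batch(small_rows, small_graph, tiny_config)
        _, cache = encoder_forward(params, tiny_config, tb, need_cache=True)
        attn = cache[1][0][10]  # layer 0 attention [B, nh, T, T]
        sums = attn.sum(axis=-1)[tb.mask[:, None, :].repeat(tiny_config.n_heads, 1)]
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_reduces_to_plain_attention_on_uniform_graph(self, small_rows, small_graph):
        """With a fully connected graph, zero spatial bias and uniform
        degree embeddings the layer matches a standard transformer layer
        (independent reference implementation)."""
        cfg = ModelConfig(H=4, n_layers=1, n_heads=2, coordinate_dim=6,
                          d_max=2, max_degree_bucket=4, dtype="float64")
        fc = make_variant(small_graph, "fully_connected")
        params = init_cmm_params(20, cfg, 5)
        a = params.arrays
        a["layer0.btab"][:] = 0.0
        a["layer0.z_in"][:] = a["layer0.z_in"][0]  # degree-independent
        a["layer0.z_out"][:] = a["layer0.z_out"][0]
        row = small_rows[1:2]
        tb = build_token_batch(row, fc, cfg, training=False)
        got, cache = encoder_forward(params, cfg, tb, need_cache=True)

        # independent plain pre-norm transformer layer on the same embeddings
        E, nh, Dh = cfg.E, cfg.n_heads, cfg.D
        name = a["name_emb"][tb.tokens[0]]
        exprp = tb.expr[0][:, None] * a["expr_w"] + a["expr_b"]
        exprp[0] = a["cls_expr"]
        x = np.concatenate([name, exprp], axis=-1)

        def ln(v, g, b):
            mu = v.mean(-1, keepdims=True)
            sd = np.sqrt(((v - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
            return g * (v - mu) / sd + b

        h = ln(x, a["layer0.ln1_g"], a["layer0.ln1_b"])
        h1 = h @ a["layer0.mlp_W1"] + a["layer0.mlp_b1"]
        gelu = 0.5 * h1 * (1 + np.vectorize(math.erf)(h1 / np.sqrt(2)))
        u = x + gelu @ a["layer0.mlp_W2"] + a["layer0.mlp_b2"]
        u = u + a["layer0.z_in"][0] + a["layer0.z_out"][0]
        v = ln(u, a["layer0.ln2_g"], a["layer0.ln2_b"])
        T = v.shape[0]
        q = (v @ a["layer0.Wq"] + a["layer0.bq"]).reshape(T, nh, Dh)
        k = (v @ a["layer0.Wk"] + a["layer0.bk"]).reshape(T, nh, Dh)
        val = (v @ a["layer0.Wv"] + a["layer0.bv"]).reshape(T, nh, Dh)
        out = np.empty((T, nh, Dh))
        for hI in range(nh):
            logits = q[:, hI] @ k[:, hI].T / np.sqrt(Dh)
            p = np.exp(logits - logits.max(-1, keepdims=True))
            p /= p.sum(-1, keepdims=True)
            out[:, hI] = p @ val[:, hI]
        y = out.reshape(T, E) @ a["layer0.Wo"] + a["layer0.bo"]
        expect = (u + y)[0] @ a["out_W"] + a["out_b"]
        assert np.abs(got[0] - expect).max() < 1e-5


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_config):
        params = init_cmm_params(20, tiny_config, 0)
        extra = {"dgp": {"W": np.arange(6.0).reshape(2, 3)}}
        save_checkpoint(tmp_path / "ck.npz", tiny_config, params, extra)
        cfg2, params2, extra2 = load_checkpoint(tmp_path / "ck.npz")
        assert cfg2 == tiny_config
        assert params2.vocab_size == 20
        for k, v in params.arrays.items():
            np.testing.assert_array_equal(v, params2.arrays[k])
        np.testing.assert_array_equal(extra2["dgp"]["W"], extra["dgp"]["W"])
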