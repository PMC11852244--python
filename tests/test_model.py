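"""Encoder geometry, sparse attention structure, and the dense-attention
reference oracle."""

import numpy as np
import pytest

from sebird.bpe import PAD_ID, TokenizedExample
from sebird.model import (
    SparseAttentionConfig,
    SparseTransformerClassifier,
    analytic_parameter_count,
    load_preset,
    mask_for_mlm,
    sparse_attention_mask,
)


def _example(ids):
    return TokenizedExample(ids=tuple(ids),
                            offsets=tuple((i, i + 1) for i in range(len(ids))))


# ---------------------------------------------------------------------------
# independent dense-attention reference forward pass (plain numpy)
# ---------------------------------------------------------------------------

def _np_gelu(x):
    return 0.5 * x * (1 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x**3)))


def _np_ln(x, g, b, eps=1e-12):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def dense_reference_logits(model, ids):
    """Full (non-sparse) attention forward pass, written independently."""
    cfg = model.config
    p = {k: v.data for k, v in model.params.items()}
    T = len(ids)
    x = p["tok_emb"][np.array(ids)] + p["pos_emb"][:T]
    x = _np_ln(x, p["emb_ln_g"], p["emb_ln_b"])
    dh = cfg.head_dim
    for i in range(cfg.n_layers):
        heads_out = []
        for h in range(cfg.n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            q = (x @ p[f"l{i}.wq"] + p[f"l{i}.bq"])[:, sl]
            k = (x @ p[f"l{i}.wk"] + p[f"l{i}.bk"])[:, sl]
            v = (x @ p[f"l{i}.wv"] + p[f"l{i}.bv"])[:, sl]
            scores = q @ k.T / np.sqrt(dh)
            e = np.exp(scores - scores.max(-1, keepdims=True))
            attn = e / e.sum(-1, keepdims=True)
            heads_out.append(attn @ v)
        ctx = np.concatenate(heads_out, axis=-1)
        x = _np_ln(x + ctx @ p[f"l{i}.wo"] + p[f"l{i}.bo"],
                   p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
        ffn = _np_gelu(x @ p[f"l{i}.ffn_w1"] + p[f"l{i}.ffn_b1"])
        x = _np_ln(x + ffn @ p[f"l{i}.ffn_w2"] + p[f"l{i}.ffn_b2"],
                   p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
    pooled = x[0]
    hid = _np_gelu(pooled @ p["head_w1"] + p["head_b1"])
    return hid @ p["head_w2"] + p["head_b2"]


class TestSparseAttentionMask:
    def test_all_global_is_full_attention(self):
        cfg = SparseAttentionConfig(
            n_layers=1, n_heads=1, hidden_size=8, block_size=4,
            n_random_blocks=0, n_global_blocks=8, n_window_blocks=1,
            max_positions=32, vocab_size=16,
        )
        assert sparse_attention_mask(cfg, 32).all()

    def test_window_only_is_block_diagonal(self):
        cfg = SparseAttentionConfig(
            n_layers=1, n_heads=1, hidden_size=8, block_size=4,
            n_random_blocks=0, n_global_blocks=0, n_window_blocks=1,
            max_positions=32, vocab_size=16,
        )
        mask = sparse_attention_mask(cfg, 16)
        expected = np.kron(np.eye(4, dtype=bool), np.ones((4, 4), dtype=bool))
        assert (mask == expected).all()

    def test_eight_block_window3_global1_enumeration(self):
        # 8 blocks, window 3, 1 global, no random: row 1 reaches blocks
        # {0,1,2} via window plus global {0} -> 3 distinct; interior row 4
        # reaches {3,4,5} + {0} -> 4 distinct
        cfg = SparseAttentionConfig(
            n_layers=1, n_heads=1, hidden_size=8, block_size=2,
            n_random_blocks=0, n_global_blocks=1, n_window_blocks=3,
            max_positions=16, vocab_size=16,
        )
        mask = sparse_attention_mask(cfg, 16)
        block_rows = mask.reshape(8, 2, 8, 2).any(axis=(1, 3))
        assert block_rows[1].sum() == 3
        assert block_rows[4].sum() == 4
        # global block attends to and from everything
        assert block_rows[0].all() and block_rows[:, 0].all()

    def test_random_blocks_seeded_and_counted(self):
        cfg = SparseAttentionConfig(
            n_layers=1, n_heads=1, hidden_size=8, block_size=2,
            n_random_blocks=2, n_global_blocks=1, n_window_blocks=3,
            max_positions=40, vocab_size=16,
        )
        rng = lambda: np.random.default_rng(123)  # noqa: E731
        a = sparse_attention_mask(cfg, 40, rng())
        b = sparse_attention_mask(cfg, 40, rng())
        assert (a == b).all()
        block_rows = a.reshape(20, 2, 20, 2).any(axis=(1, 3))
        for i in range(2, 18):  # interior non-global rows: 3 window + 1 global + 2 random
            assert block_rows[i].sum() == 6


class TestForwardPass:
    def test_logits_shape_and_eval_determinism(self, micro_config):
        model = SparseTransformerClassifier(micro_config, seed=1)
        model.eval_mode()
        ex = _example([2, 5, 6, 7, 8, 9, 5, 6])
        out1 = model.forward_classify(ex)
        out2 = model.forward_classify(ex)
        assert out1.logits.shape == (1, 2)
        assert np.array_equal(out1.logits, out2.logits)

    def test_dense_oracle_equivalence_with_all_global_blocks(self):
        # every block global -> sparse mask is all-true -> must equal the
        # dense reference within float tolerance
        cfg = SparseAttentionConfig(
            n_layers=2, n_heads=2, hidden_size=16, intermediate_size=32,
            block_size=4, n_random_blocks=0, n_global_blocks=8,
            n_window_blocks=1, max_positions=32, vocab_size=24, dropout=0.0,
        )
        rng = np.random.default_rng(0)
        for trial in range(20):
            model = SparseTransformerClassifier(cfg, seed=trial)
            model.eval_mode()
            ids = [2] + rng.integers(5, 24, size=11).tolist()
            got = model.forward_classify(_example(ids)).logits[0]
            want = dense_reference_logits(model, ids)
            assert np.allclose(got, want, atol=1e-5), trial

    def test_embedding_additivity(self, micro_config):
        model = SparseTransformerClassifier(micro_config, seed=0)
        e57 = model.embed(np.array([[5, 7]])).data[0]
        e55 = model.embed(np.array([[5, 5]])).data[0]
        tok = model.params["tok_emb"].data
        # same position, different tokens: differ by token-embedding delta
        assert np.allclose(e57[1] - e55[1], tok[7] - tok[5])
        # same token, different positions: differ by position delta
        pos = model.params["pos_emb"].data
        assert np.allclose(e55[1] - e55[0], pos[1] - pos[0])

    def test_length_overflow_rejected(self, micro_config):
        model = SparseTransformerClassifier(micro_config, seed=0)
        with pytest.raises(ValueError):
            model.embed(np.zeros((1, micro_config.max_positions + 1), dtype=int))

    def test_pad_extension_leaves_logits_unchanged(self):
        cfg = SparseAttentionConfig(
            n_layers=2, n_heads=2, hidden_size=16, intermediate_size=32,
            block_size=4, n_random_blocks=0, n_global_blocks=1,
            n_window_blocks=3, max_positions=32, vocab_size=24, dropout=0.0,
        )
        model = SparseTransformerClassifier(cfg, seed=3)
        model.eval_mode()
        ids = [2, 5, 6, 7, 8, 9, 10, 11]
        base = model.forward_logits(np.array([ids])).data
        padded = np.array([ids + [PAD_ID] * 8])
        ext = model.forward_logits(padded).data
        assert np.allclose(base, ext, atol=1e-9)

    def test_parameter_count_matches_analytic_formula(self, micro_config):
        model = SparseTransformerClassifier(micro_config, seed=0)
        assert model.n_parameters() == analytic_parameter_count(micro_config)

    def test_full_preset_geometry(self):
        cfg = load_preset("full")
        assert (cfg.n_layers, cfg.n_heads, cfg.hidden_size) == (12, 12, 768)
        assert (cfg.block_size, cfg.n_random_blocks, cfg.n_global_blocks,
                cfg.n_window_blocks) == (64, 3, 2, 3)
        assert cfg.max_positions == 4096 and cfg.vocab_size == 32000
        assert cfg.mlm_mask_rate == 0.15
        assert analytic_parameter_count(cfg) > 80_000_000  # BigBird-base class


class TestMlmMasking:
    def test_fifteen_percent_of_tokens_masked(self):
        rng = np.random.default_rng(0)
        ids = [2] + list(np.random.default_rng(1).integers(5, 50, size=100))
        masked, pos = mask_for_mlm(ids, rng, rate=0.15)
        assert len(pos) == 15
        assert (masked[pos] == 4).all()  # MASK id
        untouched = np.setdiff1d(np.arange(len(ids)), pos)
        assert (masked[untouched] == np.array(ids)[untouched]).all()

    def test_specials_never_masked(self):
        rng = np.random.default_rng(0)
        ids = [2, 0, 0] + [5] * 10
        masked, pos = mask_for_mlm(ids, rng, rate=1.0)
        assert set(pos.tolist()) == set(range(3, 13))

    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        ids = [2, 5, 6, 7]
        masked, pos = mask_for_mlm(ids, rng, rate=0.0)
        assert (masked == ids).all() and len(pos) == 0

    def test_seeded_mask_reproducible(self):
        ids = [2] + [5] * 60
        a, pa = mask_for_mlm(ids, np.random.default_rng(9))
        b, pb = mask_for_mlm(ids, np.random.default_rng(9))
        assert (a == b).all() and (pa == pb).all()


class TestCheckpoint:
    def test_save_load_round_trip(self, micro_config, tmp_path):
        model = SparseTransformerClassifier(micro_config, seed=4)
        model.eval_mode()
        ex = _example([2, 5, 6, 7])
        before = model.forward_classify(ex).logits
        model.save_checkpoint(tmp_path / "ckpt")
        loaded = SparseTransformerClassifier.load_checkpoint(tmp_path / "ckpt")
        loaded.eval_mode()
        assert np.allclose(loaded.forward_classify(ex).logits, before)
        assert (tmp_path / "ckpt" / "manifest.json").exists()

    def test_config_mismatch_rejected(self, micro_config):
        model = SparseTransformerClassifier(micro_config, seed=0)
        bad = model.state_dict()
        bad["tok_emb"] = bad["tok_emb"][:, :-1]
        with pytest.raises(ValueError):
            model.load_state_dict(bad)


class TestConfigValidation:
    def test_indivisible_hidden_size_rejected(self):
        with pytest.raises(ValueError):
            SparseAttentionConfig(n_heads=5, hidden_size=32)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            SparseAttentionConfig(n_window_blocks=2)

    def test_preset_file_round_trip(self, tmp_path, micro_config):
        micro_config.save(tmp_path / "m.cfg")
        assert SparseAttentionConfig.from_file(tmp_path / "m.cfg") == micro_config
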