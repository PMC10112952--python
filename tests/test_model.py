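"""Mask-self-attention, the encoder forward pass, loss, and checkpoints."""

import numpy as np
import pytest

from kret.model import (
    MaskTransformer,
    ModelConfig,
    Vocabulary,
    attention_mask,
    gelu,
    init_params,
    load_checkpoint,
    mask_self_attention,
    save_checkpoint,
    softmax,
    weighted_loss,
)


def reference_forward(params, config, ids, soft, seg, visible):
    """Independent re-implementation of the full forward pass.

    Written with explicit per-example, per-head loops and scipy's softmax so
    that it shares no code path with the vectorized encoder.
    """
    from scipy.special import softmax as sp_softmax

    H = config.hidden
    nh = config.heads
    dh = H // nh
    eps = 1e-5

    def ln(x, g, b):
        mu = x.mean(-1, keepdims=True)
        sd = np.sqrt(x.var(-1, keepdims=True) + eps)
        return g * (x - mu) / sd + b

    out = []
    for b_i in range(ids.shape[0]):
        x = (
            params["emb/token"][ids[b_i]]
            + params["emb/pos"][soft[b_i]]
            + params["emb/seg"][seg[b_i]]
        )
        x = ln(x, params["emb/ln_g"], params["emb/ln_b"])
        T = x.shape[0]
        mask = np.where(visible[b_i], 0.0, -1e9)
        for l in range(config.layers):
            lp = f"layer{l}/"
            q = x @ params[lp + "attn/wq"] + params[lp + "attn/bq"]
            k = x @ params[lp + "attn/wk"] + params[lp + "attn/bk"]
            v = x @ params[lp + "attn/wv"] + params[lp + "attn/bv"]
            ctx = np.zeros((T, H))
            for h in range(nh):
                sl = slice(h * dh, (h + 1) * dh)
                scores = q[:, sl] @ k[:, sl].T / np.sqrt(dh) + mask
                ctx[:, sl] = sp_softmax(scores, axis=-1) @ v[:, sl]
            x = ln(x + ctx @ params[lp + "attn/wo"] + params[lp + "attn/bo"],
                   params[lp + "ln1_g"], params[lp + "ln1_b"])
            ff = gelu(x @ params[lp + "ffn/w1"] + params[lp + "ffn/b1"])
            ff = ff @ params[lp + "ffn/w2"] + params[lp + "ffn/b2"]
            x = ln(x + ff, params[lp + "ln2_g"], params[lp + "ln2_b"])
        pooled = np.tanh(x[0] @ params["pooler/w"] + params["pooler/b"])
        out.append(pooled @ params["cls/w"] + params["cls/b"])
    return np.stack(out)


def toy_batch(cfg, seed=0, all_visible=False):
    rng = np.random.default_rng(seed)
    B, T = 3, 7
    ids = rng.integers(0, cfg.vocab_size, (B, T))
    soft = rng.integers(0, T, (B, T))
    seg = np.zeros((B, T), dtype=np.int64)
    if all_visible:
        vis = np.ones((B, T, T), dtype=bool)
    else:
        vis = rng.random((B, T, T)) < 0.6
        vis = vis | vis.transpose(0, 2, 1)
        for b in range(B):
            np.fill_diagonal(vis[b], True)
    return ids, soft, seg, vis


class TestMaskSelfAttention:
    def test_all_visible_equals_plain_attention(self):
        rng = np.random.default_rng(0)
        q, k, v = (rng.normal(size=(5, 4)) for _ in range(3))
        plain = softmax(q @ k.T / 2.0) @ v
        masked = mask_self_attention(q, k, v, np.zeros((5, 5)))
        np.testing.assert_allclose(masked, plain, atol=1e-12)

    def test_hidden_position_gets_negligible_weight(self):
        rng = np.random.default_rng(1)
        q, k, v = (rng.normal(size=(4, 4)) for _ in range(3))
        vis = np.ones((4, 4), dtype=bool)
        vis[1, 3] = vis[3, 1] = False
        mask = attention_mask(vis)
        scores = q @ k.T / 2.0 + mask
        from scipy.special import softmax as sp_softmax

        weights = sp_softmax(scores, axis=-1)
        assert weights[1, 3] < 1e-6 and weights[3, 1] < 1e-6

    def test_block_diagonal_mask_decomposes(self):
        rng = np.random.default_rng(2)
        q, k, v = (rng.normal(size=(6, 4)) for _ in range(3))
        vis = np.zeros((6, 6), dtype=bool)
        vis[:3, :3] = True
        vis[3:, 3:] = True
        out = mask_self_attention(q, k, v, attention_mask(vis))
        top = mask_self_attention(q[:3], k[:3], v[:3], np.zeros((3, 3)))
        bottom = mask_self_attention(q[3:], k[3:], v[3:], np.zeros((3, 3)))
        np.testing.assert_allclose(out, np.vstack([top, bottom]), atol=1e-10)

    def test_all_invisible_row_falls_back_to_self(self):
        vis = np.ones((3, 3), dtype=bool)
        vis[2, :] = False
        mask = attention_mask(vis)
        assert mask[2, 2] == 0.0
        assert (mask[2, [0, 1]] < -1e8).all()

    def test_rows_are_convex_combinations_of_visible_values(self):
        rng = np.random.default_rng(3)
        q, k = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        v = np.eye(4)
        vis = np.eye(4, dtype=bool)
        vis[0, 1] = vis[1, 0] = True
        out = mask_self_attention(q, k, v, attention_mask(vis))
        # row 2 sees only itself -> output is exactly e_2
        np.testing.assert_allclose(out[2], v[2], atol=1e-9)
        # row 0 mixes only positions 0 and 1
        assert abs(out[0, 2]) < 1e-9 and abs(out[0, 3]) < 1e-9


class TestForward:
    @pytest.fixture
    def cfg(self):
        return ModelConfig(
            vocab_size=17, n_labels=3, hidden=8, layers=2, heads=2,
            max_len=16, seed=11, dtype="float64",
        )

    def test_all_visible_matches_standard_encoder(self, cfg):
        model = MaskTransformer(cfg)
        ids, soft, seg, vis = toy_batch(cfg, all_visible=True)
        got = model.forward(ids, soft, seg, vis)
        expect = reference_forward(model.params, cfg, ids, soft, seg, vis)
        np.testing.assert_allclose(got, expect, atol=1e-5)

    def test_masked_forward_matches_independent_oracle(self, cfg):
        model = MaskTransformer(cfg)
        ids, soft, seg, vis = toy_batch(cfg, seed=5)
        got = model.forward(ids, soft, seg, vis)
        expect = reference_forward(model.params, cfg, ids, soft, seg, vis)
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_single_layer_single_head_toy_oracle(self):
        cfg = ModelConfig(
            vocab_size=5, n_labels=2, hidden=4, layers=1, heads=1,
            max_len=8, seed=2, dtype="float64",
        )
        model = MaskTransformer(cfg)
        ids = np.array([[0, 2, 4]])
        soft = np.array([[0, 1, 2]])
        seg = np.zeros((1, 3), dtype=np.int64)
        vis = np.ones((1, 3, 3), dtype=bool)
        got = model.forward(ids, soft, seg, vis)
        expect = reference_forward(model.params, cfg, ids, soft, seg, vis)
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_batch_order_invariance(self, cfg):
        model = MaskTransformer(cfg)
        ids, soft, seg, vis = toy_batch(cfg, seed=9)
        full = model.forward(ids, soft, seg, vis)
        perm = np.array([2, 0, 1])
        permuted = model.forward(ids[perm], soft[perm], seg[perm], vis[perm])
        np.testing.assert_allclose(full[perm], permuted, atol=1e-12)

    def test_determinism_across_runs(self, cfg):
        ids, soft, seg, vis = toy_batch(cfg, seed=4)
        a = MaskTransformer(cfg).forward(ids, soft, seg, vis)
        b = MaskTransformer(cfg).forward(ids, soft, seg, vis)
        np.testing.assert_array_equal(a, b)

    def test_out_of_vocab_id_rejected(self, cfg):
        model = MaskTransformer(cfg)
        ids, soft, seg, vis = toy_batch(cfg)
        ids[0, 0] = cfg.vocab_size
        with pytest.raises(ValueError):
            model.forward(ids, soft, seg, vis)


class TestGradients:
    def test_numeric_gradient_check(self):
        cfg = ModelConfig(
            vocab_size=9, n_labels=2, hidden=8, layers=2, heads=2,
            max_len=8, seed=3, dtype="float64",
        )
        model = MaskTransformer(cfg)
        ids, soft, seg, vis = toy_batch(cfg, seed=8)
        gold = np.array([0, 1, 1])
        w = np.array([1.0, 2.0])

        def loss_of():
            logits = model.forward(ids, soft, seg, vis)
            return weighted_loss(logits, gold, w)

        loss, dlogits = loss_of()
        grads = model.backward(dlogits)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name in ["emb/token", "layer0/attn/wq", "layer1/ffn/w1",
                     "layer0/ln1_g", "pooler/w", "cls/b"]:
            p = model.params[name]
            for flat in rng.integers(0, p.size, 4):
                idx = np.unravel_index(flat, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                up, _ = loss_of()
                p[idx] = orig - eps
                down, _ = loss_of()
                p[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(numeric, abs=1e-6, rel=1e-4)

    def test_invisible_positions_receive_no_value_gradient(self):
        """A token visible only to itself cannot influence other outputs."""
        cfg = ModelConfig(
            vocab_size=9, n_labels=2, hidden=8, layers=1, heads=1,
            max_len=8, seed=3, dtype="float64",
        )
        model = MaskTransformer(cfg)
        B, T = 1, 4
        ids = np.arange(4).reshape(1, 4)
        soft = np.arange(4).reshape(1, 4)
        seg = np.zeros((1, 4), dtype=np.int64)
        vis = np.ones((1, T, T), dtype=bool)
        vis[0, :, 3] = False          # nobody sees position 3
        vis[0, 3, :] = False
        vis[0, 3, 3] = True
        base = model.forward(ids, soft, seg, vis)
        # perturbing token 3's embedding must not change the CLS-position scores
        model.params["emb/token"][3] += 10.0
        shifted = model.forward(ids, soft, seg, vis)
        np.testing.assert_allclose(base, shifted, atol=1e-9)


class TestWeightedLoss:
    def test_uniform_weights_equal_plain_cross_entropy(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(6, 3))
        gold = rng.integers(0, 3, 6)
        loss, _ = weighted_loss(scores, gold, np.ones(3))
        probs = softmax(scores)
        expect = -np.log(probs[np.arange(6), gold]).mean()
        assert loss == pytest.approx(expect)

    def test_doubling_a_weight_doubles_its_contribution(self):
        scores = np.array([[2.0, 0.0], [0.0, 1.5], [1.0, 1.0]])
        gold = np.array([0, 1, 0])
        base, _ = weighted_loss(scores, gold, np.array([1.0, 1.0]))
        doubled, _ = weighted_loss(scores, gold, np.array([1.0, 2.0]))
        probs = softmax(scores)
        class1_term = -np.log(probs[1, 1]) / 3
        assert doubled - base == pytest.approx(class1_term)

    def test_two_class_hand_computation(self):
        scores = np.array([[np.log(3.0), 0.0]])
        gold = np.array([0])
        loss, _ = weighted_loss(scores, gold, np.array([2.0, 1.0]))
        # p(class 0) = 3/4 -> loss = 2 * -log(3/4)
        assert loss == pytest.approx(-2 * np.log(0.75))

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            weighted_loss(np.zeros((1, 2)), np.array([2]), np.ones(2))


class TestCheckpoints:
    def make(self, tmp_path, **overrides):
        kwargs = dict(vocab_size=11, n_labels=2, hidden=8, layers=1, heads=2,
                      max_len=8, seed=5, dtype="float64")
        kwargs.update(overrides)
        return ModelConfig(**kwargs)

    def test_round_trip_bit_identical(self, tmp_path):
        cfg = self.make(tmp_path)
        model = MaskTransformer(cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        params, report = load_checkpoint(path, cfg)
        assert not report["missing"] and not report["ignored"]
        for name, arr in model.params.items():
            np.testing.assert_array_equal(arr, params[name])

    def test_partial_load_reports_missing_head(self, tmp_path):
        cfg = self.make(tmp_path)
        model = MaskTransformer(cfg)
        path = tmp_path / "ckpt.npz"
        trimmed = {k: v for k, v in model.params.items() if not k.startswith("cls/")}
        np.savez(path, **trimmed)
        params, report = load_checkpoint(path, cfg)
        assert set(report["missing"]) == {"cls/w", "cls/b"}
        np.testing.assert_array_equal(params["pooler/w"], model.params["pooler/w"])
        # head falls back to the seeded initialization
        np.testing.assert_array_equal(params["cls/w"], init_params(cfg)["cls/w"])

    def test_shape_mismatch_names_the_tensor(self, tmp_path):
        cfg = self.make(tmp_path)
        model = MaskTransformer(cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        wider = self.make(tmp_path, hidden=16)
        with pytest.raises(ValueError, match="attn/wq|emb/token"):
            load_checkpoint(path, wider)


def test_vocabulary_specials_and_unk():
    v = Vocabulary(["alpha", "beta"])
    assert v["[PAD]"] == 0 and v["[CLS]"] == 1
    assert v["never-seen"] == v["[UNK]"]
    assert v["alpha"] != v["beta"]
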