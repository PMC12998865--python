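import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embedfuse import (
    AlignmentError,
    AttentionFusionConfig,
    EmbeddingSet,
    attention_fuse_apply,
    attention_fuse_fit,
    concat_fuse,
)
from embedfuse import attention as att


def _emb(X, name, split="train", ids=None, labels=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    return EmbeddingSet(
        model_name=name, split=split, X=X,
        sample_ids=np.array([f"s{i}" for i in range(n)]) if ids is None else ids,
        labels=labels,
    )


class TestConcat:
    def test_512_plus_768_gives_1280(self, rng):
        a = _emb(rng.normal(size=(10, 512)), "a")
        b = _emb(rng.normal(size=(10, 768)), "b")
        fused = concat_fuse([a, b])
        assert fused.dim == 1280
        assert fused.blocks == [("a", 0, 512), ("b", 512, 768)]

    def test_single_block_is_identity(self, rng):
        X = rng.normal(size=(5, 7))
        fused = concat_fuse([_emb(X, "solo")])
        np.testing.assert_array_equal(fused.matrix, X)
        assert fused.strategy == "concat"

    def test_row_layout_forced(self):
        fused = concat_fuse([_emb([[1.0, 2.0]], "a"), _emb([[3.0]], "b")])
        np.testing.assert_array_equal(fused.matrix, [[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(fused.sub_block("a"), [[1.0, 2.0]])
        np.testing.assert_array_equal(fused.sub_block("b"), [[3.0]])

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            concat_fuse([])

    def test_misaligned_ids_name_first_mismatch(self, rng):
        a = _emb(rng.normal(size=(3, 2)), "a", ids=np.array(["x", "y", "z"]))
        b = _emb(rng.normal(size=(3, 2)), "b", ids=np.array(["x", "q", "z"]))
        with pytest.raises(AlignmentError, match="row 1.*'y'.*'q'"):
            concat_fuse([a, b])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=6), st.integers(0, 10**6))
    def test_width_additivity_and_subblock_recovery(self, dims, seed):
        """Fused width is the sum of block widths and every sub-block is
        recoverable bitwise from its offsets — fusion loses nothing."""
        rng = np.random.default_rng(seed)
        blocks = [_emb(rng.normal(size=(4, d)), f"m{i}") for i, d in enumerate(dims)]
        fused = concat_fuse(blocks)
        assert fused.dim == sum(dims)
        offsets = [off for _, off, _ in fused.blocks]
        assert offsets == list(np.cumsum([0] + dims[:-1]))
        for blk in blocks:
            np.testing.assert_array_equal(fused.sub_block(blk.model_name), blk.X)

    def test_no_normalisation_by_default(self, rng):
        """Raw feature scales pass through untouched (no fitting, no scaling)."""
        X = rng.normal(size=(6, 3)) * 1e6
        fused = concat_fuse([_emb(X, "big"), _emb(rng.normal(size=(6, 2)), "small")])
        np.testing.assert_array_equal(fused.sub_block("big"), X)

    def test_optional_zscore_flag(self, rng):
        X = rng.normal(loc=5.0, scale=3.0, size=(200, 4))
        fused = concat_fuse([_emb(X, "m")], zscore_blocks=True)
        np.testing.assert_allclose(fused.matrix.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(fused.matrix.std(axis=0), 1, atol=1e-9)


def _brute_force_mhsa(T, Wq, Wk, Wv, Wo, n_heads):
    """Direct per-sample, per-head attention formula; no vectorised reshaping."""
    B, M, P = T.shape
    dh = P // n_heads
    out = np.zeros((B, P))
    for b in range(B):
        Q, K, V = T[b] @ Wq, T[b] @ Wk, T[b] @ Wv
        ctx = np.zeros((M, P))
        for h in range(n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            q, k, v = Q[:, sl], K[:, sl], V[:, sl]
            scores = q @ k.T / math.sqrt(dh)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            A = e / e.sum(axis=1, keepdims=True)
            ctx[:, sl] = A @ v
        out[b] = (ctx @ Wo).mean(axis=0)
    return out


class TestAttention:
    def test_proj_dim_is_heads_times_head_dim(self):
        assert AttentionFusionConfig(n_heads=12, d_head=64).proj_dim == 768
        assert AttentionFusionConfig(n_heads=4, d_head=64).proj_dim == 256
        assert AttentionFusionConfig(n_heads=8, d_head=64).proj_dim == 512

    def test_single_token_identity_maps(self, rng):
        """With one token the softmax has a single key, so attention weight is
        exactly 1 and the pooled output is the value projection of the token."""
        P = 4
        X = rng.normal(size=(5, P))
        Wv = rng.normal(size=(P, P))
        params = {
            "n_heads": 1, "d_head": P,
            "Wp": [np.eye(P)], "bp": [np.zeros(P)],
            "Wq": np.eye(P), "Wk": np.eye(P), "Wv": Wv, "Wo": np.eye(P),
        }
        pooled = att.fuse(params, [X])
        np.testing.assert_allclose(pooled, X @ Wv, atol=1e-12)

    @pytest.mark.parametrize("n_tokens,n_heads,d_head", [(2, 1, 4), (2, 2, 4),
                                                         (3, 2, 2), (3, 1, 8)])
    def test_matches_brute_force_oracle(self, rng, n_tokens, n_heads, d_head):
        P = n_heads * d_head
        T = rng.normal(size=(4, n_tokens, P))
        Wq, Wk, Wv, Wo = (rng.normal(size=(P, P)) for _ in range(4))
        params = {"n_heads": n_heads, "d_head": d_head,
                  "Wq": Wq, "Wk": Wk, "Wv": Wv, "Wo": Wo}
        np.testing.assert_allclose(
            att.attend(params, T),
            _brute_force_mhsa(T, Wq, Wk, Wv, Wo, n_heads),
            atol=1e-6,
        )

    def test_gradients_match_finite_differences(self, rng):
        Xs = [rng.normal(size=(6, 5)), rng.normal(size=(6, 3))]
        y = rng.integers(0, 3, 6)
        params = att.init_params([5, 3], n_heads=2, d_head=4, n_classes=3, seed=1)
        _, grads = att._forward_backward(params, Xs, y)

        def loss_at():
            logits = att.fuse(params, Xs) @ params["Wc"] + params["bc"]
            return att._loss_and_dlogits(logits, y)[0]

        eps = 1e-6
        for key in ("Wq", "Wk", "Wv", "Wo", "Wc"):
            W = params[key]
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in W.shape)
                orig = W[idx]
                W[idx] = orig + eps
                up = loss_at()
                W[idx] = orig - eps
                down = loss_at()
                W[idx] = orig
                assert abs((up - down) / (2 * eps) - grads[key][idx]) < 1e-6

    def _blocks(self, seed=0, n=80, split="train"):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        a = rng.normal(size=(n, 6)) + 2.0 * labels[:, None]
        b = rng.normal(size=(n, 4))
        ids = np.array([f"{split}{i}" for i in range(n)])
        return (
            [_emb(a, "a", split, ids, labels), _emb(b, "b", split, ids, labels)],
            labels,
        )

    def test_fit_apply_shapes_and_determinism(self):
        blocks, labels = self._blocks()
        cfg = AttentionFusionConfig(n_heads=2, d_head=4, epochs=3, seed=3)
        m1 = attention_fuse_fit(blocks, labels, cfg)
        m2 = attention_fuse_fit(blocks, labels, cfg)
        f1 = attention_fuse_apply(m1, blocks)
        f2 = attention_fuse_apply(m2, blocks)
        assert f1.matrix.shape == (80, cfg.proj_dim)
        assert f1.strategy == "self_attention"
        assert f1.blocks == []
        np.testing.assert_array_equal(f1.matrix, f2.matrix)
        assert np.isfinite(f1.matrix).all()

    def test_apply_rejects_reordered_blocks(self):
        blocks, labels = self._blocks()
        cfg = AttentionFusionConfig(n_heads=2, d_head=4, epochs=2, seed=0)
        model = attention_fuse_fit(blocks, labels, cfg)
        with pytest.raises(AlignmentError, match="expected"):
            attention_fuse_apply(model, list(reversed(blocks)))

    def test_training_learns_separable_signal(self):
        """After training, the fused representation linearly separates the
        classes that were separable in one input block."""
        blocks, labels = self._blocks(seed=1, n=200)
        vblocks, vlabels = self._blocks(seed=2, n=100, split="valid")
        cfg = AttentionFusionConfig(n_heads=2, d_head=4, epochs=40,
                                    learning_rate=3e-3, seed=0)
        model = attention_fuse_fit(blocks, labels, cfg, vblocks, vlabels)
        fused = attention_fuse_apply(model, vblocks).matrix
        mu0 = fused[vlabels == 0].mean(axis=0)
        mu1 = fused[vlabels == 1].mean(axis=0)
        proj = fused @ (mu1 - mu0)
        acc = ((proj > np.median(proj)).astype(int) == vlabels).mean()
        assert acc > 0.8
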