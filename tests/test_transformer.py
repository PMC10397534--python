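"""Architecture contracts of the shared drug encoder."""

import numpy as np
import pytest

from combosyn import nn
from combosyn.autodiff import Tensor, no_grad
from combosyn.patching import PAD_ID, PatchConfig, PatchSequence, build_vocab, make_patches, tokenize_smiles
from combosyn.transformer import DrugTransformer, TransformerConfig


def tiny_cfg(**over):
    base = dict(d_model=16, num_heads=2, depth_L=2, mlp_hidden=32,
                dropout=0.0, pooling="cls", vocab_size=12, max_patches=6)
    base.update(over)
    return TransformerConfig(**base)


def seq_for(smiles, vocab, max_patches=6, patch_size=4):
    cfg = PatchConfig(patch_size=patch_size, overlap_ratio=0.5,
                      max_patches=max_patches, vocab=vocab)
    return make_patches(tokenize_smiles(smiles), cfg)


@pytest.fixture()
def vocab():
    return build_vocab(["CCOCNCOCC", "C(Cl)BrNOC"])


class TestEncoding:
    def test_weight_sharing_both_drug_paths_identical(self, vocab):
        enc = DrugTransformer(tiny_cfg(), np.random.default_rng(0))
        enc.eval()
        s = seq_for("CCOCNC", vocab)
        with no_grad():
            out = enc.encode([s, s]).data      # drug-1 path and drug-2 path
        np.testing.assert_array_equal(out[0], out[1])

    def test_inference_deterministic(self, vocab):
        enc = DrugTransformer(tiny_cfg(dropout=0.1), np.random.default_rng(0))
        enc.eval()
        s = seq_for("CCOCNC", vocab)
        with no_grad():
            a = enc.encode([s]).data
            b = enc.encode([s]).data
        np.testing.assert_array_equal(a, b)

    def test_pad_patch_invariance(self, vocab):
        """Appending extra all-PAD patch slots must not change oF."""
        enc = DrugTransformer(tiny_cfg(max_patches=8), np.random.default_rng(1))
        enc.eval()
        short = seq_for("CCOCNCOCC", vocab, max_patches=4)
        padded = PatchSequence(
            patches=np.vstack([short.patches,
                               np.full((4, 4), PAD_ID, dtype=np.int64)]),
            valid_count=short.valid_count,
        )
        trimmed = PatchSequence(patches=padded.patches[:4].copy(),
                                valid_count=short.valid_count)
        # encode both within one config by placing each in its own batch
        with no_grad():
            a = enc.forward(padded.patches[None], padded.pad_mask[None]).data
            b = enc.forward(
                np.vstack([trimmed.patches,
                           np.full((4, 4), PAD_ID, dtype=np.int64)])[None],
                np.concatenate([trimmed.pad_mask, np.ones(4, bool)])[None],
            ).data
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_permutation_invariance_with_zero_positions_mean_pooling(self, vocab):
        cfg = tiny_cfg(pooling="mean")
        enc = DrugTransformer(cfg, np.random.default_rng(2))
        enc.eval()
        enc.pos_emb.data[:] = 0.0
        s = seq_for("CCOCNCOC", vocab)  # 8 tokens -> exactly 3 patches
        assert s.valid_count == 3
        # permute the valid patches only, keeping PAD slots in place
        perm3 = np.array([2, 0, 1, 3, 4, 5])
        permuted = PatchSequence(patches=s.patches[perm3], valid_count=3)
        with no_grad():
            a = enc.encode([s]).data
            b = enc.encode([permuted]).data
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_depth_zero_is_pooled_embedding(self, vocab):
        cfg = tiny_cfg(depth_L=0)
        enc = DrugTransformer(cfg, np.random.default_rng(3))
        enc.eval()
        s = seq_for("CCONC", vocab)
        with no_grad():
            out = enc.encode([s]).data[0]
            emb, _ = enc.embed_patches(s.patches[None], s.pad_mask[None])
        np.testing.assert_allclose(out, emb.data[0, 0], atol=1e-12)


class TestGradients:
    def test_gradient_reaches_every_parameter_group(self, vocab):
        enc = DrugTransformer(tiny_cfg(dropout=0.0), np.random.default_rng(4))
        s1 = seq_for("CCOCNC", vocab)
        s2 = seq_for("C(Cl)BrN", vocab)
        oF = enc.encode([s1, s2])
        (oF * oF).sum().backward()
        params = list(enc.parameters())
        assert len(params) > 10
        for p in params:
            assert p.grad is not None, "parameter missed by backward"
            assert np.all(np.isfinite(p.grad))
        assert any(np.abs(p.grad).max() > 0 for p in params)

    def test_finite_difference_agreement_at_random_points(self, vocab):
        """Autodiff gradient vs central differences on 3 random weights."""
        enc = DrugTransformer(tiny_cfg(depth_L=1, dropout=0.0),
                              np.random.default_rng(5))
        s = seq_for("CCONCOC", vocab)

        def loss_value():
            with no_grad():
                return float((enc.encode([s]) ** 2).sum().data)

        oF = enc.encode([s])
        (oF ** 2).sum().backward()
        rng = np.random.default_rng(0)
        params = list(enc.parameters())
        for p in (params[0], params[3], params[-1]):
            flat = p.data.ravel()
            idx = int(rng.integers(flat.size))
            orig = flat[idx]
            eps = 1e-5
            flat[idx] = orig + eps
            fp = loss_value()
            flat[idx] = orig - eps
            fm = loss_value()
            flat[idx] = orig
            numeric = (fp - fm) / (2 * eps)
            analytic = p.grad.ravel()[idx]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)


def test_attention_mask_rows_sum_to_one():
    rng = np.random.default_rng(6)
    mha = nn.MultiheadAttention(d_model=8, num_heads=2, rng=rng)
    x = Tensor(rng.normal(size=(3, 5, 8)))
    mask = np.zeros((3, 5), dtype=bool)
    mask[1, 2:] = True
    mha(x, key_padding_mask=mask)
    np.testing.assert_allclose(mha.last_attention.sum(axis=-1), 1.0, atol=1e-6)


def test_single_head_attention_matches_hand_computation():
    """S=2, one head, fixed tiny weights: compare with explicit softmax(QK^T/sqrt(d))V."""
    rng = np.random.default_rng(7)
    d = 4
    mha = nn.MultiheadAttention(d_model=d, num_heads=1, rng=rng)
    x = rng.normal(size=(1, 2, d))
    with no_grad():
        out = mha(Tensor(x)).data[0]
    W = {k: getattr(mha, k).weight.data for k in ("wq", "wk", "wv", "wo")}
    b = {k: getattr(mha, k).bias.data for k in ("wq", "wk", "wv", "wo")}
    q = x[0] @ W["wq"] + b["wq"]
    k = x[0] @ W["wk"] + b["wk"]
    v = x[0] @ W["wv"] + b["wv"]
    scores = q @ k.T / np.sqrt(d)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    attn = e / e.sum(axis=-1, keepdims=True)
    expected = (attn @ v) @ W["wo"] + b["wo"]
    np.testing.assert_allclose(out, expected, atol=1e-10)
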