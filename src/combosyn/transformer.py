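"""Transformer feature extractor for drugs (patch sequence -> vector oF).

Architecture: token embedding, patch vectors formed as the mean of each
patch's non-PAD token embeddings, a learned position embedding added per
patch slot, an optional learned classification token, and L pre-norm
encoder blocks (x + MHA(LN(x)), then + MLP(LN(.))) with padded patch
slots masked out of attention.  The pooled output is the classification
token (or the masked mean of patch outputs).  One weight set serves both
drugs of a pair — callers encode drug 1 and drug 2 through the same
object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .patching import PAD_ID, PatchSequence


@dataclass
class TransformerConfig:
    d_model: int = 128
    num_heads: int = 4
    depth_L: int = 4
    mlp_hidden: int = 256
    dropout: float = 0.1
    pooling: str = "cls"          # "cls" | "mean"
    vocab_size: int = 64
    max_patches: int = 32

    def __post_init__(self):
        if self.d_model % self.num_heads != 0:
            raise ValueError("d_model must be divisible by num_heads")
        if self.depth_L < 0:
            raise ValueError("depth_L must be >= 0")
        if self.pooling not in ("cls", "mean"):
            raise ValueError("pooling must be 'cls' or 'mean'")


class EncoderBlock(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator,
                 dropout: nn.Dropout):
        super().__init__()
        self.ln1 = nn.LayerNorm(cfg.d_model)
        self.attn = nn.MultiheadAttention(cfg.d_model, cfg.num_heads, rng)
        self.ln2 = nn.LayerNorm(cfg.d_model)
        self.mlp = nn.MLP([cfg.d_model, cfg.mlp_hidden, cfg.d_model], rng, dropout)
        self.dropout = dropout

    def forward(self, x: Tensor, key_padding_mask: np.ndarray | None) -> Tensor:
        x = x + self.dropout(self.attn(self.ln1(x), key_padding_mask))
        x = x + self.dropout(self.mlp(self.ln2(x)))
        return x


class DrugTransformer(nn.Module):
    """Shared drug encoder: batched patch sequences -> (B, d_model) vectors."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.token_emb = nn.Embedding(cfg.vocab_size, cfg.d_model, rng)
        n_pos = cfg.max_patches + (1 if cfg.pooling == "cls" else 0)
        self.pos_emb = nn.Parameter(rng.normal(0.0, 0.02, size=(n_pos, cfg.d_model)))
        if cfg.pooling == "cls":
            self.cls_token = nn.Parameter(rng.normal(0.0, 0.02, size=(1, cfg.d_model)))
        self.dropout = nn.Dropout(cfg.dropout, rng)
        self.blocks = [EncoderBlock(cfg, rng, self.dropout) for _ in range(cfg.depth_L)]

    # -- patch embedding ------------------------------------------------------

    def embed_patches(self, patches: np.ndarray, pad_mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """(B, M, patch_size) token ids -> (B, S, d_model) with attention mask.

        A patch vector is the mean of its non-PAD token embeddings (zero for
        all-PAD patches); the learned position embedding for the slot is
        added, and the classification token is prepended when configured.
        Returns the embedded sequence and the (B, S) key-padding mask.
        """
        B, M, _ = patches.shape
        tok = self.token_emb(patches)                       # (B, M, P, d)
        nonpad = (patches != PAD_ID).astype(float)[..., None]
        denom = np.maximum(nonpad.sum(axis=2), 1.0)         # avoid 0/0 on all-PAD
        patch_vec = (tok * nonpad).sum(axis=2) / denom      # (B, M, d)
        if self.cfg.pooling == "cls":
            cls = self.cls_token + np.zeros((B, 1, 1))      # broadcast to (B, 1, d)
            x = concat([cls, patch_vec], axis=1)
            mask = np.concatenate([np.zeros((B, 1), dtype=bool), pad_mask], axis=1)
        else:
            x = patch_vec
            mask = pad_mask.copy()
        x = x + self.pos_emb[: x.shape[1]]
        return x, mask

    # -- full encoder ---------------------------------------------------------

    def forward(self, patches: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        x, mask = self.embed_patches(patches, pad_mask)
        x = self.dropout(x)
        for block in self.blocks:
            x = block(x, mask)
        if self.cfg.pooling == "cls":
            return x[:, 0, :]
        keep = (~mask).astype(float)[..., None]
        return (x * keep).sum(axis=1) / keep.sum(axis=1)

    def encode(self, seqs: list[PatchSequence]) -> Tensor:
        """Encode a list of patch sequences into a (B, d_model) batch."""
        patches = np.stack([s.patches for s in seqs])
        pad_mask = np.stack([s.pad_mask for s in seqs])
        return self.forward(patches, pad_mask)
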