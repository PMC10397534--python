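"""Compound--protein interaction network and its one-class losses.

The clustered protein space ``op`` (Pc x n) is passed through multihead
self-attention over the clusters followed by a two-layer MLP that
projects it into the drug representation space, giving ``opm``
(Pc x d_model).  A drug's binding-affinity profile is the sigmoid of the
dot products of its representation oF with every row of opm.

Because only ACTIVE drug--target pairs are known, the interaction task
is trained with a one-class pair of losses: the descriptiveness loss is
the cross-entropy of the active pairs' affinities (no negative
sampling), and the compactness loss is the mean per-dimension population
variance of the drug-feature batch, which keeps the representation from
collapsing the one-class objective trivially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor
from .datasets import DTITable
from .ppi import ClusteredProteinSpace

logger = logging.getLogger(__name__)

_EPS = 1e-7


class ProteinMapper(nn.Module):
    """Self-attention over protein clusters + MLP into drug space (n -> d_model)."""

    def __init__(self, n_in: int, d_model: int, num_heads: int,
                 rng: np.random.Generator, attention: bool = True):
        super().__init__()
        self.attention = attention
        if attention:
            self.attn = nn.MultiheadAttention(n_in, num_heads, rng)
            self.ln = nn.LayerNorm(n_in)
        self.mlp = nn.MLP([n_in, max(n_in, d_model), d_model], rng)

    def forward(self, op: np.ndarray | Tensor) -> Tensor:
        x = op if isinstance(op, Tensor) else Tensor(op)
        if self.attention:
            h = x.reshape(1, *x.shape)           # clusters attend to clusters
            h = h + self.attn(self.ln(h))
            x = h.reshape(*x.shape)
        return self.mlp(x)


def binding_affinity(oF: Tensor, opm: Tensor) -> tuple[Tensor, Tensor]:
    """Per-cluster binding profile of a drug batch.

    logits[b, j] = opm[j] . oF[b];  oB = sigmoid(logits).
    Returns ``(oB, logits)``; both are (B, Pc) for a (B, d_model) oF.
    """
    logits = oF @ opm.transpose(1, 0)
    return logits.sigmoid(), logits


def lift_active_pairs(
    dti: DTITable, space: ClusteredProteinSpace
) -> dict[str, set[int]]:
    """Lift DTI protein labels to protein clusters.

    A cluster is active for a drug if any of its member proteins is a
    known target of that drug.
    """
    lifted: dict[str, set[int]] = {}
    for drug, prot in dti.pairs:
        if prot not in space.assignment:
            continue
        lifted.setdefault(drug, set()).add(space.assignment[prot])
    return lifted


def descriptiveness_loss(
    oB: Tensor, active: list[tuple[int, int]]
) -> Tensor:
    """One-class cross-entropy over active (batch row, cluster) pairs.

    ``-mean log oB[row, cluster]`` over the active pairs; zero when the
    batch contains no active pair (logged).
    """
    if not active:
        logger.debug("descriptiveness_loss: no active pairs in batch")
        return Tensor(0.0)
    rows = np.array([r for r, _ in active])
    cols = np.array([c for _, c in active])
    picked = oB[rows, cols].clip(_EPS, 1.0 - _EPS)
    return -(picked.log().mean())


def compactness_loss(features: Tensor) -> Tensor:
    """Mean over dimensions of the population variance across the batch."""
    B = features.shape[0]
    if B == 1:
        logger.warning("compactness_loss: batch of size 1 has zero variance")
        return Tensor(0.0)
    centred = features - features.mean(axis=0, keepdims=True)
    return (centred * centred).mean()
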