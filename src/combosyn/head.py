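"""Synergy prediction head: fuse drug vectors, binding profiles and cell context.

Two fusion branches feed a final MLP:

* binding branch — z_l = oB_l^T opm, the affinity-weighted sum of mapped
  protein-cluster representations for each drug; concat(z1, z2) -> MLP -> oBM.
* cell branch — the drug's binding profile against the cell's
  cluster-level protein vector.  The literal reading is a scalar dot
  product u_l = oB_l . cell per drug; an elementwise variant
  (oB_l * cell, length Pc per drug) is available behind
  ``cell_branch="elementwise"`` because the scalar carries little
  information.  concat over the two drugs -> MLP -> oCM.

The final MLP consumes concat(oF1, oF2, oBM, oCM) and squashes its
scalar output through a sigmoid, giving the synergy probability o.
The architecture is not symmetric in drug order; ``symmetrize`` averages
the two orderings at inference so evaluation respects the unordered
nature of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat


@dataclass
class HeadConfig:
    d_model: int = 128
    Pc: int = 300
    branch_hidden: tuple[int, int] = (256, 128)
    head_hidden: tuple[int, int] = (256, 64)
    cell_branch: str = "literal"      # "literal" | "elementwise"
    dropout: float = 0.1

    def __post_init__(self):
        if self.cell_branch not in ("literal", "elementwise"):
            raise ValueError("cell_branch must be 'literal' or 'elementwise'")


class SynergyHead(nn.Module):
    def __init__(self, cfg: HeadConfig, rng: np.random.Generator,
                 dropout: nn.Dropout | None = None):
        super().__init__()
        self.cfg = cfg
        h1, h2 = cfg.branch_hidden
        self.binding_mlp = nn.MLP([2 * cfg.d_model, h1, h2], rng, dropout)
        cell_in = 2 if cfg.cell_branch == "literal" else 2 * cfg.Pc
        self.cell_mlp = nn.MLP([cell_in, h1, h2], rng, dropout)
        g1, g2 = cfg.head_hidden
        self.final_mlp = nn.MLP([2 * cfg.d_model + 2 * h2, g1, g2, 1], rng, dropout)

    # -- branches -------------------------------------------------------------

    def binding_branch(self, oB1: Tensor, oB2: Tensor, opm: Tensor) -> Tensor:
        """oBM from the two affinity-weighted protein-representation sums."""
        z1 = oB1 @ opm              # (B, d_model)
        z2 = oB2 @ opm
        return self.binding_mlp(concat([z1, z2], axis=1))

    def cell_branch(self, oB1: Tensor, oB2: Tensor, cell_vec: Tensor) -> Tensor:
        """oCM from the drugs' binding profiles against the cell vector.

        ``cell_vec`` is (B, Pc): the cluster-level protein vector of each
        sample's cell line.
        """
        if self.cfg.cell_branch == "literal":
            u1 = (oB1 * cell_vec).sum(axis=1, keepdims=True)   # (B, 1)
            u2 = (oB2 * cell_vec).sum(axis=1, keepdims=True)
        else:
            u1 = oB1 * cell_vec                                # (B, Pc)
            u2 = oB2 * cell_vec
        return self.cell_mlp(concat([u1, u2], axis=1))

    # -- prediction -----------------------------------------------------------

    def predict_logit(self, oF1: Tensor, oF2: Tensor, oB1: Tensor, oB2: Tensor,
                      opm: Tensor, cell_vec: Tensor) -> Tensor:
        oBM = self.binding_branch(oB1, oB2, opm)
        oCM = self.cell_branch(oB1, oB2, cell_vec)
        logit = self.final_mlp(concat([oF1, oF2, oBM, oCM], axis=1))
        return logit.reshape(logit.shape[0])

    def forward(self, oF1, oF2, oB1, oB2, opm, cell_vec,
                symmetrize: bool = False) -> Tensor:
        """Synergy probability o in (0, 1) per sample.

        With ``symmetrize`` the probabilities of both drug orderings are
        averaged, making the prediction exactly invariant to pair order.
        """
        o = self.predict_logit(oF1, oF2, oB1, oB2, opm, cell_vec).sigmoid()
        if symmetrize:
            o_rev = self.predict_logit(oF2, oF1, oB2, oB1, opm, cell_vec).sigmoid()
            o = (o + o_rev) * 0.5
        return o
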