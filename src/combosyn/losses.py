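"""The multitask loss: synergy BCE, toxic overlap penalty, and the weighted total.

The total training objective is

    L = L_synergy + lambda1 * L_toxic + lambda2 * L_compactness
        + lambda3 * L_descriptive

where L_synergy is the binary cross-entropy of the predicted synergy
probability, L_toxic penalises overlapping binding profiles of the two
drugs of a pair (overlapping exposure is associated with adverse
effects, so safe synergistic pairs should bind disjoint target sets),
and the compactness/descriptiveness pair trains the one-class
drug--target interaction task (see :mod:`combosyn.cpi`).

The toxic penalty operates on sigmoid-squashed affinities and is
normalised by the number of protein clusters, so it is non-negative,
bounded by 1 and scale-free in the cluster count.  All batch reductions
are means.  The printed ablation variants are pure weight masks:
``transformer`` = (0,0,0), ``transformer_toxic`` = (l1,0,0),
``transformer_dti`` = (0,l2,l3), ``full`` = (l1,l2,l3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

_EPS = 1e-7

ABLATION_VARIANTS = ("transformer", "transformer_toxic", "transformer_dti", "full")


@dataclass
class LossWeights:
    toxic: float = 0.5          # lambda1
    compactness: float = 0.5    # lambda2
    descriptive: float = 0.5    # lambda3

    def __post_init__(self):
        if min(self.toxic, self.compactness, self.descriptive) < 0:
            raise ValueError("loss weights must be non-negative")

    def masked(self, variant: str) -> "LossWeights":
        """Weight mask for an ablation variant."""
        if variant == "full":
            return self
        if variant == "transformer":
            return LossWeights(0.0, 0.0, 0.0)
        if variant == "transformer_toxic":
            return LossWeights(self.toxic, 0.0, 0.0)
        if variant == "transformer_dti":
            return LossWeights(0.0, self.compactness, self.descriptive)
        raise ValueError(f"unknown ablation variant {variant!r}")


@dataclass
class LossReport:
    synergy: float
    toxic: float
    compactness: float
    descriptive: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "synergy": self.synergy,
            "toxic": self.toxic,
            "compactness": self.compactness,
            "descriptive": self.descriptive,
            "total": self.total,
        }


def synergy_loss(labels: np.ndarray, predictions: Tensor) -> Tensor:
    """Mean binary cross-entropy of predicted synergy probabilities."""
    labels = np.asarray(labels, dtype=float)
    if labels.size == 0:
        raise ValueError("empty batch")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have the same shape")
    o = predictions.clip(_EPS, 1.0 - _EPS)
    ll = labels * o.log() + (1.0 - labels) * (1.0 - o).log()
    return -(ll.mean())


def toxic_loss(oB1: Tensor, oB2: Tensor) -> Tensor:
    """Mean over the batch of oB1 . oB2 / Pc; zero iff profiles have
    disjoint support."""
    if oB1.shape != oB2.shape:
        raise ValueError("profile shapes differ")
    Pc = oB1.shape[-1]
    per_sample = (oB1 * oB2).sum(axis=-1) * (1.0 / Pc)
    return per_sample.mean()


def total_loss(
    synergy: Tensor,
    toxic: Tensor,
    compactness: Tensor,
    descriptive: Tensor,
    weights: LossWeights,
) -> tuple[Tensor, LossReport]:
    """Lambda-weighted multitask total; returns the tensor and a report."""
    total = (
        synergy
        + weights.toxic * toxic
        + weights.compactness * compactness
        + weights.descriptive * descriptive
    )
    report = LossReport(
        synergy=float(synergy.data),
        toxic=float(toxic.data),
        compactness=float(compactness.data),
        descriptive=float(descriptive.data),
        total=float(total.data),
    )
    return total, report
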