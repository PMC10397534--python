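"""Aggregate model configuration with YAML round-trip.

``ModelConfig`` collects the hyperparameters of every stage — patching,
PPI embedding, transformer encoder, fusion head, loss weights and the
training loop.  ``ModelConfig.tiny()`` is the desk-scale preset used for
synthetic-data experiments and tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .losses import LossWeights


@dataclass
class PatchingConfig:
    patch_size: int = 40
    overlap_ratio: float = 0.5
    max_patches: int = 32


@dataclass
class PPIConfig:
    walk_length: int = 80
    num_walks: int = 10
    p: float = 1.0
    q: float = 1.0
    n: int = 64                 # embedding dimension
    window: int = 5
    epochs: int = 10
    Pc: int = 300               # number of protein clusters


@dataclass
class EncoderConfig:
    d_model: int = 128
    num_heads: int = 4
    depth_L: int = 4
    mlp_hidden: int = 256
    dropout: float = 0.1
    pooling: str = "cls"


@dataclass
class FusionConfig:
    branch_hidden: tuple = (256, 128)
    head_hidden: tuple = (256, 64)
    cell_branch: str = "literal"
    symmetrize: bool = True     # average both drug orderings at inference


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 10
    val_fraction: float = 0.1
    threshold: float = 0.5


@dataclass
class ModelConfig:
    patching: PatchingConfig = field(default_factory=PatchingConfig)
    ppi: PPIConfig = field(default_factory=PPIConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    @classmethod
    def tiny(cls) -> "ModelConfig":
        """Desk-scale preset for synthetic planted-rule data.

        Small patches (synthetic SMILES run 10-60 tokens), a narrow
        two-block encoder, as many protein clusters as the synthetic
        generator plants by default, and the elementwise cell branch,
        which exposes per-cluster cell context to the fusion head.
        """
        return cls(
            patching=PatchingConfig(patch_size=10, overlap_ratio=0.5, max_patches=12),
            ppi=PPIConfig(walk_length=30, num_walks=5, n=32, window=3, epochs=10, Pc=10),
            encoder=EncoderConfig(d_model=32, num_heads=2, depth_L=2,
                                  mlp_hidden=64, dropout=0.1),
            fusion=FusionConfig(branch_hidden=(64, 32), head_hidden=(64, 32),
                                cell_branch="elementwise"),
            training=TrainingConfig(max_epochs=60, patience=8, batch_size=32),
        )

    # -- YAML round-trip ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            kwargs = {k: v for k, v in (sub or {}).items() if k in fields}
            for k, v in kwargs.items():
                if isinstance(v, list):
                    kwargs[k] = tuple(v)
            return klass(**kwargs)

        return cls(
            patching=build(PatchingConfig, d.get("patching")),
            ppi=build(PPIConfig, d.get("ppi")),
            encoder=build(EncoderConfig, d.get("encoder")),
            fusion=build(FusionConfig, d.get("fusion")),
            weights=build(LossWeights, d.get("weights")),
            training=build(TrainingConfig, d.get("training")),
        )

    @classmethod
    def load(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
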