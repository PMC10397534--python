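"""SMILES tokenization and overlapping patch segmentation.

The drug encoder consumes a SMILES string as a sequence of overlapping
token patches.  Tokenization is character-level except that the two-letter
organic-subset halogens (``Cl``, ``Br``) and bracketed atoms (``[NH2+]``)
are emitted as single tokens.  A patch of ``patch_size`` tokens starts
every ``stride`` positions, where::

    stride = patch_size - round_half_up(r * patch_size)

and ``r`` is the overlap ratio, the fraction of a patch shared with its
neighbour.  The final patch is right-aligned so the tail of the sequence
is always covered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_ID = 0
UNK_ID = 1

_TWO_CHAR = ("Cl", "Br")


class TokenizationError(ValueError):
    pass


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemistry-aware character tokens."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(f"unbalanced '[' at position {i} in {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch == "]":
            raise TokenizationError(f"unmatched ']' at position {i} in {smiles!r}")
        else:
            tokens.append(ch)
            i += 1
    return tokens


def build_vocab(smiles_list: list[str]) -> dict[str, int]:
    """Vocabulary over the tokens of a training-split catalog.

    PAD and UNK always occupy ids 0 and 1; remaining tokens are assigned
    ids in sorted order so the mapping is deterministic.
    """
    tokens: set[str] = set()
    for smi in smiles_list:
        tokens.update(tokenize_smiles(smi))
    vocab = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
    for tok in sorted(tokens):
        vocab[tok] = len(vocab)
    return vocab


def save_vocab(vocab: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for tok, idx in sorted(vocab.items(), key=lambda kv: kv[1]):
            fh.write(f"{tok}\t{idx}\n")


def load_vocab(path) -> dict[str, int]:
    vocab: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            tok, idx = line.rstrip("\n").split("\t")
            vocab[tok] = int(idx)
    return vocab


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class PatchConfig:
    patch_size: int = 40
    overlap_ratio: float = 0.5
    max_patches: int = 32
    vocab: dict[str, int] = field(default_factory=lambda: {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID})

    def __post_init__(self):
        if not 0.0 < self.overlap_ratio < 1.0:
            raise ValueError("overlap_ratio must lie in (0, 1)")
        if self.max_patches < 1:
            raise ValueError("max_patches must be >= 1")
        if self.stride < 1:
            raise ValueError(
                f"stride = patch_size - round(r * patch_size) must be >= 1 "
                f"(patch_size={self.patch_size}, r={self.overlap_ratio})"
            )

    @property
    def stride(self) -> int:
        return self.patch_size - _round_half_up(self.overlap_ratio * self.patch_size)


@dataclass
class PatchSequence:
    patches: np.ndarray   # (max_patches, patch_size) int token ids
    valid_count: int

    @property
    def pad_mask(self) -> np.ndarray:
        """Boolean (max_patches,) mask, True for padding-only patch slots."""
        mask = np.ones(self.patches.shape[0], dtype=bool)
        mask[: self.valid_count] = False
        return mask


def patch_starts(n_tokens: int, patch_size: int, stride: int) -> list[int]:
    """Start offsets of the overlapping patches covering ``n_tokens`` tokens.

    Patches begin at 0, stride, 2*stride, ...; when the next full patch
    would overrun the sequence but uncovered tokens remain, one final patch
    is right-aligned at ``n_tokens - patch_size``.
    """
    if n_tokens <= patch_size:
        return [0]
    starts = list(range(0, n_tokens - patch_size + 1, stride))
    if starts[-1] + patch_size < n_tokens:
        starts.append(n_tokens - patch_size)
    return starts


def make_patches(tokens: list[str], cfg: PatchConfig) -> PatchSequence:
    """Segment a token list into padded, overlapping patches of ids."""
    if not tokens:
        raise ValueError("token list is empty")
    ids = np.array([cfg.vocab.get(t, UNK_ID) for t in tokens], dtype=np.int64)
    starts = patch_starts(len(ids), cfg.patch_size, cfg.stride)
    if len(starts) > cfg.max_patches:
        starts = starts[: cfg.max_patches]  # truncate from the right
    out = np.full((cfg.max_patches, cfg.patch_size), PAD_ID, dtype=np.int64)
    for row, s in enumerate(starts):
        chunk = ids[s : s + cfg.patch_size]
        out[row, : len(chunk)] = chunk
    return PatchSequence(patches=out, valid_count=len(starts))


def encode_catalog(smiles_by_drug: dict[str, str], cfg: PatchConfig) -> dict[str, PatchSequence]:
    return {d: make_patches(tokenize_smiles(s), cfg) for d, s in smiles_by_drug.items()}
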