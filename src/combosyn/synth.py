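"""Synthetic five-file study generator with a planted, recoverable synergy rule.

The generator emulates the structure the synergy model assumes: proteins
form interaction modules (clusters), drugs bind a small set of modules,
cells expose a small set of active modules, and a drug pair is
synergistic in a cell iff

* both drugs hit at least one of the cell's active modules
  (complementary exposure of the disease module), and
* the two drugs' target-module sets are disjoint
  (no overlapping exposure, the mechanism the toxic penalty encodes).

Observed labels flip with probability ``label_noise``.  The five output
tables pass :func:`combosyn.datasets.assemble_bundle` unchanged, and the
ground truth is persisted so recovery tests can score against the clean
rule.

SMILES strings are drawn from a small linear grammar (alkane/ether/amine
chains with halide substituents) — valid, tokenizer-closed molecules,
one unique string per drug; they are identifiers with realistic token
statistics, not real chemistry.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .datasets import (
    CellProteinMatrix,
    DatasetBundle,
    DrugCatalog,
    DTITable,
    PPIGraph,
    SynergySample,
    assemble_bundle,
    write_cell_protein_matrix,
    write_drug_catalog,
    write_dti_table,
    write_ppi_edges,
    write_synergy_table,
)

POSITIVE_BAND = (0.40, 0.60)


@dataclass
class SynthConfig:
    n_drugs: int = 40
    n_proteins: int = 200
    n_cells: int = 8
    n_clusters_true: int = 10
    n_samples: int = 2000
    targets_per_drug: int = 2
    active_clusters_per_cell: int = 3
    label_noise: float = 0.05
    within_edge_prob: float = 0.3
    between_edge_prob: float = 0.01
    cpc_noise_sd: float = 0.0     # optional Gaussian noise on the binary Cpc
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 2 * self.n_clusters_true:
            raise ValueError("need n_proteins >= 2 * n_clusters_true")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.targets_per_drug < 1:
            raise ValueError("targets_per_drug must be >= 1")


@dataclass
class GroundTruth:
    drug_targets: dict[str, list[int]]
    cell_active: dict[str, list[int]]
    protein_cluster: dict[str, int]
    clean_labels: list[int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _drug_id(i: int) -> str:
    return f"D{i:03d}"


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def _cell_id(i: int) -> str:
    return f"CL{i:02d}"


def generate_ppi(cfg: SynthConfig, rng: np.random.Generator) -> tuple[PPIGraph, dict[str, int]]:
    """Planted-partition PPI graph; proteins assigned round-robin to clusters."""
    protein_cluster = {
        _protein_id(i): i % cfg.n_clusters_true for i in range(cfg.n_proteins)
    }
    g = nx.Graph()
    g.add_nodes_from(protein_cluster)
    proteins = list(protein_cluster)
    for i, j in itertools.combinations(range(cfg.n_proteins), 2):
        same = protein_cluster[proteins[i]] == protein_cluster[proteins[j]]
        prob = cfg.within_edge_prob if same else cfg.between_edge_prob
        if rng.random() < prob:
            g.add_edge(proteins[i], proteins[j])
    return PPIGraph(graph=g), protein_cluster


_CHAIN_ATOMS = ["C", "C", "C", "O", "N"]      # carbon-rich linear chains
_SUBSTITUENTS = ["Cl", "Br", "F", "O", "N"]


def _random_smiles(rng: np.random.Generator) -> str:
    """One linear-grammar SMILES, 10-60 tokens, balanced parentheses."""
    n_tokens = int(rng.integers(10, 61))
    parts: list[str] = []
    count = 0
    while count < n_tokens:
        atom = _CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))]
        parts.append(atom)
        count += 1
        # a branch "(X)" costs 3 tokens and must start from a carbon
        if atom == "C" and count + 3 <= n_tokens and rng.random() < 0.25:
            sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            parts.extend(["(", sub, ")"])
            count += 3
    return "".join(parts)


def generate_drugs(
    cfg: SynthConfig, rng: np.random.Generator, protein_cluster: dict[str, int]
) -> tuple[DrugCatalog, DTITable, dict[str, list[int]]]:
    """Drug catalog with unique SMILES, target clusters, and the DTI table.

    Each drug is assigned ``targets_per_drug`` distinct true clusters; the
    DTI table records one randomly chosen member protein per targeted
    cluster (active pairs only).
    """
    members: dict[int, list[str]] = {k: [] for k in range(cfg.n_clusters_true)}
    for prot, k in protein_cluster.items():
        members[k].append(prot)

    entries: dict[str, str] = {}
    seen: set[str] = set()
    drug_targets: dict[str, list[int]] = {}
    pairs: set[tuple[str, str]] = set()
    for i in range(cfg.n_drugs):
        d = _drug_id(i)
        smi = _random_smiles(rng)
        while smi in seen:
            smi = _random_smiles(rng)
        seen.add(smi)
        entries[d] = smi
        targets = rng.choice(cfg.n_clusters_true, size=cfg.targets_per_drug,
                             replace=False)
        drug_targets[d] = sorted(int(t) for t in targets)
        for t in drug_targets[d]:
            prot = members[t][rng.integers(len(members[t]))]
            pairs.add((d, prot))
    return DrugCatalog(entries=entries), DTITable(pairs=pairs), drug_targets


def clean_label(
    targets1: set[int], targets2: set[int], active: set[int]
) -> int:
    """Planted rule: synergy iff both drugs hit the cell's active modules
    with mutually disjoint target sets (complementary exposure)."""
    hit1 = bool(targets1 & active)
    hit2 = bool(targets2 & active)
    disjoint = not (targets1 & targets2)
    return int(hit1 and hit2 and disjoint)


def generate_cells_and_labels(
    cfg: SynthConfig,
    rng: np.random.Generator,
    protein_cluster: dict[str, int],
    drug_targets: dict[str, list[int]],
) -> tuple[CellProteinMatrix, list[SynergySample], GroundTruth]:
    """Cells, the binary Cpc matrix and label-balanced synergy samples.

    Triples are drawn uniformly over unordered drug pairs x cells; a draw
    is rejected whenever accepting it would push its class above 60% of
    the requested sample count, which bounds the positive rate to the
    40-60% band.
    """
    cell_active = {
        _cell_id(c): sorted(
            int(k) for k in rng.choice(cfg.n_clusters_true,
                                       size=cfg.active_clusters_per_cell,
                                       replace=False)
        )
        for c in range(cfg.n_cells)
    }
    proteins = sorted(protein_cluster)
    cells = sorted(cell_active)
    matrix = np.zeros((len(proteins), len(cells)))
    for i, p in enumerate(proteins):
        for j, c in enumerate(cells):
            if protein_cluster[p] in cell_active[c]:
                matrix[i, j] = 1.0
    if cfg.cpc_noise_sd > 0:
        matrix = matrix + rng.normal(0.0, cfg.cpc_noise_sd, size=matrix.shape)
    cpc = CellProteinMatrix(matrix=matrix, protein_index=proteins, cell_index=cells)

    drugs = sorted(drug_targets)
    pair_list = list(itertools.combinations(range(len(drugs)), 2))
    cap = int(np.ceil(0.6 * cfg.n_samples))
    samples: list[SynergySample] = []
    clean: list[int] = []
    n_pos = n_neg = 0
    max_draws = 200 * cfg.n_samples
    draws = 0
    while len(samples) < cfg.n_samples:
        draws += 1
        if draws > max_draws:
            raise ValueError(
                "could not reach the 40-60% positive band; the configuration "
                "admits too few samples of one class — adjust targets_per_drug "
                "or active_clusters_per_cell"
            )
        i, j = pair_list[rng.integers(len(pair_list))]
        c = cells[rng.integers(len(cells))]
        d1, d2 = drugs[i], drugs[j]
        y = clean_label(set(drug_targets[d1]), set(drug_targets[d2]),
                        set(cell_active[c]))
        if (y == 1 and n_pos >= cap) or (y == 0 and n_neg >= cap):
            continue
        observed = y if rng.random() >= cfg.label_noise else 1 - y
        # score on a ZIP-like scale consistent with threshold-10 binarisation
        score = 10.0 + (5.0 if observed else -5.0) + rng.normal(0, 1.0)
        samples.append(SynergySample(d1, d2, c, float(score), int(observed)))
        clean.append(y)
        n_pos += y
        n_neg += 1 - y

    truth = GroundTruth(
        drug_targets=drug_targets,
        cell_active=cell_active,
        protein_cluster=dict(protein_cluster),
        clean_labels=clean,
    )
    return cpc, samples, truth


def generate_dataset(cfg: SynthConfig) -> tuple[DatasetBundle, GroundTruth]:
    """Generate all five components and assemble them into a validated bundle."""
    rng = np.random.default_rng(cfg.seed)
    ppi, protein_cluster = generate_ppi(cfg, rng)
    catalog, dti, drug_targets = generate_drugs(cfg, rng, protein_cluster)
    cpc, samples, truth = generate_cells_and_labels(cfg, rng, protein_cluster, drug_targets)
    bundle = assemble_bundle(samples, catalog, ppi, cpc, dti)
    return bundle, truth


def write_dataset(cfg: SynthConfig, out_dir) -> tuple[DatasetBundle, GroundTruth]:
    """Generate and write the five input files plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, truth = generate_dataset(cfg)
    write_synergy_table(bundle.samples, out / "samples.csv")
    write_drug_catalog(bundle.catalog, out / "drugs.csv")
    write_ppi_edges(bundle.ppi, out / "ppi.tsv")
    write_cell_protein_matrix(bundle.cpc, out / "cpc.csv")
    write_dti_table(bundle.dti, out / "dti.csv")
    truth.to_json(out / "ground_truth.json")
    return bundle, truth
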