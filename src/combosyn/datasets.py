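"""Loading, validation and indexing of the five synergy-study input tables.

The study consumes five plain-text files:

* a synergy triple table (drug1, drug2, cell line, continuous score and/or
  binary label),
* a drug catalog mapping drug id to SMILES,
* a protein--protein interaction (PPI) edge list,
* a cell--protein association matrix ``Cpc`` (proteins x cells),
* a drug--target interaction (DTI) table of known ACTIVE pairs.

:func:`assemble_bundle` cross-validates the five components and builds
contiguous, sorted-id integer indices for drugs, proteins and cells, which
every downstream module relies on.

Continuous synergy scores (e.g. ZIP) are binarised with a strict
``score > threshold`` rule; the conventional threshold for ZIP scores is 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SYNERGY_THRESHOLD = 10.0


class SchemaError(ValueError):
    """A loaded file does not match its expected schema."""


class ValidationError(ValueError):
    """Cross-references between loaded components do not resolve."""


@dataclass(frozen=True)
class SynergySample:
    drug1_id: str
    drug2_id: str
    cell_id: str
    score: float
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class DrugCatalog:
    entries: dict[str, str]

    def __post_init__(self):
        for drug, smiles in self.entries.items():
            if not smiles:
                raise SchemaError(f"empty SMILES for drug {drug!r}")

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def __getitem__(self, drug_id: str) -> str:
        return self.entries[drug_id]


@dataclass
class PPIGraph:
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class CellProteinMatrix:
    matrix: np.ndarray          # shape (P, C)
    protein_index: list[str]
    cell_index: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        P, C = self.matrix.shape
        if len(self.protein_index) != P or len(self.cell_index) != C:
            raise SchemaError("matrix shape does not match index lengths")
        if len(set(self.protein_index)) != P:
            raise SchemaError("duplicate protein ids in Cpc rows")
        if len(set(self.cell_index)) != C:
            raise SchemaError("duplicate cell ids in Cpc columns")


@dataclass
class DTITable:
    pairs: set[tuple[str, str]]  # (drug_id, protein_id), active interactions only

    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def proteins(self) -> set[str]:
        return {p for _, p in self.pairs}


@dataclass
class DatasetBundle:
    samples: list[SynergySample]
    catalog: DrugCatalog
    ppi: PPIGraph
    cpc: CellProteinMatrix
    dti: DTITable
    drug_index: dict[str, int]
    protein_index: dict[str, int]
    cell_index: dict[str, int]
    report: dict = field(default_factory=dict)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_index)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_index)

    @property
    def n_cells(self) -> int:
        return len(self.cell_index)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)


# ---------------------------------------------------------------------------
# loaders


def _read_table(path, **kwargs) -> pd.DataFrame:
    """Read a CSV/TSV with delimiter auto-detected between comma and tab."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, **kwargs)
    if df.empty:
        raise SchemaError(f"{path}: file contains no data rows")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def load_synergy_table(
    path,
    score_column: str = "score",
    threshold: float = DEFAULT_SYNERGY_THRESHOLD,
    label_column: str = "label",
) -> list[SynergySample]:
    """Load synergy triples; derive labels from scores when no label column.

    Binarisation is strict: ``label = 1`` iff ``score > threshold``, so a
    score exactly at the threshold is negative.  Rows with unparseable
    scores abort the load (no partial return), reporting 1-based data line
    numbers.
    """
    df = _read_table(path)
    required = ["drug1", "drug2", "cell"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    has_label = label_column in df.columns
    has_score = score_column in df.columns
    if not has_label and not has_score:
        raise SchemaError(
            f"{path}: needs a {label_column!r} column or a {score_column!r} column"
        )

    bad_lines: list[int] = []
    scores = np.full(len(df), np.nan)
    if has_score:
        for i, raw in enumerate(df[score_column]):
            try:
                scores[i] = float(raw)
            except (TypeError, ValueError):
                bad_lines.append(i + 1)
    if bad_lines:
        raise SchemaError(
            f"{path}: unparseable score on data line(s) {bad_lines} "
            f"(column {score_column!r})"
        )

    if has_label:
        labels = []
        for i, raw in enumerate(df[label_column]):
            v = str(raw).strip()
            if v not in ("0", "1"):
                raise SchemaError(f"{path}: bad label {raw!r} on data line {i + 1}")
            labels.append(int(v))
    else:
        labels = (scores > threshold).astype(int).tolist()

    samples = [
        SynergySample(
            drug1_id=str(r.drug1).strip(),
            drug2_id=str(r.drug2).strip(),
            cell_id=str(r.cell).strip(),
            score=float(scores[i]) if has_score else float("nan"),
            label=labels[i],
        )
        for i, r in enumerate(df.itertuples(index=False))
    ]
    n_self = sum(s.drug1_id == s.drug2_id for s in samples)
    if n_self:
        logger.warning("%d self-pair sample(s) (drug1 == drug2) retained", n_self)
    return samples


def load_ppi_edges(path) -> PPIGraph:
    """Load an undirected PPI edge list from a two-column TSV/CSV."""
    df = _read_table(path, header=None)
    if df.shape[1] < 2 or df.iloc[:, :2].isna().any().any():
        raise SchemaError(f"{path}: expected two id columns on every row")
    g = nx.Graph()
    n_self = 0
    for a, b in df.iloc[:, :2].itertuples(index=False):
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            n_self += 1
            g.add_node(a)
            continue
        g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loop(s) from PPI edge list", n_self)
    return PPIGraph(graph=g)


def load_cell_protein_matrix(path) -> CellProteinMatrix:
    """Load Cpc: header row = cell ids, first column = protein ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    proteins = [str(p).strip() for p in df.index]
    cells = [str(c).strip() for c in df.columns]
    try:
        matrix = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric matrix entry ({exc})") from exc
    return CellProteinMatrix(matrix=matrix, protein_index=proteins, cell_index=cells)


def load_dti_table(path) -> DTITable:
    df = _read_table(path)
    for col in ("drug", "protein"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    pairs = {
        (str(d).strip(), str(p).strip())
        for d, p in zip(df["drug"], df["protein"])
    }
    return DTITable(pairs=pairs)


def load_drug_catalog(path) -> DrugCatalog:
    df = _read_table(path)
    for col in ("drug", "smiles"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    entries: dict[str, str] = {}
    for d, s in zip(df["drug"], df["smiles"]):
        d = str(d).strip()
        if d in entries:
            raise SchemaError(f"{path}: duplicate drug id {d!r}")
        entries[d] = str(s).strip()
    return DrugCatalog(entries=entries)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the loaders)


def write_synergy_table(samples: list[SynergySample], path) -> None:
    pd.DataFrame(
        {
            "drug1": [s.drug1_id for s in samples],
            "drug2": [s.drug2_id for s in samples],
            "cell": [s.cell_id for s in samples],
            "score": [s.score for s in samples],
            "label": [s.label for s in samples],
        }
    ).to_csv(path, index=False)


def write_ppi_edges(ppi: PPIGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in ppi.graph.edges):
            fh.write(f"{a}\t{b}\n")


def write_cell_protein_matrix(cpc: CellProteinMatrix, path) -> None:
    pd.DataFrame(cpc.matrix, index=cpc.protein_index, columns=cpc.cell_index).to_csv(path)


def write_dti_table(dti: DTITable, path) -> None:
    pd.DataFrame(sorted(dti.pairs), columns=["drug", "protein"]).to_csv(path, index=False)


def write_drug_catalog(catalog: DrugCatalog, path) -> None:
    pd.DataFrame(
        sorted(catalog.entries.items()), columns=["drug", "smiles"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# assembly


def assemble_bundle(
    samples: list[SynergySample],
    catalog: DrugCatalog,
    ppi: PPIGraph,
    cpc: CellProteinMatrix,
    dti: DTITable,
) -> DatasetBundle:
    """Cross-validate the five components and build contiguous index maps.

    The protein universe is the intersection of PPI nodes and Cpc rows;
    proteins present in only one source are dropped and reported.  DTI pairs
    whose protein falls outside the universe are dropped likewise.  Index
    maps use sorted-id order so they are deterministic given the same files.
    """
    sample_drugs = {s.drug1_id for s in samples} | {s.drug2_id for s in samples}
    unknown_drugs = sorted(sample_drugs - set(catalog.entries))
    if unknown_drugs:
        raise ValidationError(f"samples reference unknown drug id(s): {unknown_drugs}")
    unknown_cells = sorted(
        {s.cell_id for s in samples} - set(cpc.cell_index)
    )
    if unknown_cells:
        raise ValidationError(f"samples reference unknown cell id(s): {unknown_cells}")
    dti_unknown_drugs = sorted(dti.drugs() - set(catalog.entries))
    if dti_unknown_drugs:
        raise ValidationError(
            f"DTI table references unknown drug id(s): {dti_unknown_drugs}"
        )

    ppi_nodes = set(ppi.graph.nodes)
    cpc_proteins = set(cpc.protein_index)
    universe = ppi_nodes & cpc_proteins
    dropped_ppi_only = sorted(ppi_nodes - universe)
    dropped_cpc_only = sorted(cpc_proteins - universe)
    if not universe:
        raise ValidationError("PPI nodes and Cpc rows share no proteins")

    dropped_dti = sorted(p for p in dti.proteins() if p not in universe)
    kept_pairs = {(d, p) for d, p in dti.pairs if p in universe}

    if dropped_ppi_only or dropped_cpc_only or dropped_dti:
        logger.info(
            "protein reconciliation: %d PPI-only, %d Cpc-only, %d DTI protein id(s) dropped",
            len(dropped_ppi_only), len(dropped_cpc_only), len(dropped_dti),
        )

    # restrict components to the universe
    sub = ppi.graph.subgraph(universe).copy()
    keep_rows = [i for i, p in enumerate(cpc.protein_index) if p in universe]
    cpc_r = CellProteinMatrix(
        matrix=cpc.matrix[keep_rows],
        protein_index=[cpc.protein_index[i] for i in keep_rows],
        cell_index=list(cpc.cell_index),
    )

    drug_index = {d: i for i, d in enumerate(sorted(catalog.entries))}
    protein_index = {p: i for i, p in enumerate(sorted(universe))}
    cell_index = {c: i for i, c in enumerate(sorted(cpc.cell_index))}

    n_self = sum(s.drug1_id == s.drug2_id for s in samples)
    report = {
        "dropped_ppi_only_proteins": dropped_ppi_only,
        "dropped_cpc_only_proteins": dropped_cpc_only,
        "dropped_dti_pairs": len(dti.pairs) - len(kept_pairs),
        "self_pair_samples": n_self,
    }
    return DatasetBundle(
        samples=list(samples),
        catalog=catalog,
        ppi=PPIGraph(graph=sub),
        cpc=cpc_r,
        dti=DTITable(pairs=kept_pairs),
        drug_index=drug_index,
        protein_index=protein_index,
        cell_index=cell_index,
        report=report,
    )


def load_bundle_from_config(paths: dict, score_column: str = "score",
                            threshold: float = DEFAULT_SYNERGY_THRESHOLD) -> DatasetBundle:
    """Build a bundle from a mapping with keys samples/catalog/ppi/cpc/dti."""
    return assemble_bundle(
        samples=load_synergy_table(paths["samples"], score_column=score_column,
                                   threshold=threshold),
        catalog=load_drug_catalog(paths["catalog"]),
        ppi=load_ppi_edges(paths["ppi"]),
        cpc=load_cell_protein_matrix(paths["cpc"]),
        dti=load_dti_table(paths["dti"]),
    )
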