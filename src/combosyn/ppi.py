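"""Clustered protein representation from the PPI graph.

Pipeline: second-order biased random walks over the interaction graph
(the node2vec scheme: unnormalised weight 1/p for stepping back to the
previous node, 1 for moving to a common neighbour, 1/q for moving
outward), a skip-gram embedding with negative sampling trained on the
walk corpus, and k-means over the node vectors.  The protein space is
thereby reduced to ``Pc`` clusters; the cluster matrix ``op`` (Pc x n)
holds the centroid of each cluster's member embeddings, and the
cell--protein matrix is aggregated to cluster level by the mean of
member rows.

The skip-gram trainer is a vectorised numpy implementation (sigmoid
binary objective on positive centre/context pairs plus sampled
negatives), single-threaded and fully seeded, so embeddings are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .datasets import CellProteinMatrix, PPIGraph

logger = logging.getLogger(__name__)


@dataclass
class WalkParams:
    walk_length: int = 80
    num_walks: int = 10
    p: float = 1.0
    q: float = 1.0
    seed: int = 0


@dataclass
class WalkCorpus:
    walks: list[list[str]]
    params: WalkParams


@dataclass
class NodeEmbeddings:
    matrix: np.ndarray          # (P, n)
    protein_index: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ClusteredProteinSpace:
    op: np.ndarray                      # (Pc, n) cluster centroids
    assignment: dict[str, int]          # protein id -> cluster
    Pc: int
    cpc_clustered: np.ndarray           # (Pc, C) mean of member Cpc rows
    cluster_sizes: np.ndarray           # (Pc,) member counts

    def lift_proteins(self, proteins) -> set[int]:
        """Map a collection of protein ids to the set of their clusters."""
        return {self.assignment[p] for p in proteins if p in self.assignment}


def generate_walks(
    ppi: PPIGraph,
    walk_length: int = 80,
    num_walks: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> WalkCorpus:
    """Biased second-order random walks from every node of the graph.

    With p = q = 1 this reduces to a first-order uniform random walk.
    Isolated nodes yield constant walks of their own id.
    """
    if walk_length < 1 or num_walks < 1:
        raise ValueError("walk_length and num_walks must be >= 1")
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    g = ppi.graph
    if g.number_of_nodes() == 0:
        raise ValueError("PPI graph is empty")
    nodes = sorted(g.nodes)
    nbrs = {v: sorted(g.neighbors(v)) for v in nodes}
    nbr_sets = {v: set(ns) for v, ns in nbrs.items()}
    rng = np.random.default_rng(seed)

    walks: list[list[str]] = []
    for _ in range(num_walks):
        order = rng.permutation(len(nodes))
        for idx in order:
            start = nodes[idx]
            walk = [start]
            if not nbrs[start]:
                walk = [start] * walk_length
                walks.append(walk)
                continue
            while len(walk) < walk_length:
                cur = walk[-1]
                candidates = nbrs[cur]
                if not candidates:
                    break
                if len(walk) == 1 or (p == 1.0 and q == 1.0):
                    nxt = candidates[rng.integers(len(candidates))]
                else:
                    prev = walk[-2]
                    prev_nbrs = nbr_sets[prev]
                    w = np.empty(len(candidates))
                    for i, x in enumerate(candidates):
                        if x == prev:
                            w[i] = 1.0 / p
                        elif x in prev_nbrs:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / q
                    w /= w.sum()
                    nxt = candidates[rng.choice(len(candidates), p=w)]
                walk.append(nxt)
            walks.append(walk)
    return WalkCorpus(
        walks=walks,
        params=WalkParams(walk_length, num_walks, p, q, seed),
    )


def embed_nodes(
    corpus: WalkCorpus,
    n: int = 64,
    window: int = 5,
    epochs: int = 10,
    seed: int = 0,
    negatives: int = 5,
    lr: float = 0.2,
    batch_size: int = 512,
) -> NodeEmbeddings:
    """Skip-gram with negative sampling over the walk corpus.

    Centre/context pairs are harvested from a symmetric window and shuffled
    once per epoch; negatives are drawn from the unigram distribution
    raised to 3/4.  The learning rate decays linearly to 10% of ``lr``.
    """
    if not corpus.walks:
        raise ValueError("walk corpus is empty")
    if n < 2:
        raise ValueError("embedding dimension must be >= 2")
    vocab = sorted({v for walk in corpus.walks for v in walk})
    v2i = {v: i for i, v in enumerate(vocab)}
    P = len(vocab)

    centers, contexts = [], []
    counts = np.zeros(P)
    for walk in corpus.walks:
        idxs = [v2i[v] for v in walk]
        L = len(idxs)
        for pos, c in enumerate(idxs):
            counts[c] += 1
            lo, hi = max(0, pos - window), min(L, pos + window + 1)
            for j in range(lo, hi):
                if j != pos:
                    centers.append(c)
                    contexts.append(idxs[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)

    rng = np.random.default_rng(seed)
    W = (rng.random((P, n)) - 0.5) / n   # input (centre) vectors
    C = np.zeros((P, n))                 # output (context) vectors
    noise = counts**0.75
    noise /= noise.sum()

    n_pairs = len(centers)
    total_steps = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        perm = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = perm[lo : lo + batch_size]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(P, size=(len(sel), negatives), p=noise)
            cur_lr = lr * max(0.1, 1.0 - step / total_steps)
            step += 1

            wc = W[c]                                    # (B, n)
            co = C[o]                                    # (B, n)
            cn = C[neg]                                  # (B, K, n)
            # clamp scores as in word2vec to keep the update bounded
            score_pos = np.clip((wc * co).sum(axis=1), -6.0, 6.0)
            score_neg = np.clip((cn @ wc[:, :, None])[..., 0], -6.0, 6.0)
            s_pos = 1.0 / (1.0 + np.exp(-score_pos))     # (B,)
            s_neg = 1.0 / (1.0 + np.exp(-score_neg))     # (B, K)

            g_pos = (s_pos - 1.0)[:, None]               # d/d(score)
            g_neg = s_neg[..., None]                     # (B, K, 1)
            grad_wc = g_pos * co + (g_neg * cn).sum(axis=1)

            # apply the MEAN update per node: a node occurring k times in
            # the batch must not receive a k-fold step, or training
            # diverges for corpora much larger than the vocabulary
            dW = np.zeros_like(W)
            cntW = np.zeros(P)
            np.add.at(dW, c, grad_wc)
            np.add.at(cntW, c, 1.0)
            dC = np.zeros_like(C)
            cntC = np.zeros(P)
            np.add.at(dC, o, g_pos * wc)
            np.add.at(cntC, o, 1.0)
            np.add.at(dC, neg.ravel(), (g_neg * wc[:, None, :]).reshape(-1, n))
            np.add.at(cntC, neg.ravel(), 1.0)
            W -= cur_lr * dW / np.maximum(cntW, 1.0)[:, None]
            C -= cur_lr * dC / np.maximum(cntC, 1.0)[:, None]

    zero_nodes = [vocab[i] for i in range(P) if counts[i] == 0]
    if zero_nodes:
        W[[v2i[v] for v in zero_nodes]] = 0.0
        logger.warning("%d node(s) absent from corpus embedded as zero", len(zero_nodes))
    return NodeEmbeddings(matrix=W, protein_index=vocab)


def cluster_proteins(
    emb: NodeEmbeddings,
    cpc: CellProteinMatrix,
    Pc: int = 300,
    seed: int = 0,
) -> ClusteredProteinSpace:
    """k-means the node embeddings into Pc clusters and aggregate Cpc.

    Uses k-means++ initialisation with 10 restarts.  ``cpc_clustered`` row
    j is the mean of the Cpc rows of cluster j's member proteins, so the
    size-weighted column sums of the clustered matrix equal those of Cpc.
    """
    P = emb.matrix.shape[0]
    if not 2 <= Pc <= P:
        raise ValueError(f"Pc must lie in [2, {P}], got {Pc}")
    km = KMeans(n_clusters=Pc, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(emb.matrix)
    assignment = {prot: int(lab) for prot, lab in zip(emb.protein_index, labels)}

    row_of = {prot: i for i, prot in enumerate(cpc.protein_index)}
    C = cpc.matrix.shape[1]
    cpc_clustered = np.zeros((Pc, C))
    sizes = np.zeros(Pc, dtype=int)
    for prot, lab in assignment.items():
        if prot in row_of:
            cpc_clustered[lab] += cpc.matrix[row_of[prot]]
            sizes[lab] += 1
    nonzero = sizes > 0
    cpc_clustered[nonzero] /= sizes[nonzero, None]
    return ClusteredProteinSpace(
        op=km.cluster_centers_.astype(float),
        assignment=assignment,
        Pc=Pc,
        cpc_clustered=cpc_clustered,
        cluster_sizes=sizes,
    )


def write_protein_space(space: ClusteredProteinSpace, out_dir) -> None:
    """Persist op, the assignment map and the clustered Cpc as TSVs."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(space.op).to_csv(out / "op.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(
        sorted(space.assignment.items()), columns=["protein", "cluster"]
    ).to_csv(out / "assignment.tsv", sep="\t", index=False)
    pd.DataFrame(space.cpc_clustered).to_csv(
        out / "cpc_clustered.tsv", sep="\t", header=False, index=False
    )
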