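"""Random walks, skip-gram embedding and protein clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.cluster import KMeans

from combosyn.datasets import CellProteinMatrix, PPIGraph
from combosyn import ppi


def graph_of(edges, extra_nodes=()):
    g = nx.Graph(edges)
    g.add_nodes_from(extra_nodes)
    return PPIGraph(graph=g)


class TestWalks:
    def test_isolated_node_constant_walk(self):
        corpus = ppi.generate_walks(graph_of([], ["v"]), walk_length=5, num_walks=3)
        assert len(corpus.walks) == 3
        assert all(w == ["v"] * 5 for w in corpus.walks)

    def test_all_steps_are_edges(self):
        g = graph_of([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        corpus = ppi.generate_walks(g, walk_length=20, num_walks=5, seed=3)
        edges = g.edges
        assert len(corpus.walks) == 5 * 4
        for walk in corpus.walks:
            for u, v in zip(walk, walk[1:]):
                assert frozenset((u, v)) in edges

    def test_uniform_limit_matches_first_order_frequencies(self):
        # on a path a-b-c, steps from b must split 50/50 within binomial CI
        g = graph_of([("a", "b"), ("b", "c")])
        corpus = ppi.generate_walks(g, walk_length=2, num_walks=4000, seed=0)
        from_b = [w[1] for w in corpus.walks if w[0] == "b"]
        n = len(from_b)
        frac_a = from_b.count("a") / n
        assert abs(frac_a - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_return_parameter_biases_backtracking(self):
        # low p -> frequent immediate returns; high p -> rare returns
        g = graph_of([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        rates = {}
        for p in (0.1, 10.0):
            corpus = ppi.generate_walks(g, walk_length=30, num_walks=60,
                                        p=p, q=1.0, seed=0)
            returns = total = 0
            for w in corpus.walks:
                for i in range(2, len(w)):
                    total += 1
                    returns += w[i] == w[i - 2]
            rates[p] = returns / total
        assert rates[0.1] > rates[10.0] + 0.2

    def test_seed_reproducibility(self):
        g = graph_of([("a", "b"), ("b", "c")])
        w1 = ppi.generate_walks(g, walk_length=10, num_walks=4, seed=5).walks
        w2 = ppi.generate_walks(g, walk_length=10, num_walks=4, seed=5).walks
        assert w1 == w2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            ppi.generate_walks(PPIGraph(graph=nx.Graph()), walk_length=5, num_walks=1)


class TestEmbedding:
    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_cliques_separate(self, seed):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g = nx.relabel_nodes(g, {i: f"P{i:03d}" for i in g.nodes})
        corpus = ppi.generate_walks(PPIGraph(graph=g), walk_length=30,
                                    num_walks=5, seed=seed)
        emb = ppi.embed_nodes(corpus, n=16, window=3, epochs=15, seed=seed)
        order = np.argsort(emb.protein_index)  # P000..P007 = clique 1
        M = emb.matrix[order]
        M = M / np.linalg.norm(M, axis=1, keepdims=True)
        S = M @ M.T
        within = np.r_[
            S[:8, :8][np.triu_indices(8, 1)], S[8:, 8:][np.triu_indices(8, 1)]
        ].mean()
        across = S[:8, 8:].mean()
        assert within > across

    def test_shape_and_determinism(self):
        g = graph_of([("a", "b"), ("b", "c"), ("a", "c")])
        corpus = ppi.generate_walks(g, walk_length=10, num_walks=3, seed=0)
        e1 = ppi.embed_nodes(corpus, n=2, epochs=2, seed=1)
        e2 = ppi.embed_nodes(corpus, n=2, epochs=2, seed=1)
        assert e1.matrix.shape == (3, 2)
        np.testing.assert_array_equal(e1.matrix, e2.matrix)


class TestClustering:
    def _cpc(self, proteins):
        rng = np.random.default_rng(0)
        return CellProteinMatrix(rng.random((len(proteins), 3)),
                                 list(proteins), ["c1", "c2", "c3"])

    def test_two_blobs_recovered_against_brute_force(self):
        # 4 points at two well-separated locations: best 2-partition is by blob
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]])
        names = ["p1", "p2", "p3", "p4"]
        emb = ppi.NodeEmbeddings(matrix=pts, protein_index=names)
        space = ppi.cluster_proteins(emb, self._cpc(names), Pc=2, seed=0)
        assert space.assignment["p1"] == space.assignment["p2"]
        assert space.assignment["p3"] == space.assignment["p4"]
        assert space.assignment["p1"] != space.assignment["p3"]
        # brute force over all 2-partitions confirms this is the SSE argmin
        best, best_sse = None, np.inf
        for mask in itertools.product([0, 1], repeat=4):
            if len(set(mask)) < 2:
                continue
            sse = sum(
                np.sum((pts[np.array(mask) == k] -
                        pts[np.array(mask) == k].mean(axis=0)) ** 2)
                for k in (0, 1)
            )
            if sse < best_sse:
                best, best_sse = mask, sse
        assert best[0] == best[1] and best[2] == best[3]
        got_sse = sum(
            np.sum((pts[i] - space.op[space.assignment[n]]) ** 2)
            for i, n in enumerate(names)
        )
        assert got_sse == pytest.approx(best_sse, abs=1e-9)

    def test_identity_clustering_when_Pc_equals_P(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3)) * 10
        names = [f"p{i}" for i in range(5)]
        cpc = self._cpc(names)
        emb = ppi.NodeEmbeddings(matrix=pts, protein_index=names)
        space = ppi.cluster_proteins(emb, cpc, Pc=5, seed=0)
        perm = [space.assignment[n] for n in names]
        assert sorted(perm) == list(range(5))
        np.testing.assert_allclose(space.op[perm], pts, atol=1e-9)
        np.testing.assert_allclose(space.cpc_clustered[perm], cpc.matrix, atol=1e-9)

    def test_cluster_mean_of_cpc_rows(self):
        pts = np.array([[0.0], [0.01], [9.0]])
        names = ["a", "b", "c"]
        cpc = CellProteinMatrix(np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]]),
                                names, ["c1", "c2"])
        emb = ppi.NodeEmbeddings(matrix=pts, protein_index=names)
        space = ppi.cluster_proteins(emb, cpc, Pc=2, seed=0)
        j = space.assignment["a"]
        np.testing.assert_allclose(space.cpc_clustered[j], [0.5, 0.0])

    def test_aggregation_conserves_weighted_column_sums(self, small_bundle):
        bundle, _ = small_bundle
        rng = np.random.default_rng(2)
        emb = ppi.NodeEmbeddings(
            matrix=rng.normal(size=(len(bundle.cpc.protein_index), 4)),
            protein_index=list(bundle.cpc.protein_index),
        )
        space = ppi.cluster_proteins(emb, bundle.cpc, Pc=6, seed=0)
        weighted = (space.cpc_clustered * space.cluster_sizes[:, None]).sum(axis=0)
        np.testing.assert_allclose(weighted, bundle.cpc.matrix.sum(axis=0), atol=1e-9)

    def test_kmeans_objective_nonincreasing_over_iterations(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4))
        init = X[:4].copy()
        inertias = [
            KMeans(n_clusters=4, init=init, n_init=1, max_iter=it,
                   random_state=0).fit(X).inertia_
            for it in range(1, 8)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_invalid_Pc_rejected(self):
        emb = ppi.NodeEmbeddings(matrix=np.zeros((3, 2)),
                                 protein_index=["a", "b", "c"])
        with pytest.raises(ValueError):
            ppi.cluster_proteins(emb, self._cpc(["a", "b", "c"]), Pc=4)
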