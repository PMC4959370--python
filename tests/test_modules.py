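"""Correlation graphs, clique extraction and bi-clique pairing against
exhaustive enumeration."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from progmod import (
    ModuleBuildConfig,
    SimConfig,
    build_modules,
    correlation_graph,
    extract_cliques,
    maximum_clique,
    pair_clusters,
    simulate,
)
from progmod.modules import GeneCluster, max_edge_biclique

from _oracles import max_cliques_bruteforce, max_edge_biclique_bruteforce


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestCorrelationGraph:
    def test_edge_weights_match_direct_pearson(self, rng):
        X = _expr(rng.normal(size=(5, 30)))
        G = correlation_graph(X, X.index, threshold=-1.0 + 1e-9)
        for u, v, w in G.edges(data="weight"):
            direct = np.corrcoef(X.loc[u], X.loc[v])[0, 1]
            assert w == pytest.approx(direct, abs=1e-12)

    def test_duplicated_rows_form_complete_graph(self, rng):
        row = rng.normal(size=20)
        X = _expr(np.stack([row, row, row]))
        G = correlation_graph(X, X.index, threshold=0.4)
        assert G.number_of_edges() == 3

    def test_independent_genes_sparse_at_threshold(self):
        rng = np.random.default_rng(2)
        X = _expr(rng.normal(size=(60, 500)))
        G = correlation_graph(X, X.index, threshold=0.4)
        possible = 60 * 59 / 2
        assert G.number_of_edges() / possible < 0.01

    def test_negative_mode_threshold_inclusive(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = _expr(np.stack([x, -x]))
        G = correlation_graph(X, X.index, threshold=0.4, sign_mode="negative")
        assert G.has_edge("g0", "g1")
        G2 = correlation_graph(X, X.index, threshold=0.4, sign_mode="positive")
        assert G2.number_of_edges() == 0

    def test_zero_variance_gene_excluded(self, rng):
        X = _expr(np.vstack([rng.normal(size=(3, 20)), np.ones(20)]))
        G = correlation_graph(X, X.index, threshold=0.0)
        assert "g3" not in G and G.graph["excluded"] == ["g3"]

    def test_too_few_samples_rejected(self):
        X = _expr(np.ones((3, 2)))
        with pytest.raises(ValueError, match="3 samples"):
            correlation_graph(X, X.index, 0.4)


def _random_graph(rng, n, p):
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(G, {i: f"g{i:02d}" for i in G.nodes()})


class TestMaximumClique:
    def test_matches_bruteforce_with_lexicographic_ties(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            G = _random_graph(rng, int(rng.integers(4, 15)), float(rng.uniform(0.2, 0.8)))
            got = maximum_clique(G)
            k, all_best = max_cliques_bruteforce(G.nodes(), G.edges())
            assert len(got) == k
            assert set(got) in all_best
            assert list(got) == min(sorted(sorted(c) for c in all_best))

    def test_complete_graph_returns_everything(self):
        G = nx.complete_graph([f"g{i}" for i in range(20)])
        assert len(maximum_clique(G)) == 20

    def test_greedy_fallback_beyond_node_budget(self):
        G = nx.complete_graph([f"g{i}" for i in range(30)])
        got = maximum_clique(G, node_budget=10)
        assert len(got) == 30  # greedy is exact on a complete graph


class TestExtractCliques:
    def test_complete_graph_single_cluster(self):
        G = nx.complete_graph([f"g{i}" for i in range(20)])
        out = extract_cliques(G, min_cluster_size=16)
        assert len(out) == 1 and len(out[0]) == 20 and out[0].rank == 1

    def test_edgeless_graph_empty(self):
        G = nx.empty_graph([f"g{i}" for i in range(10)])
        assert extract_cliques(G, min_cluster_size=2) == []

    def test_iterative_removal_finds_second_cluster(self):
        G = nx.complete_graph([f"a{i}" for i in range(6)])
        G.update(nx.complete_graph([f"b{i}" for i in range(4)]))
        out = extract_cliques(G, min_cluster_size=3, max_clusters=2)
        assert [len(c) for c in out] == [6, 4]
        assert set(out[1].genes) == {f"b{i}" for i in range(4)}

    def test_max_clusters_caps_extraction(self):
        G = nx.complete_graph([f"a{i}" for i in range(4)])
        G.update(nx.complete_graph([f"b{i}" for i in range(4)]))
        G.update(nx.complete_graph([f"c{i}" for i in range(4)]))
        out = extract_cliques(G, min_cluster_size=3, max_clusters=2)
        assert len(out) == 2

    def test_emitted_clusters_are_cliques(self):
        rng = np.random.default_rng(13)
        G = _random_graph(rng, 25, 0.5)
        for cl in extract_cliques(G, min_cluster_size=2, max_clusters=5):
            for u in cl.genes:
                for v in cl.genes:
                    assert u == v or G.has_edge(u, v)


class TestBiclique:
    def _random_bipartite(self, rng, nl, nr, p):
        left = [f"h{i}" for i in range(nl)]
        right = [f"l{i}" for i in range(nr)]
        B = nx.Graph()
        B.add_nodes_from(left)
        B.add_nodes_from(right)
        for u in left:
            for v in right:
                if rng.random() < p:
                    B.add_edge(u, v)
        return B, left, right

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            B, left, right = self._random_bipartite(
                rng, int(rng.integers(2, 8)), int(rng.integers(2, 8)),
                float(rng.uniform(0.3, 0.9)))
            got = max_edge_biclique(B, left, right)
            want = max_edge_biclique_bruteforce(left, right, B.edges())
            assert len(got[0]) * len(got[1]) == len(want[0]) * len(want[1])
            # all cross-edges present
            for u in got[0]:
                for v in got[1]:
                    assert B.has_edge(u, v)

    def test_complete_bipartite_returns_everything(self):
        B = nx.complete_bipartite_graph(3, 4)
        B = nx.relabel_nodes(B, {i: (f"h{i}" if i < 3 else f"l{i}") for i in B})
        a, b = max_edge_biclique(B, [f"h{i}" for i in range(3)],
                                 [f"l{i}" for i in range(3, 7)])
        assert len(a) == 3 and len(b) == 4

    def test_no_edges_yields_empty(self):
        B = nx.Graph()
        B.add_nodes_from(["h0", "l0"])
        assert max_edge_biclique(B, ["h0"], ["l0"]) == ((), ())


class TestPairClusters:
    def test_fully_anticorrelated_pair_gives_full_module(self):
        x = np.linspace(-1, 1, 30)
        noise = np.random.default_rng(1).normal(0, 0.01, (8, 30))
        X = _expr(np.vstack([x + noise[i] for i in range(4)]
                            + [-x + noise[i + 4] for i in range(4)]),
                  genes=[f"h{i}" for i in range(4)] + [f"l{i}" for i in range(4)])
        hc = [GeneCluster(tuple(f"h{i}" for i in range(4)), "HIGH_POOR", 1)]
        lc = [GeneCluster(tuple(f"l{i}" for i in range(4)), "LOW_POOR", 1)]
        mods = pair_clusters(hc, lc, X)
        assert len(mods) == 1
        assert set(mods[0].high_genes) == set(hc[0].genes)
        assert set(mods[0].low_genes) == set(lc[0].genes)

    def test_uncorrelated_pair_gives_no_module(self):
        rng = np.random.default_rng(3)
        X = _expr(rng.normal(size=(8, 40)),
                  genes=[f"h{i}" for i in range(4)] + [f"l{i}" for i in range(4)])
        hc = [GeneCluster(tuple(f"h{i}" for i in range(4)), "HIGH_POOR", 1)]
        lc = [GeneCluster(tuple(f"l{i}" for i in range(4)), "LOW_POOR", 1)]
        assert pair_clusters(hc, lc, X) == []


class TestBuildModules:
    def test_planted_blocks_recovered_as_single_module(self):
        hits = 0
        for seed in range(10):
            expr, clin, truth = simulate(SimConfig(
                n_samples=300, n_genes=200, seed=100 + seed))
            mods = build_modules(expr, truth.high_genes, truth.low_genes)
            if (len(mods) == 1
                    and len(set(mods[0].high_genes) & set(truth.high_genes)) >= 16
                    and len(set(mods[0].low_genes) & set(truth.low_genes)) >= 16):
                hits += 1
        assert hits >= 9

    def test_modules_satisfy_all_pairs_anticorrelation(self):
        expr, clin, truth = simulate(SimConfig(n_samples=300, n_genes=150, seed=42))
        mods = build_modules(expr, truth.high_genes, truth.low_genes)
        assert mods
        X = expr.to_numpy()
        idx = {g: i for i, g in enumerate(expr.index)}
        for m in mods:
            for u in m.high_genes:
                for v in m.low_genes:
                    r = np.corrcoef(X[idx[u]], X[idx[v]])[0, 1]
                    assert r <= -0.4

    def test_sample_permutation_invariance(self):
        expr, clin, truth = simulate(SimConfig(n_samples=250, n_genes=120, seed=5))
        mods1 = build_modules(expr, truth.high_genes, truth.low_genes)
        perm = expr.sample(frac=1, axis=1, random_state=1)
        mods2 = build_modules(perm, truth.high_genes, truth.low_genes)
        assert [(m.high_genes, m.low_genes) for m in mods1] == \
               [(m.high_genes, m.low_genes) for m in mods2]

    def test_empty_direction_list_gives_no_modules(self, planted_cohort):
        expr, _, truth = planted_cohort
        assert build_modules(expr, [], truth.low_genes) == []
        assert build_modules(expr, truth.high_genes, []) == []

    def test_modules_ordered_by_total_size_and_labeled(self):
        expr, clin, truth = simulate(SimConfig(n_samples=300, n_genes=150, seed=42))
        mods = build_modules(expr, truth.high_genes, truth.low_genes,
                             ModuleBuildConfig(min_cluster_size=4))
        sizes = [m.n_genes for m in mods]
        assert sizes == sorted(sizes, reverse=True)
        assert [m.label for m in mods] == [f"module {i+1}" for i in range(len(mods))]
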