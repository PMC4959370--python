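"""Co-expression clique clustering and bi-clique module pairing.

The screened gene lists (over- and under-expressed in poor survival) are
clustered on their Pearson co-expression structure: within each
directional list, genes are connected when their correlation exceeds a
positive threshold (default 0.4), and the largest cliques are extracted
iteratively (find the maximum clique, remove its genes, repeat).  Each
(high, low) cluster pair is then screened for mutual anticorrelation: a
bipartite graph connects a high gene to a low gene when their correlation
is at most the negative threshold (default -0.4), and the maximal
bi-clique with the most edges becomes a prognostic module — a pair of
gene sets in which every high/low gene pair is anticorrelated.

Clique search is exact branch-and-bound up to a configurable node budget
(default 500, comfortably above the few-hundred-gene lists the screen
produces); larger graphs fall back to a greedy degeneracy heuristic with
a logged warning.  Equal-size ties are broken by the lexicographically
smallest gene-ID set so results are independent of input order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCluster",
    "PrognosticModule",
    "ModuleBuildConfig",
    "correlation_graph",
    "extract_cliques",
    "pair_clusters",
    "build_modules",
]

DEFAULT_POS_THRESHOLD = 0.4
DEFAULT_NEG_THRESHOLD = 0.4
DEFAULT_MIN_CLUSTER_SIZE = 16  # "over 15" independent genes per cluster
DEFAULT_MAX_CLUSTERS = 2       # two major clusters per direction
DEFAULT_NODE_BUDGET = 500


@dataclass(frozen=True)
class GeneCluster:
    """A clique of positively co-expressed genes from one directional list."""

    genes: tuple[str, ...]
    direction: str  # HIGH_POOR | LOW_POOR
    rank: int       # extraction order, 1-based

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class PrognosticModule:
    """Paired anticorrelated gene sets scoring one risk axis.

    ``high_genes`` are over-expressed and ``low_genes`` under-expressed in
    poor-survival patients; every cross pair is anticorrelated at the
    build threshold.  ``provenance`` records thresholds and source
    cluster ranks.
    """

    label: str
    high_genes: tuple[str, ...]
    low_genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def n_genes(self) -> int:
        return len(self.high_genes) + len(self.low_genes)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "high_genes": list(self.high_genes),
            "low_genes": list(self.low_genes),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrognosticModule":
        return cls(
            label=d["label"],
            high_genes=tuple(d["high_genes"]),
            low_genes=tuple(d["low_genes"]),
            provenance=dict(d.get("provenance", {})),
        )


@dataclass(frozen=True)
class ModuleBuildConfig:
    pos_threshold: float = DEFAULT_POS_THRESHOLD
    neg_threshold: float = DEFAULT_NEG_THRESHOLD
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    max_clusters: int = DEFAULT_MAX_CLUSTERS
    node_budget: int = DEFAULT_NODE_BUDGET


def correlation_graph(
    expr: pd.DataFrame,
    genes,
    threshold: float = DEFAULT_POS_THRESHOLD,
    sign_mode: str = "positive",
) -> nx.Graph:
    """Thresholded Pearson correlation graph over a gene subset.

    positive mode: edge iff r > +threshold (strict); negative mode: edge
    iff r <= -threshold (inclusive).  Pearson r is computed across all
    samples.  Zero-variance genes cannot carry a correlation and are
    excluded (their IDs are kept in ``G.graph['excluded']``).
    """
    genes = [g for g in genes if g in expr.index]
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    excluded = sd.index[sd == 0].tolist()
    if excluded:
        logger.info("excluding %d zero-variance genes from the graph", len(excluded))
    kept = [g for g in genes if g not in set(excluded)]
    G = nx.Graph(sign_mode=sign_mode, threshold=threshold, excluded=excluded)
    G.add_nodes_from(kept)
    if len(kept) >= 2:
        r = np.corrcoef(sub.loc[kept].to_numpy())
        iu, ju = np.triu_indices(len(kept), k=1)
        rr = r[iu, ju]
        if sign_mode == "positive":
            hit = rr > threshold
        elif sign_mode == "negative":
            hit = rr <= -threshold
        else:
            raise ValueError(f"unknown sign_mode: {sign_mode!r}")
        for i, j, w in zip(iu[hit], ju[hit], rr[hit]):
            G.add_edge(kept[i], kept[j], weight=float(w))
    return G


# ---------------------------------------------------------------------------
# exact maximum-clique search with deterministic lexicographic tie-break


def _adjacency_bitsets(nodes, G):
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in G.edges():
        i, j = index[u], index[v]
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    return adj


def _max_clique_size(adj, n) -> int:
    """Branch-and-bound maximum-clique size on bitset adjacency."""
    best = 0

    def expand(cand: int, size: int):
        nonlocal best
        if cand == 0:
            best = max(best, size)
            return
        if size + bin(cand).count("1") <= best:
            return
        while cand:
            if size + bin(cand).count("1") <= best:
                return
            v = (cand & -cand).bit_length() - 1
            cand &= cand - 1
            expand(cand & adj[v], size + 1)  # candidates after v only: no duplicates

    expand((1 << n) - 1, 0)
    return best


def _lex_smallest_clique_of_size(adj, n, k) -> list[int]:
    """First clique of size k found by depth-first search that always
    extends with the smallest admissible vertex index — with vertex
    indices in sorted gene order this is the lexicographically smallest
    such gene set."""
    result: list[int] = []

    def expand(chosen: list[int], cand: int) -> bool:
        if len(chosen) == k:
            result.extend(chosen)
            return True
        if len(chosen) + bin(cand).count("1") < k:
            return False
        c = cand
        while c:
            v = (c & -c).bit_length() - 1
            c &= c - 1
            if expand(chosen + [v], c & adj[v]):
                return True
        return False

    expand([], (1 << n) - 1)
    return result


def _greedy_clique(G) -> set:
    """Degeneracy-style greedy clique: seed at the highest-degree node
    and grow by the candidate with most remaining candidates."""
    if G.number_of_nodes() == 0:
        return set()
    start = max(sorted(G.nodes()), key=lambda v: G.degree(v))
    clique = {start}
    cand = set(G[start])
    while cand:
        v = max(sorted(cand), key=lambda u: len(cand & set(G[u])))
        clique.add(v)
        cand &= set(G[v])
    return clique


def maximum_clique(G: nx.Graph, node_budget: int = DEFAULT_NODE_BUDGET) -> tuple[str, ...]:
    """Maximum clique of G, ties broken by lexicographically smallest
    gene-ID set; exact up to ``node_budget`` nodes, greedy beyond."""
    nodes = sorted(G.nodes())
    if not nodes:
        return ()
    if len(nodes) > node_budget:
        logger.warning(
            "graph has %d nodes (> budget %d): greedy clique heuristic in use",
            len(nodes), node_budget,
        )
        return tuple(sorted(_greedy_clique(G)))
    adj = _adjacency_bitsets(nodes, G)
    k = _max_clique_size(adj, len(nodes))
    idx = _lex_smallest_clique_of_size(adj, len(nodes), k)
    return tuple(nodes[i] for i in idx)


def extract_cliques(
    G: nx.Graph,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
    direction: str = "",
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> list[GeneCluster]:
    """Iterative maximum-clique extraction.

    Repeatedly find the maximum clique, keep it if it has at least
    ``min_cluster_size`` genes, remove its nodes and continue, stopping
    after ``max_clusters`` clusters or when no qualifying clique remains.
    """
    H = G.copy()
    out: list[GeneCluster] = []
    while len(out) < max_clusters:
        clique = maximum_clique(H, node_budget=node_budget)
        if len(clique) < min_cluster_size:
            break
        out.append(GeneCluster(genes=clique, direction=direction, rank=len(out) + 1))
        H.remove_nodes_from(clique)
    return out


# ---------------------------------------------------------------------------
# maximal bi-clique with the most edges


def _bicliques_via_cliques(B: nx.Graph, left: list, right: list):
    """Maximal bicliques of a bipartite graph as maximal cliques of the
    graph completed within each side."""
    H = nx.Graph(B)
    H.add_nodes_from(left)
    H.add_nodes_from(right)
    H.add_edges_from(itertools.combinations(left, 2))
    H.add_edges_from(itertools.combinations(right, 2))
    lset = set(left)
    for clique in nx.find_cliques(H):
        a = sorted(v for v in clique if v in lset)
        b = sorted(v for v in clique if v not in lset)
        if a and b:
            yield tuple(a), tuple(b)


def max_edge_biclique(
    B: nx.Graph, left, right
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Maximal bi-clique maximizing |A|x|B| (edge count); ties broken by
    the larger smaller side, then lexicographically.  Returns ((), ())
    when the graph has no cross edges."""
    left = sorted(left)
    right = sorted(right)
    if B.number_of_edges() == 0:
        return (), ()
    best = None
    best_key = None
    for a, b in _bicliques_via_cliques(B, left, right):
        # sort key: maximize edges, then min side; prefer lexicographically
        # smaller gene sets on ties (negate via sorting on the tuple itself)
        key = (len(a) * len(b), min(len(a), len(b)))
        if best is None or key > best_key or (key == best_key and (a, b) < best):
            best, best_key = (a, b), key
    return best


def pair_clusters(
    high_clusters: list[GeneCluster],
    low_clusters: list[GeneCluster],
    expr: pd.DataFrame,
    neg_threshold: float = DEFAULT_NEG_THRESHOLD,
) -> list[PrognosticModule]:
    """Pair every high cluster with every low cluster through the maximal
    bi-clique of their bipartite anticorrelation graph.

    A module is emitted for each pair whose bi-clique has both sides
    non-empty; modules are ordered by total gene count (descending) and
    labeled "module 1", "module 2", ...  With two clusters per direction
    this yields up to four modules.
    """
    candidates = []
    for hc in high_clusters:
        for lc in low_clusters:
            union = list(hc.genes) + list(lc.genes)
            G = correlation_graph(expr, union, threshold=neg_threshold,
                                  sign_mode="negative")
            B = nx.Graph()
            B.add_nodes_from(hc.genes)
            B.add_nodes_from(lc.genes)
            hset = set(hc.genes)
            B.add_edges_from(
                (u, v) for u, v in G.edges()
                if (u in hset) != (v in hset)
            )
            a, b = max_edge_biclique(B, hc.genes, lc.genes)
            if a and b:
                candidates.append((a, b, hc.rank, lc.rank))
            else:
                logger.info(
                    "cluster pair (high rank %d, low rank %d) has no "
                    "anticorrelated bi-clique", hc.rank, lc.rank,
                )
    candidates.sort(key=lambda c: (-(len(c[0]) + len(c[1])), c[2], c[3]))
    out = []
    for i, (a, b, hr_, lr_) in enumerate(candidates, start=1):
        out.append(PrognosticModule(
            label=f"module {i}",
            high_genes=a,
            low_genes=b,
            provenance={
                "high_cluster_rank": hr_,
                "low_cluster_rank": lr_,
                "neg_threshold": neg_threshold,
            },
        ))
    return out


def build_modules(
    expr: pd.DataFrame,
    high_genes,
    low_genes,
    config: ModuleBuildConfig | None = None,
) -> list[PrognosticModule]:
    """Full module construction from the two screened gene lists:
    positive-correlation graphs per direction, iterative clique
    extraction, then bi-clique pairing of every cluster combination."""
    cfg = config or ModuleBuildConfig()
    high_genes = list(high_genes)
    low_genes = list(low_genes)
    if not high_genes or not low_genes:
        return []
    clusters = {}
    for direction, genes in (("HIGH_POOR", high_genes), ("LOW_POOR", low_genes)):
        G = correlation_graph(expr, genes, threshold=cfg.pos_threshold,
                              sign_mode="positive")
        clusters[direction] = extract_cliques(
            G, min_cluster_size=cfg.min_cluster_size,
            max_clusters=cfg.max_clusters, direction=direction,
            node_budget=cfg.node_budget,
        )
    if not clusters["HIGH_POOR"] or not clusters["LOW_POOR"]:
        return []
    mods = pair_clusters(clusters["HIGH_POOR"], clusters["LOW_POOR"], expr,
                         neg_threshold=cfg.neg_threshold)
    for m in mods:
        m.provenance.update(
            pos_threshold=cfg.pos_threshold,
            min_cluster_size=cfg.min_cluster_size,
            max_clusters=cfg.max_clusters,
        )
    return mods
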