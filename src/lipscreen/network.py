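"""Network propagation and disease-module detection.

Hit lists are expanded over a weighted interactome by personalized PageRank
(random walk with restart to the seed genes), nodes above the third quartile
of the score distribution are clustered with the walktrap algorithm, and a
module is selected when it holds at least ``min_size`` nodes, at least one
seed hit, and its inside PageRank scores are significantly higher than the
outside scores (one-sided Kolmogorov–Smirnov, BH-adjusted).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import jaccard_index
from .stats import bh_adjust, fisher_exact_one_sided, ks_two_sample

__all__ = [
    "InteractionNetwork",
    "PropagatedModule",
    "personalized_pagerank",
    "threshold_top_quartile",
    "walktrap_communities",
    "score_module_significance",
    "propagate_and_detect",
    "compare_modules",
    "annotate_module_enrichment",
]


@dataclass
class InteractionNetwork:
    """Undirected weighted interaction network (confidence weights in (0, 1])."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        g.remove_edges_from(nx.selfloop_edges(g))
        for _, _, data in g.edges(data=True):
            data.setdefault("weight", 1.0)

    @classmethod
    def from_edge_list(cls, path: str | Path) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: edge list needs node_a and node_b columns")
        g = nx.Graph()
        has_w = len(cols) >= 3
        for row in df.itertuples(index=False):
            w = float(row[2]) if has_w else 1.0
            g.add_edge(str(row[0]), str(row[1]), weight=w)
        return cls(g)

    @classmethod
    def from_graphml(cls, path: str | Path) -> "InteractionNetwork":
        return cls(nx.Graph(nx.read_graphml(path)))

    def to_edge_list(self, path: str | Path) -> None:
        rows = [
            (a, b, d.get("weight", 1.0)) for a, b, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def largest_component(self) -> set[str]:
        return max(nx.connected_components(self.graph), key=len)

    def subgraph(self, nodes) -> "InteractionNetwork":
        return InteractionNetwork(nx.Graph(self.graph.subgraph(nodes)))


@dataclass
class PropagatedModule:
    """One network community from the propagation pipeline."""

    member_nodes: frozenset[str]
    seed_hits: frozenset[str]
    pagerank_scores: dict[str, float]
    ks_p: float = math.nan
    ks_q: float = math.nan
    selected: bool = False


def personalized_pagerank(
    network: InteractionNetwork,
    seeds: set[str],
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Random walk with restart to the uniform-over-seeds distribution.

    Power iteration on the edge-weight row-normalized transition matrix;
    dangling mass is redirected to the restart vector.  Converges when the
    L1 change falls below ``tol``; the returned scores sum to 1.
    """
    nodes = network.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    index = {v: i for i, v in enumerate(nodes)}
    present = seeds & set(nodes)
    dropped = seeds - present
    if dropped:
        warnings.warn(f"{len(dropped)} seed(s) absent from the network were dropped",
                      stacklevel=2)
    if not present:
        raise ValueError("no seed maps to the network")
    from scipy.sparse import csr_matrix

    rows, cols, vals = [], [], []
    for a, b, data in network.graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    W = csr_matrix((vals, (rows, cols)), shape=(n, n))
    strength = np.asarray(W.sum(axis=1)).ravel()
    dangling = strength == 0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, strength))
    restart = np.zeros(n)
    for s in present:
        restart[index[s]] = 1.0 / len(present)
    p = restart.copy()
    for _ in range(max_iter):
        walk = (p * inv) @ W  # row-normalized transition applied to p
        walk = walk + p[dangling].sum() * restart  # dangling mass restarts
        p_new = (1.0 - damping) * restart + damping * walk
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    p = p / p.sum()
    return {v: float(p[index[v]]) for v in nodes}


def threshold_top_quartile(scores: dict[str, float]) -> set[str]:
    """Nodes scoring strictly above the 75th percentile (type-7 quantile)
    of the full score distribution."""
    if len(scores) < 4:
        raise ValueError("need at least 4 scored nodes")
    vals = np.array(list(scores.values()), dtype=float)
    q3 = float(np.quantile(vals, 0.75))
    return {v for v, s in scores.items() if s > q3}


def walktrap_communities(network: InteractionNetwork, steps: int = 4) -> list[set[str]]:
    """Random-walk (walktrap) community detection, cut at maximum modularity.

    Runs per connected component; isolated nodes become singleton
    communities.  Deterministic given the graph; communities are returned
    ordered by (size descending, smallest member id).
    """
    g = network.graph
    out: list[set[str]] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            out.append(set(comp))
            continue
        sub = g.subgraph(comp)
        igg = ig.Graph()
        igg.add_vertices(comp)
        edges = [(a, b) for a, b, _ in sub.edges(data=True)]
        weights = [float(d.get("weight", 1.0)) for _, _, d in sub.edges(data=True)]
        igg.add_edges(edges)
        dendrogram = igg.community_walktrap(weights=weights, steps=steps)
        clustering = dendrogram.as_clustering()
        for cluster in clustering:
            out.append({comp[i] for i in cluster})
    out.sort(key=lambda m: (-len(m), min(m)))
    return out


def score_module_significance(
    modules: list[set[str]],
    pagerank_scores: dict[str, float],
    seeds: set[str],
    min_size: int = 10,
    alpha: float = 0.05,
) -> list[PropagatedModule]:
    """KS-based module significance over the whole-network score distribution.

    Per module the inside scores are compared to the outside scores with a
    one-sided (inside greater) two-sample KS test; p-values are BH-adjusted
    across modules.  ``selected`` requires size >= ``min_size``, at least
    one seed hit and adjusted p < ``alpha``.
    """
    all_nodes = set(pagerank_scores)
    ps = []
    for members in modules:
        inside = [pagerank_scores[v] for v in members]
        outside = [pagerank_scores[v] for v in all_nodes - members]
        if not inside or not outside:
            ps.append(math.nan)
            continue
        _, p = ks_two_sample(inside, outside, alternative="greater")
        ps.append(p)
    qs = bh_adjust(ps)
    out = []
    for members, p, q in zip(modules, ps, qs):
        hit_seeds = frozenset(members & seeds)
        selected = (
            len(members) >= min_size
            and len(hit_seeds) >= 1
            and np.isfinite(q)
            and q < alpha
        )
        out.append(
            PropagatedModule(
                member_nodes=frozenset(members),
                seed_hits=hit_seeds,
                pagerank_scores={v: pagerank_scores[v] for v in members},
                ks_p=float(p),
                ks_q=float(q),
                selected=bool(selected),
            )
        )
    return out


def propagate_and_detect(
    network: InteractionNetwork,
    seeds: set[str],
    damping: float = 0.85,
    steps: int = 4,
    min_size: int = 10,
    alpha: float = 0.05,
) -> tuple[list[PropagatedModule], dict[str, float]]:
    """Full propagation pipeline: PageRank -> top-quartile threshold ->
    walktrap on the induced subgraph -> KS module significance."""
    scores = personalized_pagerank(network, seeds, damping=damping)
    top = threshold_top_quartile(scores)
    modules = walktrap_communities(network.subgraph(top), steps=steps)
    return score_module_significance(modules, scores, seeds, min_size, alpha), scores


def compare_modules(runs: dict[str, list[PropagatedModule]]) -> pd.DataFrame:
    """Pairwise Jaccard matrix between the selected modules of >= 2 runs;
    rows/columns labelled ``<trait>/m<k>``."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to compare")
    labels, sets = [], []
    for trait, mods in runs.items():
        for k, mod in enumerate(mods):
            labels.append(f"{trait}/m{k}")
            sets.append(set(mod.member_nodes))
    mat = np.array([[jaccard_index(a, b) for b in sets] for a in sets])
    return pd.DataFrame(mat, index=labels, columns=labels)


def annotate_module_enrichment(
    module: PropagatedModule,
    annotations: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of annotation terms in the module, BH
    adjusted across terms; module members must lie inside the universe."""
    if not universe:
        raise ValueError("empty universe")
    members = set(module.member_nodes)
    if not members <= universe:
        raise ValueError("module members must be a subset of the universe")
    rows = []
    for term, nodes in sorted(annotations.items()):
        nodes = set(nodes) & universe
        a = len(members & nodes)
        b = len(members - nodes)
        c = len(nodes - members)
        d = len(universe) - a - b - c
        rows.append((term, a, b, c, d, fisher_exact_one_sided(a, b, c, d)))
    out = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "p"]).set_index("term")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
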