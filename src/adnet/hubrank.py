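"""Topology-based hub-gene screening.

Eleven node-importance indices (the cytoHubba family, restricted to the
set used here) are computed for every gene: degree (DC), betweenness
(BC), harmonic closeness (CC), maximum neighbourhood component (MNC) and
its density variant (DMNC), BottleNeck (BN), edge percolated component
(EPC), maximal clique centrality (MCC), edge clustering coefficient
(ECC), radiality, and the local clustering coefficient.  The consensus
screen takes the top-k genes of each index and selects genes appearing in
more than six (default: at least 7) of the eleven top lists.

EPC is the only stochastic index: it averages, over random edge-kept
subgraphs, the fraction of other nodes still connected to each node.  Its
seed is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .graphio import GeneNetwork

logger = logging.getLogger(__name__)

INDEX_NAMES = (
    "dc", "bc", "cc", "mnc", "dmnc", "bn",
    "epc", "mcc", "ecc", "radiality", "clustering",
)

DMNC_EXPONENT = 1.7  # published cytoHubba constant


@dataclass
class CentralityTable:
    """Genes x indices matrix of non-negative finite centrality values."""

    values: pd.DataFrame
    epc_seed: int | None = None
    epc_reps: int = 0
    epc_keep_prob: float = 0.5

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("centrality values must be finite and >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def indices(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ConsensusResult:
    """Per-gene top-list membership counts and the selected gene set."""

    counts: dict[str, int]
    selected: set[str]
    k: int = 100
    threshold: int = 7


# ---------------------------------------------------------------------------
# individual indices
# ---------------------------------------------------------------------------


def _mnc_dmnc(g: nx.Graph, nodes: list[str]) -> tuple[dict, dict]:
    mnc, dmnc = {}, {}
    for v in nodes:
        nbrs = set(g[v])
        if not nbrs:
            mnc[v], dmnc[v] = 0.0, 0.0
            continue
        sub = g.subgraph(nbrs)
        # largest component; ties broken by edge count, then members
        best = max(
            (sub.subgraph(c) for c in nx.connected_components(sub)),
            key=lambda s: (s.number_of_nodes(), s.number_of_edges(),
                           sorted(s.nodes)),
        )
        mnc[v] = float(best.number_of_nodes())
        dmnc[v] = best.number_of_edges() / best.number_of_nodes() ** DMNC_EXPONENT
    return mnc, dmnc


def _bottleneck(g: nx.Graph, nodes: list[str]) -> dict[str, float]:
    """One point per BFS shortest-path tree in which >= |tree|/4 of the
    tree's nodes reach the root through the scored node (itself included).

    Trees are built breadth-first with lexicographic parent tie-breaking,
    which fixes the ambiguity of shortest-path-tree construction.
    """
    scores = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        parent: dict[str, str | None] = {s: None}
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(g[u]):
                    if w not in parent:
                        parent[w] = u
                        nxt.append(w)
                        order.append(w)
            frontier = sorted(set(nxt))
        if len(parent) < 2:
            continue  # a single-node tree carries no paths
        size = dict.fromkeys(parent, 1)
        for v in reversed(order):
            p = parent[v]
            if p is not None:
                size[p] += size[v]
        cut = len(parent) / 4.0
        for v in parent:
            if size[v] >= cut:
                scores[v] += 1.0
    return scores


def _epc(
    g: nx.Graph, nodes: list[str], reps: int, keep_prob: float, rng: np.random.Generator
) -> dict[str, float]:
    n = len(nodes)
    if n <= 1 or reps <= 0:
        return dict.fromkeys(nodes, 0.0)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([[idx[u], idx[v]] for u, v in g.edges], dtype=int).reshape(-1, 2)
    acc = np.zeros(n)
    for _ in range(reps):
        keep = rng.random(len(edges)) < keep_prob
        kept = edges[keep]
        adj = coo_matrix(
            (np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels)
        acc += (sizes[labels] - 1) / (n - 1)
    acc /= reps
    return {v: float(acc[idx[v]]) for v in nodes}


def _mcc(g: nx.Graph, nodes: list[str]) -> dict[str, float]:
    # Sum of (|clique|-1)! over maximal cliques of size >= 2; a node whose
    # neighbourhood has no internal edge then automatically scores its
    # degree (all its maximal cliques are single edges).
    mcc = dict.fromkeys(nodes, 0.0)
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        contrib = float(factorial(len(clique) - 1))
        for v in clique:
            mcc[v] += contrib
    return mcc


def _ecc(g: nx.Graph, nodes: list[str]) -> dict[str, float]:
    ecc = dict.fromkeys(nodes, 0.0)
    for u, v in g.edges:
        denom = min(g.degree(u) - 1, g.degree(v) - 1)
        if denom <= 0:
            continue
        tri = len(set(g[u]) & set(g[v]))
        term = (tri + 1) / denom
        ecc[u] += term
        ecc[v] += term
    return ecc


def _radiality(g: nx.Graph, nodes: list[str]) -> dict[str, float]:
    rad = dict.fromkeys(nodes, 0.0)
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        nc = len(comp)
        if nc == 1:
            continue
        sub = g.subgraph(comp)
        dists = {v: nx.single_source_shortest_path_length(sub, v) for v in comp}
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            rad[v] = sum(
                (diam + 1 - d) / (nc - 1) for w, d in dists[v].items() if w != v
            )
    return rad


def compute_centralities(
    net: GeneNetwork,
    epc_reps: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int = 0,
) -> CentralityTable:
    """All eleven indices for every gene of the network."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.to_networkx()
    nodes = sorted(g)

    dc = {v: float(g.degree(v)) for v in nodes}
    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.harmonic_centrality(g)
    mnc, dmnc = _mnc_dmnc(g, nodes)
    bn = _bottleneck(g, nodes)
    rng = np.random.default_rng(seed)
    epc = _epc(g, nodes, epc_reps, epc_keep_prob, rng)
    mcc = _mcc(g, nodes)
    ecc = _ecc(g, nodes)
    rad = _radiality(g, nodes)
    clu = nx.clustering(g)

    df = pd.DataFrame(
        {
            "dc": dc, "bc": bc, "cc": cc, "mnc": mnc, "dmnc": dmnc, "bn": bn,
            "epc": epc, "mcc": mcc, "ecc": ecc, "radiality": rad,
            "clustering": clu,
        },
        index=nodes,
    ).astype(float)
    # betweenness can go epsilon-negative through float cancellation
    df[df.abs() < 1e-12] = 0.0
    return CentralityTable(
        values=df[list(INDEX_NAMES)],
        epc_seed=seed,
        epc_reps=epc_reps,
        epc_keep_prob=epc_keep_prob,
    )


# ---------------------------------------------------------------------------
# consensus screen
# ---------------------------------------------------------------------------


def consensus_screen(
    tab: CentralityTable, k: int = 100, threshold: int = 7
) -> ConsensusResult:
    """Select genes in the top-k of at least ``threshold`` indices.

    Within each index genes are ranked by descending value with ties
    broken by ascending gene symbol.  The default threshold 7 encodes
    "more than six" top-list appearances.
    """
    genes = tab.genes
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} genes available")
    counts = dict.fromkeys(genes, 0)
    for index in tab.indices:
        col = tab.values[index]
        ranked = sorted(genes, key=lambda gname: (-col[gname], gname))
        for gname in ranked[:k]:
            counts[gname] += 1
    selected = {gname for gname, c in counts.items() if c >= threshold}
    return ConsensusResult(counts=counts, selected=selected, k=k, threshold=threshold)
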