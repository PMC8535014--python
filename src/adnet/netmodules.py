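"""Module detection (MCODE, MCL) and network structure entropy.

Network structure entropy is the Shannon entropy of the degree-share
distribution: with N nodes of degree k_i and I_i = k_i / sum_j k_j,

    E = - sum_i I_i ln I_i .

A d-regular graph attains the maximum E = ln N; heterogeneous degree
distributions score lower, which is read as a more stable (hub-dominated)
organisation.  Partitions produced by different clustering methods are
compared by the entropy of the intra-module graph, and the minimum-entropy
method is flagged optimal.

MCODE follows the three-stage seeded greedy scheme: core-clustering-
coefficient vertex weighting, greedy complex growth from high-weight
seeds, then post-processing (2-core haircut, optional fluff).  A module's
score is density x size of its induced subgraph.  MCL iterates expansion
(matrix powers) and inflation (entrywise powers with renormalisation) on
the self-loop-augmented column-stochastic adjacency matrix until the flow
matrix stabilises; clusters are the connected components of its support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphio import GeneNetwork

logger = logging.getLogger(__name__)

#: closed-neighbourhood density above which fluff adds a boundary node
FLUFF_DENSITY_THRESHOLD = 0.2


@dataclass
class ModulePartition:
    """Assignment of genes to named modules with per-module scores.

    For ``method`` 'mcode' or 'mcl' the modules are pairwise disjoint and
    each score equals density x size of the module's induced subgraph.
    """

    modules: dict[str, set[str]]
    method: str = "external"
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, members in self.modules.items():
            if not members:
                raise ValueError(f"module {mid!r} is empty")
        if self.method in ("mcode", "mcl"):
            seen: set[str] = set()
            for members in self.modules.values():
                if seen & members:
                    raise ValueError(f"{self.method} modules must be disjoint")
                seen |= members

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for members in self.modules.values():
            out |= members
        return out


@dataclass
class EntropyReport:
    """Network structure entropy E plus the node count it was taken over."""

    entropy: float
    n_nodes: int
    degrees_source: str = "network"
    n_zero_degree: int = 0


@dataclass
class McodeParams:
    vwp: float = 0.2          # vertex weight percentage for complex growth
    haircut: bool = True      # trim members outside the complex's 2-core
    fluff: bool = False       # add dense boundary neighbours
    min_core: int = 2         # discard complexes without a min_core-core

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError("vwp must be in [0, 1)")


@dataclass
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------


def network_entropy(net: GeneNetwork, degrees_source: str = "network") -> EntropyReport:
    """Degree-share Shannon entropy of a network.

    Zero-degree nodes carry no degree share (I_i = 0, and 0 ln 0 is taken
    by excluding them); their count is reported.  An edgeless network has
    no defined entropy and raises.
    """
    degs = net.degrees()
    ks = np.array([d for d in degs.values() if d > 0], dtype=float)
    n_zero = len(degs) - len(ks)
    if ks.size == 0:
        raise ValueError("entropy undefined: network has no edges")
    share = ks / ks.sum()
    entropy = float(-(share * np.log(share)).sum())
    return EntropyReport(
        entropy=entropy,
        n_nodes=int(ks.size),
        degrees_source=degrees_source,
        n_zero_degree=n_zero,
    )


def partition_entropy(net: GeneNetwork, part: ModulePartition) -> EntropyReport:
    """Entropy of the intra-module graph of a partition.

    The intra-module graph keeps every module member as a node and every
    network edge whose endpoints share a module; edges orphaned by the
    partition are dropped, which penalises divisions that cut many edges.
    """
    missing = part.all_members() - net.nodes
    if missing:
        raise ValueError(f"partition members absent from network: {sorted(missing)[:5]}")
    intra = GeneNetwork()
    for members in part.modules.values():
        for g in members:
            intra.add_node(g)
        sub = net.subgraph(members)
        for u, v in sub.iter_edges():
            intra.add_edge(u, v)
    report = network_entropy(intra, degrees_source="intra-module")
    return report


# ---------------------------------------------------------------------------
# scoring helpers
# ---------------------------------------------------------------------------


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def module_score(net: GeneNetwork, members: Iterable[str]) -> float:
    """MCODE module score: density x vertex count of the induced subgraph."""
    sub = net.to_networkx().subgraph(set(members))
    return _density(sub) * sub.number_of_nodes()


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------


def _mcode_vertex_weights(g: nx.Graph) -> dict[str, float]:
    """Stage 1: weight = (highest core number of the closed neighbourhood's
    k-core) x (density of that k-core)."""
    weights: dict[str, float] = {}
    for v in g:
        nbhd = set(g[v]) | {v}
        sub = g.subgraph(nbhd)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        kmax = max(core.values())
        core_nodes = [n for n, c in core.items() if c == kmax]
        weights[v] = kmax * _density(sub.subgraph(core_nodes))
    return weights


def mcode(net: GeneNetwork, params: McodeParams | None = None) -> ModulePartition:
    """Seeded greedy dense-complex detection.

    Complexes grow from the highest-weight unassigned vertex, adding
    (recursively) unassigned neighbours whose weight is at least
    ``(1 - vwp)`` of the seed's.  Haircut trims members outside the
    complex's 2-core; fluff then adds unassigned boundary neighbours whose
    closed neighbourhood is denser than ``FLUFF_DENSITY_THRESHOLD``.
    Complexes lacking a ``min_core``-core are discarded.  Vertices belong
    to at most one complex, so the result is a disjoint partition; modules
    are numbered '1', '2', ... in decreasing score order.
    """
    params = params or McodeParams()
    g = net.to_networkx()
    weights = _mcode_vertex_weights(g)

    assigned: set[str] = set()
    raw: list[set[str]] = []
    for seed in sorted(g, key=lambda v: (-weights[v], v)):
        if seed in assigned:
            continue
        cutoff = (1.0 - params.vwp) * weights[seed]
        complex_: set[str] = {seed}
        stack = [seed]
        while stack:
            u = stack.pop()
            for w in sorted(g[u]):
                if w in assigned or w in complex_:
                    continue
                if weights[w] >= cutoff:
                    complex_.add(w)
                    stack.append(w)
        assigned |= complex_
        raw.append(complex_)

    final: list[set[str]] = []
    for complex_ in raw:
        sub = g.subgraph(complex_)
        if params.haircut:
            sub = nx.k_core(sub, 2)
            if sub.number_of_nodes() == 0:
                continue
        if sub.number_of_nodes() < 2:
            continue
        if params.min_core > 0:
            if max(nx.core_number(sub).values(), default=0) < params.min_core:
                continue
        members = set(sub.nodes)
        if params.fluff:
            fluffed = set(members)
            for v in sorted(members):
                for w in sorted(g[v]):
                    if w in assigned or w in fluffed:
                        continue
                    closed = set(g[w]) | {w}
                    if _density(g.subgraph(closed)) > FLUFF_DENSITY_THRESHOLD:
                        fluffed.add(w)
            assigned |= fluffed
            members = fluffed
        final.append(members)

    final.sort(key=lambda m: (-module_score(net, m), sorted(m)))
    modules = {str(i + 1): m for i, m in enumerate(final)}
    scores = {mid: module_score(net, m) for mid, m in modules.items()}
    return ModulePartition(modules=modules, method="mcode", scores=scores)


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------


def mcl(net: GeneNetwork, params: MclParams | None = None) -> ModulePartition:
    """Markov clustering on the self-loop-augmented adjacency matrix."""
    params = params or MclParams()
    nodes = sorted(net.nodes)
    n = len(nodes)
    if n == 0:
        return ModulePartition(modules={}, method="mcl", scores={})
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v in net.iter_edges():
        m[idx[u], idx[v]] = 1.0
        m[idx[v], idx[u]] = 1.0
    np.fill_diagonal(m, 1.0)  # self-loops
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(params.max_iter):
        new = np.linalg.matrix_power(m, params.expansion)
        new = new ** params.inflation
        new[new < params.prune_threshold] = 0.0
        colsum = new.sum(axis=0)
        dead = colsum == 0.0
        if dead.any():  # resurrect fully pruned columns as self-attractors
            new[dead, dead] = 1.0
            colsum = new.sum(axis=0)
        new /= colsum
        diff = float(np.abs(new - m).max())
        m = new
        if diff < params.tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", params.max_iter)

    support = nx.Graph()
    support.add_nodes_from(range(n))
    ii, jj = np.nonzero(m > params.prune_threshold)
    for i, j in zip(ii, jj):
        if i != j:
            support.add_edge(int(i), int(j))
    clusters = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    clusters.sort(key=lambda c: (-len(c), c))
    modules = {str(i + 1): set(c) for i, c in enumerate(clusters)}
    scores = {mid: module_score(net, mem) for mid, mem in modules.items()}
    return ModulePartition(modules=modules, method="mcl", scores=scores)


# ---------------------------------------------------------------------------
# comparison and partition I/O
# ---------------------------------------------------------------------------


def compare_partitions(
    net: GeneNetwork, parts: Sequence[ModulePartition]
) -> pd.DataFrame:
    """Entropy comparison table across partitions.

    Rows sorted ascending by entropy (ties by method name); every
    minimum-entropy method is flagged optimal.
    """
    if not parts:
        raise ValueError("need at least one partition")
    rows = []
    for part in parts:
        rep = partition_entropy(net, part)
        rows.append(
            {"method": part.method, "n_modules": part.n_modules, "entropy": rep.entropy}
        )
    df = pd.DataFrame(rows).sort_values(["entropy", "method"], kind="mergesort")
    df["optimal"] = np.isclose(df["entropy"], df["entropy"].min())
    return df.reset_index(drop=True)


def write_partition(part: ModulePartition, path: str | Path) -> None:
    """Partition TSV: module-id TAB gene."""
    with open(path, "w") as fh:
        for mid in sorted(part.modules, key=lambda m: (len(m), m)):
            for gene in sorted(part.modules[mid]):
                fh.write(f"{mid}\t{gene}\n")


def read_partition(
    path: str | Path, method: str = "external", net: GeneNetwork | None = None
) -> ModulePartition:
    """Load a partition TSV; scores are recomputed when a network is given."""
    modules: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected module-id TAB gene")
        modules.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    scores = (
        {mid: module_score(net, mem) for mid, mem in modules.items()}
        if net is not None
        else {}
    )
    return ModulePartition(modules=modules, method=method, scores=scores)
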