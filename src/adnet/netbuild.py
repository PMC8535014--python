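"""Integrated network construction.

The disease network is assembled in three steps: (1) merge the available
protein-interaction networks; (2) keep only the genes and edges that also
appear in a co-expression network (gene pairs whose Pearson correlation
across samples exceeds a threshold, 0.5 by default, strictly); (3) link
every pair of genes that co-occur in any pathway set.  Each step is a
free-standing operation so alternative orders remain scriptable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graphio import ExpressionMatrix, GeneNetwork, PathwaySets

logger = logging.getLogger(__name__)


@dataclass
class BuildConfig:
    """Parameters of the construction stage.

    pcc_threshold
        Strict lower bound on the Pearson correlation for a co-expression
        edge; must lie in (0, 1).
    restrict_to
        Optional seed gene set; when given, co-expression and pathway
        co-membership only consider these genes.
    """

    pcc_threshold: float = 0.5
    restrict_to: set[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pcc_threshold < 1.0:
            raise ValueError("pcc_threshold must be in (0, 1)")


def coexpression_network(
    expr: ExpressionMatrix, cfg: BuildConfig | None = None
) -> GeneNetwork:
    """Link gene pairs whose Pearson correlation exceeds the threshold.

    Genes with zero variance are excluded (their correlation is
    undefined); the exclusion count is logged.  Requires >= 2 samples.
    """
    cfg = cfg or BuildConfig()
    if expr.n_samples < 2:
        raise ValueError("co-expression needs at least 2 samples")
    genes = list(expr.genes)
    values = expr.values
    if cfg.restrict_to is not None:
        keep = [i for i, g in enumerate(genes) if g in cfg.restrict_to]
        genes = [genes[i] for i in keep]
        values = values[keep]
    var = values.var(axis=1)
    nz = var > 0.0
    if not np.all(nz):
        logger.warning("excluding %d zero-variance gene(s)", int((~nz).sum()))
    genes = [g for g, ok in zip(genes, nz) if ok]
    values = values[nz]
    net = GeneNetwork()
    for g in genes:
        net.add_node(g)
    if len(genes) >= 2:
        corr = np.corrcoef(values)
        ii, jj = np.where(np.triu(corr, k=1) > cfg.pcc_threshold)
        for i, j in zip(ii, jj):
            net.add_edge(genes[i], genes[j], provenance="coexpr")
    return net


def intersect_networks(
    a: GeneNetwork, b: GeneNetwork, on: str = "edges"
) -> GeneNetwork:
    """Keep what appears in both networks.

    ``on='edges'`` (default): edge set = a.edges & b.edges, node set = the
    endpoints of surviving edges.  ``on='nodes'``: node set = a.nodes &
    b.nodes, edge set = the union of both networks' edges induced on the
    common nodes.
    """
    net = GeneNetwork()
    if on == "edges":
        common = a.edges() & b.edges()
        for e in common:
            u, v = sorted(e)
            net.add_edge(u, v, provenance=a.provenance(u, v) | b.provenance(u, v))
    elif on == "nodes":
        common = a.nodes & b.nodes
        for n in common:
            net.add_node(n)
        for src in (a, b):
            for u, v in src.iter_edges():
                if u in common and v in common:
                    net.add_edge(u, v, provenance=src.provenance(u, v))
    else:
        raise ValueError(f"unknown intersection mode {on!r}")
    if net.n_edges == 0:
        logger.warning("network intersection is empty")
    return net


def pathway_comembership_edges(
    net: GeneNetwork, pw: PathwaySets, restrict_to: set[str] | None = None
) -> GeneNetwork:
    """Return ``net`` plus an edge for every pair co-occurring in a pathway.

    The node set grows to include pathway genes.  ``restrict_to`` confines
    the added clique edges (and nodes) to the given gene set.
    """
    out = net.copy()
    for pid in sorted(pw.sets):
        members = pw.sets[pid]
        if restrict_to is not None:
            members = members & restrict_to
        for u, v in itertools.combinations(sorted(members), 2):
            out.add_edge(u, v, provenance="pathway")
        for g in members:
            out.add_node(g)
    return out


def merge_networks(nets: Sequence[GeneNetwork]) -> GeneNetwork:
    """Union of node and edge sets; provenance tags merged per edge."""
    if not nets:
        raise ValueError("merge_networks needs at least one network")
    out = GeneNetwork()
    for net in nets:
        for n in net.nodes:
            out.add_node(n)
        for u, v in net.iter_edges():
            out.add_edge(u, v, provenance=net.provenance(u, v) or {"merged"})
    return out


def build_integrated(
    ppi_nets: Sequence[GeneNetwork],
    expr: ExpressionMatrix,
    pw: PathwaySets | None = None,
    cfg: BuildConfig | None = None,
    intersect_on: str = "edges",
) -> GeneNetwork:
    """Full construction chain: merge -> intersect with co-expression ->
    add pathway co-membership edges."""
    cfg = cfg or BuildConfig()
    merged = merge_networks(ppi_nets)
    coexpr = coexpression_network(expr, cfg)
    net = intersect_networks(merged, coexpr, on=intersect_on)
    if pw is not None:
        net = pathway_comembership_edges(net, pw, restrict_to=cfg.restrict_to)
    logger.info(
        "integrated network: %d genes, %d edges", net.n_nodes, net.n_edges
    )
    return net
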