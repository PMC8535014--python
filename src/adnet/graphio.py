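"""Core containers and file formats for the disease gene-network pipeline.

The pipeline passes five kinds of objects between stages: an undirected
simple gene network, a genes x samples expression matrix, named pathway
gene sets, a protein-complex catalog, and a disease-gene catalog.  All of
them are plain-text backed: 2-column edge lists or SIF for interactions,
GMT for gene sets, header-row TSV for matrices and catalogs, GraphML for
export.  Gene symbols are treated as opaque case-sensitive strings; they
are whitespace-trimmed on input and never alias-resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: recognised per-edge provenance tags
PROVENANCE_TAGS = ("ppi", "coexpr", "pathway", "merged")


def _clean_symbol(raw: str) -> str:
    sym = raw.strip()
    if not sym:
        raise ValueError("empty gene symbol")
    return sym


class GeneNetwork:
    """Simple undirected graph over gene symbols.

    Backed by a :class:`networkx.Graph`.  Self-loops are silently refused,
    duplicate edges merge their provenance tags, and edge pairs are
    unordered: adding ``(a, b)`` and ``(b, a)`` yields one edge.

    Parameters
    ----------
    graph
        Optional networkx graph to copy nodes/edges (and any ``provenance``
        edge attribute) from.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph()
        if graph is not None:
            for n in graph.nodes:
                self.add_node(str(n))
            for u, v, d in graph.edges(data=True):
                self.add_edge(str(u), str(v), provenance=d.get("provenance"))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        provenance: str | Iterable[str] | None = None,
    ) -> "GeneNetwork":
        net = cls()
        for n in nodes:
            net.add_node(n)
        for u, v in edges:
            net.add_edge(u, v, provenance=provenance)
        return net

    def add_node(self, n: str) -> None:
        self._g.add_node(_clean_symbol(n))

    def add_edge(
        self, u: str, v: str, provenance: str | Iterable[str] | None = None
    ) -> bool:
        """Add edge {u, v}; return False for a refused self-loop."""
        u, v = _clean_symbol(u), _clean_symbol(v)
        if u == v:
            self._g.add_node(u)
            return False
        tags: set[str] = set()
        if provenance is not None:
            if isinstance(provenance, str):
                tags = set(t for t in provenance.split(",") if t)
            else:
                tags = set(provenance)
        if self._g.has_edge(u, v):
            self._g[u][v]["provenance"] |= tags
        else:
            self._g.add_edge(u, v, provenance=tags)
        return True

    # -- inspection -------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def iter_edges(self) -> Iterator[tuple[str, str]]:
        """Edges as (min, max) symbol pairs, deterministic order."""
        for u, v in sorted(tuple(sorted(e)) for e in self._g.edges):
            yield u, v

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, n: str) -> int:
        return int(self._g.degree(n))

    def degrees(self) -> dict[str, int]:
        return {n: int(d) for n, d in self._g.degree()}

    def neighbors(self, n: str) -> set[str]:
        return set(self._g[n])

    def provenance(self, u: str, v: str) -> set[str]:
        return set(self._g[u][v].get("provenance", set()))

    def subgraph(self, nodes: Iterable[str]) -> "GeneNetwork":
        return GeneNetwork(self._g.subgraph(set(nodes)))

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self._g)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __contains__(self, n: str) -> bool:
        return n in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix in arbitrary expression units."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in expression matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class PathwaySets:
    """Named gene sets plus the size of the pathway universe.

    ``universe_size`` is the total number of pathways available for
    enrichment (the *n* of the pathway-set Pearson association index); it
    defaults to the number of sets carried.
    """

    sets: dict[str, set[str]]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        if self.universe_size is None:
            self.universe_size = len(self.sets)
        for pid, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")
        if self.universe_size < len(self.sets):
            raise ValueError("universe_size smaller than number of sets")

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ComplexCatalog:
    """Protein-complex membership: complex-id -> member gene symbols."""

    complexes: dict[str, set[str]]

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {cid!r} is empty")

    def complexes_of(self, gene: str) -> list[str]:
        return sorted(c for c, m in self.complexes.items() if gene in m)


@dataclass
class DiseaseCatalog:
    """Known disease-gene sets, one focal disease, and the gene universe.

    ``total_human_genes`` is the D of the fallback prior C/D; C is the
    size of the focal disease's gene set.
    """

    disease_genes: dict[str, set[str]]
    focal_disease: str
    total_human_genes: int

    def __post_init__(self) -> None:
        if self.focal_disease not in self.disease_genes:
            raise ValueError(f"focal disease {self.focal_disease!r} not in catalog")
        union = set().union(*self.disease_genes.values()) if self.disease_genes else set()
        if self.total_human_genes < len(union):
            raise ValueError("total_human_genes smaller than known disease-gene union")

    @property
    def focal_genes(self) -> set[str]:
        return set(self.disease_genes[self.focal_disease])

    def all_disease_genes(self) -> set[str]:
        return set().union(*self.disease_genes.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """Plain gene list, one symbol per line; blank lines skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym:
            out.append(sym)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def _split_fields(line: str) -> list[str]:
    # tab-separated if tabs present, otherwise any whitespace
    return line.split("\t") if "\t" in line else line.split()


def read_edge_list(path: str | Path, format: str = "tsv") -> GeneNetwork:
    """Load an undirected simple network from a 2-column TSV or a SIF file.

    Self-loops and duplicate edges are dropped silently (a count is
    logged).  SIF rows ``source relation target1 target2 ...`` expand to
    one edge per target; a 1-field SIF row declares an isolated node.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    text = Path(path).read_text()
    net = GeneNetwork()
    n_self, n_dup, n_edges_seen = 0, 0, 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = [f.strip() for f in _split_fields(line)]
        if format == "tsv":
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 columns")
            pairs = [(fields[0], fields[1])]
        else:  # sif
            if len(fields) == 1:
                net.add_node(fields[0])
                continue
            if len(fields) == 2:
                raise ValueError(
                    f"{path}: line {lineno}: SIF row has a relation but no target"
                )
            pairs = [(fields[0], t) for t in fields[2:]]
        for u, v in pairs:
            n_edges_seen += 1
            if u == v:
                n_self += 1
                net.add_node(u)
                continue
            if net.has_edge(u, v):
                n_dup += 1
            net.add_edge(u, v)
    if n_edges_seen == 0 and net.n_nodes == 0:
        raise ValueError(f"{path}: no edges or nodes found")
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop(s), merged %d duplicate edge(s)",
            path, n_self, n_dup,
        )
    return net


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in net.iter_edges():
            fh.write(f"{u}\t{v}\n")


def read_gmt(path: str | Path) -> PathwaySets:
    """GMT gene-set file: ``set-id TAB description TAB gene TAB gene...``."""
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = [f.strip() for f in raw.split("\t")]
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT row needs >=3 fields")
        pid = fields[0]
        if pid in sets:
            raise ValueError(f"{path}: line {lineno}: duplicate set id {pid!r}")
        members = {g for g in fields[2:] if g}
        if not members:
            raise ValueError(f"{path}: line {lineno}: set {pid!r} has no genes")
        sets[pid] = members
    return PathwaySets(sets=sets)


def write_gmt(pw: PathwaySets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pw.sets):
            genes = "\t".join(sorted(pw.sets[pid]))
            fh.write(f"{pid}\t{pid}\t{genes}\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Header-row TSV, first column gene symbols, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene row(s): {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite expression cell")
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", index_label="gene")


def read_two_column_catalog(path: str | Path) -> dict[str, set[str]]:
    """TSV of (group-id, gene) rows -> mapping group-id -> gene set.

    A header row is detected (and skipped) when the first line repeats as
    column titles 'id'/'gene'-like tokens; plain data files need none.
    """
    mapping: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = [f.strip() for f in _split_fields(raw)]
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns")
        mapping.setdefault(fields[0], set()).add(fields[1])
    if not mapping:
        raise ValueError(f"{path}: empty catalog")
    return mapping


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    return ComplexCatalog(complexes=read_two_column_catalog(path))


def read_disease_catalog(
    path: str | Path, focal_disease: str, total_human_genes: int
) -> DiseaseCatalog:
    return DiseaseCatalog(
        disease_genes=read_two_column_catalog(path),
        focal_disease=focal_disease,
        total_human_genes=total_human_genes,
    )


def write_two_column_catalog(mapping: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(mapping):
            for gene in sorted(mapping[gid]):
                fh.write(f"{gid}\t{gene}\n")


def write_graphml(net: GeneNetwork, path: str | Path) -> None:
    """GraphML export; provenance tag sets serialise as sorted CSV strings."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for u, v in net.iter_edges():
        tags = net.provenance(u, v)
        g.add_edge(u, v, provenance=",".join(sorted(tags)))
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> GeneNetwork:
    g = nx.read_graphml(str(path))
    net = GeneNetwork()
    for n in g.nodes:
        net.add_node(str(n))
    for u, v, d in g.edges(data=True):
        net.add_edge(str(u), str(v), provenance=d.get("provenance") or None)
    return net
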