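"""Herb-compound-ingredient-target set algebra.

A herb catalog is a four-level hierarchy: herb -> constituent compound ->
chemical ingredient -> protein target genes.  "Similar genes" of a herb
or compound are the intersection of its (union-aggregated) target genes
with a reference gene set, typically the disease's essential genes.  The
tripartite export writes the layered graph with similar targets marked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .graphio import _split_fields


@dataclass
class HerbCatalog:
    """herb -> compound -> ingredient -> set of target genes."""

    herbs: dict[str, dict[str, dict[str, set[str]]]]

    def __post_init__(self) -> None:
        for herb, compounds in self.herbs.items():
            for compound, ingredients in compounds.items():
                for ingredient, targets in ingredients.items():
                    if not targets:
                        raise ValueError(
                            f"{herb}/{compound}/{ingredient} has no targets"
                        )

    def herb_targets(self, herb: str) -> set[str]:
        out: set[str] = set()
        for ingredients in self.herbs[herb].values():
            for targets in ingredients.values():
                out |= targets
        return out

    def compound_targets(self, herb: str, compound: str) -> set[str]:
        out: set[str] = set()
        for targets in self.herbs[herb][compound].values():
            out |= targets
        return out


@dataclass
class OverlapReport:
    """Similar-gene sets and counts per herb and per (herb, compound)."""

    per_herb: dict[str, set[str]]
    per_compound: dict[tuple[str, str], set[str]]

    def herb_counts(self) -> pd.DataFrame:
        rows = [
            {"herb": h, "n_similar": len(s), "similar": ",".join(sorted(s))}
            for h, s in self.per_herb.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["n_similar", "herb"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True)
        )

    def compound_counts(self) -> pd.DataFrame:
        rows = [
            {
                "herb": h,
                "compound": c,
                "n_similar": len(s),
                "similar": ",".join(sorted(s)),
            }
            for (h, c), s in self.per_compound.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(
                ["n_similar", "herb", "compound"],
                ascending=[False, True, True],
                kind="mergesort",
            )
            .reset_index(drop=True)
        )


def read_herb_catalog(path: str | Path) -> HerbCatalog:
    """Catalog TSV: herb TAB compound TAB ingredient TAB target."""
    herbs: dict[str, dict[str, dict[str, set[str]]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = [f.strip() for f in _split_fields(raw)]
        if len(fields) < 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 columns")
        herb, compound, ingredient, target = fields[:4]
        herbs.setdefault(herb, {}).setdefault(compound, {}).setdefault(
            ingredient, set()
        ).add(target)
    if not herbs:
        raise ValueError(f"{path}: empty herb catalog")
    return HerbCatalog(herbs=herbs)


def similar_genes(targets: set[str], reference: set[str]) -> set[str]:
    """Exact intersection of target genes with the reference gene set."""
    return targets & reference


def overlap_report(cat: HerbCatalog, reference: set[str]) -> OverlapReport:
    """Similar-gene sets per herb (union over compounds/ingredients) and
    per compound."""
    per_herb = {
        herb: similar_genes(cat.herb_targets(herb), reference) for herb in cat.herbs
    }
    per_compound = {
        (herb, compound): similar_genes(cat.compound_targets(herb, compound), reference)
        for herb in cat.herbs
        for compound in cat.herbs[herb]
    }
    return OverlapReport(per_herb=per_herb, per_compound=per_compound)


def export_tripartite(cat: HerbCatalog, reference: set[str], path: str | Path) -> None:
    """GraphML of the layered herb->compound->ingredient->target graph.

    Node attributes: ``layer`` (herb/compound/ingredient/target) and, on
    target nodes, ``similar`` marking membership in the reference set.
    Node names are used verbatim, so names must not collide across layers.
    """
    g = nx.Graph()
    for herb in sorted(cat.herbs):
        g.add_node(herb, layer="herb")
        for compound in sorted(cat.herbs[herb]):
            g.add_node(compound, layer="compound")
            g.add_edge(herb, compound)
            for ingredient in sorted(cat.herbs[herb][compound]):
                g.add_node(ingredient, layer="ingredient")
                g.add_edge(compound, ingredient)
                for target in sorted(cat.herbs[herb][compound][ingredient]):
                    g.add_node(target, layer="target", similar=target in reference)
                    g.add_edge(ingredient, target)
    nx.write_graphml(g, str(path))
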