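"""Gene-set enrichment, pathway-association indices and coverage rate.

Enrichment is one-sided hypergeometric over-representation with
Benjamini-Hochberg correction: for a query of size q drawn from a
universe of M genes, a pathway of size K with overlap x scores
p = P[X >= x], X ~ Hypergeom(M, K, q).  The enriched-pathway sets of the
original network (O) and of each module (C_i) feed five association
indices (Jaccard, Simpson, geometric, cosine, and a Pearson index over
the pathway universe of size n) and the coverage rate
100 * |O ∩ union(C_i)| / |O|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graphio import PathwaySets


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment rows plus the significant-pathway set."""

    table: pd.DataFrame  # pathway, overlap, query_size, pathway_size, universe, pvalue, qvalue
    significant: set[str]
    alpha: float = 0.05


@dataclass
class AssociationScores:
    """The five pathway-set association indices plus their raw counts."""

    jaccard: float
    simpson: float
    geometric: float
    cosine: float
    pcc: float
    o_size: int
    c_size: int
    intersection: int
    union: int
    n: int


def hypergeom_enrich(
    genes: set[str],
    pw: PathwaySets,
    universe_genes: int | None = None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation with BH correction.

    ``universe_genes`` defaults to the number of distinct genes appearing
    in any pathway set.  Significance: BH q < alpha.
    """
    if not genes:
        raise ValueError("empty query gene set")
    if universe_genes is None:
        universe_genes = len(pw.all_genes())
    if universe_genes < len(genes):
        raise ValueError("universe smaller than the query gene set")
    rows = []
    for pid in sorted(pw.sets):
        members = pw.sets[pid]
        if len(members) > universe_genes:
            raise ValueError(f"pathway {pid!r} larger than the universe")
        overlap = len(genes & members)
        p = float(hypergeom.sf(overlap - 1, universe_genes, len(members), len(genes)))
        rows.append(
            {
                "pathway": pid,
                "overlap": overlap,
                "query_size": len(genes),
                "pathway_size": len(members),
                "universe": universe_genes,
                "pvalue": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        _, qvals, _, _ = multipletests(df["pvalue"], method="fdr_bh")
        df["qvalue"] = qvals
    else:
        df["qvalue"] = []
    df = df.sort_values(["pvalue", "pathway"], kind="mergesort").reset_index(drop=True)
    significant = set(df.loc[df["qvalue"] < alpha, "pathway"])
    return EnrichmentResult(table=df, significant=significant, alpha=alpha)


def association_indices(
    o: set[str], c: set[str], n: int
) -> AssociationScores:
    """Association between the original-network pathway set O and a
    module's pathway set C over a universe of n pathways.

    jaccard = |O∩C|/|O∪C|, simpson = |O∩C|/min(|O|,|C|),
    geometric = |O∩C|^2/(|O||C|), cosine = |O∩C|/sqrt(|O||C|), and the
    Pearson index is the correlation of the two membership indicators
    over the n-pathway universe.
    """
    if not o or not c:
        raise ValueError("association indices need non-empty pathway sets")
    if n < len(o | c):
        raise ValueError("pathway universe n smaller than |O ∪ C|")
    inter = len(o & c)
    union = len(o | c)
    o_size, c_size = len(o), len(c)
    pcc_den = o_size * c_size * (n - o_size) * (n - c_size)
    pcc = (
        (inter * n - o_size * c_size) / np.sqrt(pcc_den)
        if pcc_den > 0
        else float("nan")
    )
    return AssociationScores(
        jaccard=inter / union,
        simpson=inter / min(o_size, c_size),
        geometric=inter**2 / (o_size * c_size),
        cosine=inter / np.sqrt(o_size * c_size),
        pcc=float(pcc),
        o_size=o_size,
        c_size=c_size,
        intersection=inter,
        union=union,
        n=n,
    )


def coverage_rate(o: set[str], module_sets: Sequence[set[str]]) -> float:
    """Percentage of the original network's pathways covered by modules:
    100 * |O ∩ union(module_sets)| / |O|."""
    if not o:
        raise ValueError("coverage rate needs a non-empty original pathway set")
    covered: set[str] = set()
    for s in module_sets:
        covered |= s
    return 100.0 * len(o & covered) / len(o)
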