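"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the roles of the real data sources with known
ground truth: a planted-partition interaction network (dense modules in a
sparser background), block-correlated expression (a shared latent factor
per module), pathway sets drawn mostly from single modules, protein
complexes seeded with disease genes so that complex-informed priors are
informative, and a disease catalog listing a fraction of the planted
disease genes as known, plus decoy diseases.

Every generator is deterministic under a fixed config seed; each one
derives its own random stream so the outputs are individually stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graphio import (
    ComplexCatalog,
    DiseaseCatalog,
    ExpressionMatrix,
    GeneNetwork,
    PathwaySets,
    write_edge_list,
    write_expression,
    write_gene_list,
    write_gmt,
    write_two_column_catalog,
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic bundle.

    Defaults: five planted modules of 40 genes inside a 400-gene universe
    (half background), intra/inter edge probabilities 0.6/0.02, 79
    expression samples with within-module correlation 0.8, 40 pathways of
    10-24 genes drawn 90% from a home module, 40 complexes of 4-10 genes,
    module 0 as the disease module with 30% of its genes known.
    """

    n_genes: int = 400
    module_sizes: tuple[int, ...] = (40, 40, 40, 40, 40)
    p_in: float = 0.6
    p_out: float = 0.02
    n_samples: int = 79
    rho_in: float = 0.8
    n_pathways: int = 40
    pathway_module_fidelity: float = 0.9
    n_complexes: int = 40
    disease_module: int = 0
    frac_disease_known: float = 0.3
    seed: int = 11

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene count")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.rho_in < 1.0:
            raise ValueError("rho_in must be in [0, 1)")
        if not 0.0 <= self.pathway_module_fidelity <= 1.0:
            raise ValueError("pathway_module_fidelity must be in [0, 1]")
        if not 0 <= self.disease_module < len(self.module_sizes):
            raise ValueError("disease_module index out of range")

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted module membership and disease-gene identities."""

    module_of: dict[str, int | None]
    disease_genes: set[str]
    known_disease_genes: set[str]

    def __post_init__(self) -> None:
        if not self.known_disease_genes <= self.disease_genes:
            raise ValueError("known genes must be a subset of disease genes")

    def genes_of_module(self, m: int) -> set[str]:
        return {g for g, mm in self.module_of.items() if mm == m}

    @property
    def unknown_disease_genes(self) -> set[str]:
        return self.disease_genes - self.known_disease_genes


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def make_network(cfg: SynthConfig) -> tuple[GeneNetwork, GroundTruth]:
    """Planted-partition graph plus its ground truth.

    Intra-module pairs are linked with probability ``p_in``, all other
    pairs (including background genes) with ``p_out``.  The disease gene
    set is the whole disease module; a ``frac_disease_known`` fraction of
    it is marked known.
    """
    rng = _rng(cfg, 0)
    genes = cfg.gene_names()
    module_of: dict[str, int | None] = {g: None for g in genes}
    pos = 0
    for m, size in enumerate(cfg.module_sizes):
        for g in genes[pos : pos + size]:
            module_of[g] = m
        pos += size

    net = GeneNetwork()
    for g in genes:
        net.add_node(g)
    labels = np.array([-1 if module_of[g] is None else module_of[g] for g in genes])
    n = len(genes)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
    prob = np.where(same, cfg.p_in, cfg.p_out)
    draw = rng.random((n, n))
    ii, jj = np.where(upper & (draw < prob))
    for i, j in zip(ii, jj):
        net.add_edge(genes[i], genes[j], provenance="ppi")

    disease = {g for g in genes if module_of[g] == cfg.disease_module}
    n_known = int(round(cfg.frac_disease_known * len(disease)))
    known = set(rng.choice(sorted(disease), size=n_known, replace=False))
    truth = GroundTruth(
        module_of=module_of, disease_genes=disease, known_disease_genes=known
    )
    return net, truth


def make_expression(cfg: SynthConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Latent-factor expression: x = sqrt(rho) z_module + sqrt(1-rho) eps.

    Genes of one module share the module factor z (population correlation
    rho_in within a module, ~0 across); background genes are pure noise.
    """
    if cfg.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = _rng(cfg, 1)
    genes = cfg.gene_names()
    z = rng.standard_normal((len(cfg.module_sizes), cfg.n_samples))
    eps = rng.standard_normal((len(genes), cfg.n_samples))
    rho = cfg.rho_in
    values = np.empty((len(genes), cfg.n_samples))
    for i, g in enumerate(genes):
        m = truth.module_of[g]
        if m is None:
            values[i] = eps[i]
        else:
            values[i] = math.sqrt(rho) * z[m] + math.sqrt(1.0 - rho) * eps[i]
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]
    return ExpressionMatrix(genes=genes, samples=samples, values=values)


def make_pathways(cfg: SynthConfig, truth: GroundTruth) -> PathwaySets:
    """Pathways drawn mostly (fidelity fraction) from one home module.

    Home modules are sampled with double weight on the disease module:
    pathway catalogs assembled around a disease over-represent its
    functional module, which also gives the pipeline a well-defined key
    module (the synthetic analogue of a dominant pathway-driven module).
    """
    rng = _rng(cfg, 2)
    genes = cfg.gene_names()
    n_mod = len(cfg.module_sizes)
    weights = np.ones(n_mod)
    weights[cfg.disease_module] = 2.0
    weights /= weights.sum()
    sets: dict[str, set[str]] = {}
    for p in range(cfg.n_pathways):
        home = int(rng.choice(n_mod, p=weights))
        size = int(rng.integers(10, 25))
        members_home = sorted(truth.genes_of_module(home))
        n_home = min(int(round(cfg.pathway_module_fidelity * size)), len(members_home))
        chosen = set(rng.choice(members_home, size=n_home, replace=False))
        outside = [g for g in genes if g not in chosen]
        n_rand = size - len(chosen)
        if n_rand > 0:
            chosen |= set(rng.choice(outside, size=n_rand, replace=False))
        sets[f"P{p:03d}"] = chosen
    return PathwaySets(sets=sets, universe_size=cfg.n_pathways)


def make_complexes(
    cfg: SynthConfig, truth: GroundTruth
) -> tuple[ComplexCatalog, DiseaseCatalog]:
    """Protein complexes plus the disease catalog.

    Half the complexes are disease-informative (members drawn mostly from
    the disease module, with an occasional decoy-disease gene so B can
    exceed A); the rest are random.  The disease catalog lists only the
    *known* planted disease genes for the focal disease, plus two decoy
    diseases drawn from other modules.
    """
    rng = _rng(cfg, 3)
    genes = cfg.gene_names()
    non_disease = sorted(set(genes) - truth.disease_genes)
    decoys = {
        "DECOY1": set(rng.choice(non_disease, size=15, replace=False)),
        "DECOY2": set(rng.choice(non_disease, size=15, replace=False)),
    }
    decoy_pool = sorted(decoys["DECOY1"] | decoys["DECOY2"])
    disease_pool = sorted(truth.disease_genes)

    complexes: dict[str, set[str]] = {}
    n_informative = cfg.n_complexes // 2
    for c in range(cfg.n_complexes):
        size = int(rng.integers(4, 11))
        if c < n_informative:
            n_dis = max(2, int(round(0.6 * size)))
            members = set(rng.choice(disease_pool, size=min(n_dis, len(disease_pool)),
                                     replace=False))
            if rng.random() < 0.5 and decoy_pool:
                members.add(str(rng.choice(decoy_pool)))
            rest = [g for g in genes if g not in members]
            n_fill = size - len(members)
            if n_fill > 0:
                members |= set(rng.choice(rest, size=n_fill, replace=False))
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        complexes[f"CPX{c:03d}"] = members

    disease_catalog = DiseaseCatalog(
        disease_genes={"FOCAL": set(truth.known_disease_genes), **decoys},
        focal_disease="FOCAL",
        total_human_genes=cfg.n_genes,
    )
    return ComplexCatalog(complexes=complexes), disease_catalog


def write_bundle(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate everything and write the standard-format files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, truth = make_network(cfg)
    expr = make_expression(cfg, truth)
    pw = make_pathways(cfg, truth)
    cat, dis = make_complexes(cfg, truth)

    paths = {
        "ppi": outdir / "ppi.tsv",
        "expression": outdir / "expression.tsv",
        "pathways": outdir / "pathways.gmt",
        "complexes": outdir / "complexes.tsv",
        "diseases": outdir / "diseases.tsv",
        "known_genes": outdir / "known_genes.txt",
        "truth": outdir / "truth.tsv",
    }
    write_edge_list(net, paths["ppi"])
    write_expression(expr, paths["expression"])
    write_gmt(pw, paths["pathways"])
    write_two_column_catalog(cat.complexes, paths["complexes"])
    write_two_column_catalog(dis.disease_genes, paths["diseases"])
    write_gene_list(sorted(truth.known_disease_genes), paths["known_genes"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tmodule\tdisease\tknown\n")
        for g in cfg.gene_names():
            m = truth.module_of[g]
            fh.write(
                f"{g}\t{'' if m is None else m}\t"
                f"{int(g in truth.disease_genes)}\t"
                f"{int(g in truth.known_disease_genes)}\n"
            )
    return paths
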