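"""End-to-end orchestration of the disease gene-network analysis.

The pipeline chains every stage the way the analysis is meant to run:
build the integrated network, detect modules (MCODE + MCL + any external
partitions), pick the minimum-entropy division, enrich the network and
its modules and score their pathway association, screen hub genes in the
top-scoring module, run the Bayesian-framework logistic prioritizer, and
intersect the two gene sets into the final essential-gene prediction.
All intermediates and a JSON run report (with seeds and parameters) are
written to the output directory; a fixed seed makes the report
byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import bayeslr, graphio, herbnet, hubrank, netbuild, netmodules, pathstats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for a full run."""

    ppi: list[str]
    expr: str
    gmt: str
    complexes: str
    diseases: str
    total_genes: int
    focal: str = "FOCAL"
    herb_catalog: str | None = None
    external_partitions: dict[str, str] = field(default_factory=dict)
    pcc_threshold: float = 0.5
    intersect_on: str = "edges"
    mcode: dict[str, Any] = field(default_factory=dict)
    mcl: dict[str, Any] = field(default_factory=dict)
    k: int = 100
    hub_threshold: int = 7
    epc_reps: int = 1000
    reps: int = 50
    alpha: float = 0.05
    score_cut: float = 0.9  # decision-score percentile for "essential"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        required = list(self.ppi) + [self.expr, self.gmt, self.complexes, self.diseases]
        if self.herb_catalog:
            required.append(self.herb_catalog)
        required += list(self.external_partitions.values())
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full chain and return (and write) the run report."""
    cfg.validate_paths()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": {
            "pcc_threshold": cfg.pcc_threshold, "k": cfg.k,
            "hub_threshold": cfg.hub_threshold, "epc_reps": cfg.epc_reps,
            "reps": cfg.reps, "alpha": cfg.alpha, "score_cut": cfg.score_cut,
            "seed": cfg.seed, "focal": cfg.focal, "total_genes": cfg.total_genes,
        }
    }

    # --- build -----------------------------------------------------------
    build = _stage("build")(_build)
    net, pw = build(cfg)
    graphio.write_graphml(net, outdir / "network.graphml")
    report["network"] = {"n_genes": net.n_nodes, "n_edges": net.n_edges}

    # --- detect + compare ------------------------------------------------
    detect = _stage("detect")(_detect)
    parts = detect(cfg, net)
    for part in parts:
        netmodules.write_partition(part, outdir / f"partition_{part.method}.tsv")
    table = _stage("compare")(netmodules.compare_partitions)(net, parts)
    table.to_csv(outdir / "partition_entropy.tsv", sep="\t", index=False)
    report["partitions"] = table.to_dict(orient="records")
    winner_method = table.loc[0, "method"]
    winner = next(p for p in parts if p.method == winner_method)
    report["winner"] = winner_method

    # --- enrichment + association ---------------------------------------
    enrich = _stage("enrichment")(_enrich)
    report["pathways"] = enrich(cfg, net, pw, winner, outdir)

    # --- hub screen on the top module ------------------------------------
    hubs = _stage("hubs")(_hub_screen)
    hub_result, top_module = hubs(cfg, net, winner, outdir)
    report["hubs"] = {
        "top_module": top_module,
        "k_effective": hub_result.k,
        "threshold": hub_result.threshold,
        "selected": sorted(hub_result.selected),
    }

    # --- prioritizer ------------------------------------------------------
    prioritize = _stage("prioritize")(_prioritize)
    post, selected_prior = prioritize(cfg, net, outdir)
    report["prioritizer"] = {
        "n_scored": post.n_scored,
        "n_selected": len(selected_prior),
        "score_cut": cfg.score_cut,
    }

    # --- final essential genes -------------------------------------------
    final = sorted(hub_result.selected & selected_prior)
    report["essential_genes"] = final
    graphio.write_gene_list(final, outdir / "essential_genes.txt")

    # --- optional herb overlap -------------------------------------------
    if cfg.herb_catalog:
        overlap = _stage("herb_overlap")(_herb_overlap)
        report["herbs"] = overlap(cfg, set(final), outdir)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _build(cfg: PipelineConfig):
    ppi_nets = [graphio.read_edge_list(p) for p in cfg.ppi]
    expr = graphio.read_expression(cfg.expr)
    pw = graphio.read_gmt(cfg.gmt)
    net = netbuild.build_integrated(
        ppi_nets, expr, pw,
        cfg=netbuild.BuildConfig(pcc_threshold=cfg.pcc_threshold),
        intersect_on=cfg.intersect_on,
    )
    return net, pw


def _detect(cfg: PipelineConfig, net):
    parts = [
        netmodules.mcode(net, netmodules.McodeParams(**cfg.mcode)),
        netmodules.mcl(net, netmodules.MclParams(**cfg.mcl)),
    ]
    for method, path in sorted(cfg.external_partitions.items()):
        parts.append(netmodules.read_partition(path, method=method, net=net))
    return parts


def _enrich(cfg: PipelineConfig, net, pw, winner, outdir: Path):
    # background = all assayed genes (D), so network-level enrichment is
    # meaningful even when the network nearly exhausts the pathway union
    original = pathstats.hypergeom_enrich(
        net.nodes, pw, universe_genes=cfg.total_genes, alpha=cfg.alpha
    )
    original.table.to_csv(outdir / "enrichment_network.tsv", sep="\t", index=False)
    o_set = original.significant
    out: dict[str, Any] = {"n_original_pathways": len(o_set)}
    module_sets = []
    assoc_rows = []
    for mid in sorted(winner.modules, key=lambda m: (len(m), m)):
        members = winner.modules[mid]
        if len(members) < 3:
            continue
        res = pathstats.hypergeom_enrich(
            members, pw, universe_genes=cfg.total_genes, alpha=cfg.alpha
        )
        if not res.significant:
            continue  # modules enriched to nothing are ignored
        module_sets.append(res.significant)
        if o_set:
            scores = pathstats.association_indices(
                o_set, res.significant, pw.universe_size
            )
            row = {"module": mid, **asdict(scores)}
            if row["pcc"] != row["pcc"]:  # undefined when a set fills the universe
                row["pcc"] = None
            assoc_rows.append(row)
    if assoc_rows:
        import pandas as pd

        pd.DataFrame(assoc_rows).to_csv(
            outdir / "association_indices.tsv", sep="\t", index=False
        )
    out["modules_with_pathways"] = len(module_sets)
    out["association"] = assoc_rows
    out["coverage_rate"] = (
        pathstats.coverage_rate(o_set, module_sets) if o_set and module_sets else None
    )
    return out


def _hub_screen(cfg: PipelineConfig, net, winner, outdir: Path):
    if not winner.modules:
        raise ValueError("winning partition has no modules")
    top = max(
        winner.modules,
        key=lambda mid: (winner.scores.get(mid, 0.0), len(winner.modules[mid])),
    )
    sub = net.subgraph(winner.modules[top])
    tab = hubrank.compute_centralities(
        sub, epc_reps=cfg.epc_reps, seed=cfg.seed
    )
    k_eff = min(cfg.k, len(tab.genes))
    if k_eff < cfg.k:
        logger.info("top module has %d genes; clamping k to %d", len(tab.genes), k_eff)
    result = hubrank.consensus_screen(tab, k=k_eff, threshold=cfg.hub_threshold)
    df = tab.values.copy()
    df["count"] = [result.counts[g] for g in df.index]
    df["selected"] = [g in result.selected for g in df.index]
    df.to_csv(outdir / "hubs.tsv", sep="\t", index_label="gene")
    return result, top


def _prioritize(cfg: PipelineConfig, net, outdir: Path):
    cat = graphio.read_complex_catalog(cfg.complexes)
    dis = graphio.read_disease_catalog(cfg.diseases, cfg.focal, cfg.total_genes)
    post = bayeslr.run_integrated(net, cat, dis, reps=cfg.reps, seed=cfg.seed)
    with open(outdir / "scores.tsv", "w") as fh:
        fh.write("gene\tposterior\tscore\n")
        ranked = sorted(post.scores, key=lambda g: (-post.scores[g], g))
        for g in ranked:
            fh.write(f"{g}\t{post.posteriors[g]:.6g}\t{post.scores[g]:.6g}\n")
    selected = {g for g, q in post.scores.items() if q >= cfg.score_cut}
    return post, selected


def _herb_overlap(cfg: PipelineConfig, reference: set[str], outdir: Path):
    cat = herbnet.read_herb_catalog(cfg.herb_catalog)
    rep = herbnet.overlap_report(cat, reference)
    rep.herb_counts().to_csv(outdir / "herb_overlap.tsv", sep="\t", index=False)
    herbnet.export_tripartite(cat, reference, outdir / "herb_network.graphml")
    return {
        herb: {"n_similar": len(genes), "similar": sorted(genes)}
        for herb, genes in rep.per_herb.items()
    }
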