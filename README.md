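# adnet

Network and statistical analysis of a disease gene network: integrated
network construction, module detection evaluated by network structure
entropy, pathway-association scoring of modules, consensus hub-gene
screening over eleven topology indices, a Bayesian-framework
logistic-regression gene prioritizer with ROC evaluation, and
herb–compound–target overlap analysis.

The package is written for computational biologists who want the whole
chain — from raw edge lists and expression matrices to a ranked
essential-gene prediction — as reusable, tested library code with a thin
command-line layer, plus a synthetic-data generator so every stage can
be exercised with planted ground truth and no database downloads.

## The methods

**Integrated network.** Protein-interaction networks are merged, then
intersected with a co-expression network (genes *i*, *j* linked when
their Pearson correlation across samples satisfies r<sub>ij</sub> > 0.5,
strictly), and finally augmented with an edge for every gene pair
co-occurring in any pathway set. The result is a simple undirected graph
over gene symbols with per-edge provenance tags.

**Module detection and entropy.** Modules come from MCODE (seeded greedy
growth on core-clustering-coefficient vertex weights, 2-core haircut,
score = density × size) and MCL (alternating expansion/inflation of the
column-stochastic adjacency matrix). Competing partitions are compared by
network structure entropy

E = −Σ<sub>i</sub> I<sub>i</sub> ln I<sub>i</sub>,  I<sub>i</sub> = k<sub>i</sub> / Σ<sub>j</sub> k<sub>j</sub>,

computed on the intra-module graph; the minimum-entropy division wins
(a d-regular graph attains the maximum E = ln N, so lower E means a more
heterogeneous, hub-dominated organisation).

**Pathway association.** Network and modules are enriched by one-sided
hypergeometric tests with Benjamini–Hochberg correction; the enriched
sets O (network) and C<sub>i</sub> (module) are compared by the Jaccard,
Simpson, geometric, cosine and Pearson association indices, and the
coverage rate 100·|O ∩ ∪C<sub>i</sub>|/|O|.

**Hub consensus.** Eleven node-importance indices (degree, betweenness,
harmonic closeness, MNC, DMNC, BottleNeck, EPC, maximal-clique
centrality, edge clustering coefficient, radiality, clustering
coefficient) are ranked; genes in the top-k of more than six indices are
the topological essential genes.

**Prioritizer.** Complex-informed priors P = A/B (A focal-disease genes,
B any-disease genes in a gene's complexes; fallback C/D over the genome)
drive stochastic binary labels; feature vectors
φ<sub>i</sub> = (1, φ<sub>i1</sub>, φ<sub>i0</sub>, φ′<sub>i1</sub>, φ′<sub>i0</sub>)
count labelled first- and second-order neighbours; a logistic model is
fitted by penalised maximum likelihood; posteriors are averaged over
repeated label draws and converted to percentile decision scores
q<sub>i</sub> = |{j : P<sub>i</sub> ≥ P<sub>j</sub>}| / n. The final
essential-gene set is the intersection of the hub consensus and the
prioritizer's top decile, and ROC/AUC against positive/negative control
genes evaluates the ranking.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
from adnet import (SynthConfig, write_bundle, read_edge_list, read_expression,
                   read_gmt, build_integrated, mcode, mcl, compare_partitions)
from adnet.pipeline import PipelineConfig, run_pipeline

cfg = SynthConfig(seed=11)                      # 400 genes, 5 planted modules
paths = write_bundle(cfg, "sim/")
net = build_integrated([read_edge_list(paths["ppi"])],
                       read_expression(paths["expression"]),
                       read_gmt(paths["pathways"]))
print(f"integrated network: {net.n_nodes} genes, {net.n_edges} edges")
print(compare_partitions(net, [mcode(net), mcl(net)]).to_string(index=False))
```

prints

```
integrated network: 228 genes, 4448 edges
method  n_modules  entropy  optimal
 mcode          6 5.188297     True
   mcl          5 5.394257    False
```

The construction keeps the 228 genes whose interactions are confirmed by
co-expression (plus pathway genes) and 4448 edges; MCODE's division has
the lower intra-module entropy, so it is flagged the optimal partition.
Continuing through the whole chain,

```python
report = run_pipeline(PipelineConfig(
    ppi=[str(paths["ppi"])], expr=str(paths["expression"]),
    gmt=str(paths["pathways"]), complexes=str(paths["complexes"]),
    diseases=str(paths["diseases"]), total_genes=cfg.n_genes, seed=11,
), "run/")
print(report["pathways"]["coverage_rate"])       # 100.0
print(len(report["essential_genes"]))            # 23
```

the modules cover 100 % of the network's 40 enriched pathways, and the
intersection of the hub consensus with the prioritizer's top decile
yields 23 predicted essential genes — on this synthetic bundle, every
one of them a planted disease-module gene.

The same chain is scriptable from a shell (`adnet simulate`, `adnet
build-net`, `adnet detect`, `adnet entropy`, `adnet rank`, `adnet
enrich`, `adnet assoc`, `adnet prioritize`, `adnet roc`, `adnet
overlap`, `adnet run`); see `adnet --help`.

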