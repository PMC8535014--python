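# Methods

This note records the models behind each stage, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data
do and do not establish.

## Network construction

The integrated network is a simple undirected graph over gene symbols.
Symbols are whitespace-trimmed, case-sensitive, and never alias-resolved;
identifier mapping is out of scope. Self-loops are refused and duplicate
edges merge their provenance tags (`ppi`, `coexpr`, `pathway`, `merged`),
so re-loading a file with repeated edges is idempotent.

The build order is fixed: merge the interaction networks, intersect with
the co-expression network, then add pathway co-membership cliques. Each
step is also exposed separately so other orders are scriptable.

*Co-expression.* An edge requires sample Pearson correlation strictly
above `pcc_threshold` (default 0.5). Genes with zero variance are
excluded (their correlation is undefined) with a logged count; at least
two samples are required.

*Intersection.* "Appears in both networks" is read as edge-set
intersection, keeping only endpoints of surviving edges. A node-set
variant (`on="nodes"`: common nodes, union of induced edges) is exposed
because the narrower reading is also defensible; edge intersection is
the default as it is the stricter confirmation requirement.

*Pathway co-membership.* Every unordered pair co-occurring in any
pathway set is linked and pathway genes join the node set. An optional
`restrict_to` confines this to a seed gene list, since linking all
pathway members can pull in genes outside the disease context.

## Module detection and entropy

*Network structure entropy.* E = −Σ I_i ln I_i with I_i the degree share
k_i/Σk. Zero-degree nodes are excluded (0·ln 0 treated as 0) and
counted in the report; an edgeless graph has no defined entropy and
raises. Any d-regular graph on N nodes attains E = ln N exactly, which
the tests assert to 1e−12.

*Partition entropy.* Applied to the intra-module graph: all module
members as nodes, only edges whose endpoints share a module. This
penalises divisions that orphan many edges, which is what makes entropy
informative for comparing divisions; computing it on the untouched
network would make every partition score the same. Whole-network entropy
remains available via `network_entropy`. Ties in the comparison table
are broken by method name, and every minimum-entropy method is flagged.

*MCODE.* Stage 1 weights each vertex by the highest core number of its
closed neighbourhood's k-core times that core's density. Stage 2 grows a
complex from the highest-weight unassigned seed, recursively adding
unassigned neighbours with weight ≥ (1 − vwp)·seed weight (vwp default
0.2). Stage 3 applies the 2-core haircut (default on), optional fluff
(boundary neighbours with closed-neighbourhood density > 0.2, a module
constant), and discards complexes without a `min_core`-core (default 2).
Vertices join at most one complex, so modules are disjoint by
construction; modules are numbered in decreasing score order, score =
density × size with density = 2E/(|V|(|V|−1)).

*MCL.* Self-loops of weight 1 are added, the adjacency matrix is column
normalised, and expansion (matrix power, default 2) alternates with
inflation (entrywise power, default 2.0, then renormalisation) and
pruning of entries < 1e−5 until the flow matrix changes by < 1e−6 or 100
iterations (non-convergence returns the current interpretation with a
warning). Clusters are the connected components of the converged
matrix's off-diagonal support; singletons are retained. Node order is
lexicographic throughout for reproducibility. Dense linear algebra is
used — appropriate for networks of a few thousand nodes, not for
hundreds of thousands.

## Hub indices and consensus

Eleven indices per node; conventions that the published definitions
leave open are fixed as follows.

- Closeness is the harmonic form Σ 1/d(v,w) so disconnected networks
  need no special casing (unreachable pairs contribute 0).
- BottleNeck builds one breadth-first shortest-path tree per root with
  lexicographic parent tie-breaks; a node scores a point in a tree when
  its subtree (itself included) holds ≥ |tree|/4 nodes. Single-node
  trees carry no paths and are skipped, so isolated nodes score 0.
- MNC is the order of the largest component of the open-neighbourhood
  subgraph (size-1 components count, so a star centre has MNC 1);
  DMNC divides that component's edge count by size^1.7 (the published
  constant).
- EPC is the only stochastic index: the mean, over `epc_reps` (default
  1000) random subgraphs keeping each edge with probability 0.5, of the
  fraction of other nodes still connected to v. The seed is recorded in
  the output. With keep probability 1 it reduces exactly to
  (component size − 1)/(N − 1).
- MCC sums (|clique| − 1)! over maximal cliques of size ≥ 2 containing
  the node; when a node's neighbourhood has no internal edge all its
  maximal cliques are single edges, so the stated degree fallback holds
  automatically.
- ECC sums, over incident edges, (triangles on the edge + 1)/min(k_u − 1,
  k_v − 1), dropping terms with zero denominator; node-level
  aggregation by sum (mean/max would be alternatives; sum preserves the
  degree-scale of the index).
- Radiality is computed within each connected component with that
  component's diameter and size.

The consensus screen ranks each index descending (ties by gene symbol
ascending), takes the top k (default 100), and selects genes appearing
in at least 7 of the 11 lists — the strict reading of "more than six".
The screen is invariant to index order and to any strictly increasing
transform of an index, which the tests assert.

## Enrichment and association

Over-representation is one-sided hypergeometric: p = P[X ≥ overlap] for
X ~ Hypergeom(universe, pathway size, query size), with
Benjamini–Hochberg correction and significance q < 0.05 by default. The
default universe is the union of pathway genes (overridable); the
pipeline overrides it with the total assayed-gene count, because a
query that nearly exhausts the pathway union can never look enriched
against it.

The association indices operate on enriched-pathway *sets*; the Pearson
index is the correlation of the two membership indicator vectors over a
universe of n pathways, with n taken from `PathwaySets.universe_size`.
It is undefined (reported as NaN, null in the pipeline report) when
either set fills the whole universe. Union sizes are always computed
via inclusion–exclusion from the actual sets, never trusted from
summaries. Coverage rate requires a non-empty original set.

## Prioritizer

Priors: a candidate in ≥ 1 complex pools the member union of all its
complexes before computing A/B (per-complex maximum is exposed as
`combine="max"`); B = 0 or no complex falls back to C/D; known focal
genes get prior 1 and are kept in fitting and scoring (reference
rankings also retain known genes). Labels: 1 iff u ≤ P with one uniform
draw per unknown gene — the boundary convention that makes prior 1
deterministic. Second-order neighbours are nodes at shortest-path
distance exactly 2, counted once.

The logistic log-likelihood Σ[x f − ln(1 + e^f)] − ridge‖ω‖² is
maximised by Newton iterations with step halving (the recorded objective
path is non-decreasing), gradient tolerance 1e−8, at most 200
iterations. The ridge (default 1e−6) guarantees a finite optimum under
complete separation, where the unpenalised problem has none; it is far
too small to matter otherwise.

A single label draw makes the posterior seed-dependent, so
`run_integrated` averages posteriors over `reps` independent draws
(default 50; reps = 1 reproduces the single-pass procedure). The
run-to-run spread of the averaged posteriors shrinks like 1/√reps; on
the 24-gene test problem it is ≈ 0.04 (mean absolute difference) at 50
reps and ≈ 0.009 at 800. Decision scores are percentile ranks with ties
sharing the higher rank, so the maximal posterior always scores 1 and
the scores are invariant under strictly increasing transforms. ROC uses
a full threshold sweep; the trapezoidal AUC equals the tie-corrected
Mann–Whitney statistic, which the tests verify by pair counting.

## Pipeline

The orchestrator chains build → detect (MCODE + MCL + optional external
partitions loaded from TSV) → entropy comparison → enrichment and
association on the winning partition (modules with < 3 genes or no
significant pathway are skipped, mirroring how empty modules are ignored
in practice) → hub consensus on the top-scoring module → prioritizer →
intersection. Two orchestration choices the stages themselves do not
dictate: k is clamped to the module size when the top module has fewer
genes than k (the library function errors instead, by contract), and
"prioritizer-selected" means decision score ≥ 0.9, i.e. the top decile
(configurable; no canonical cut exists for turning a ranking into a
set). Reports are JSON with sorted keys; a fixed seed yields
byte-identical reruns.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Network**: planted-partition graph; five modules of 40 genes inside
  400 total (half background), p_in = 0.6, p_out = 0.02.
- **Expression**: one latent factor per module,
  x = √ρ·z_module + √(1−ρ)·ε, ρ = 0.8, across 79 samples (the scale of
  a multi-tissue expression atlas); background genes are pure noise.
- **Pathways**: 40 sets of 10–24 genes, 90 % drawn from a home module,
  the rest random. Home modules are sampled with double weight on the
  disease module: disease-centred pathway catalogs over-represent the
  disease's functional module, and the extra pathway-clique edges make
  that module the densest — giving the pipeline a well-defined key
  module, the synthetic analogue of a dominant pathway-driven module.
- **Complexes and catalog**: 40 complexes of 4–10 genes, half seeded
  with disease genes (occasionally salted with a decoy-disease gene so
  B > A occurs); the catalog lists only the known 30 % of the disease
  module for the focal disease, plus two decoy diseases.

Deterministic per seed, with an independent stream per generator.

What this emulates — block community structure, block-correlated
expression, module-aligned gene sets, informative complex priors.
What it does not — scale-free degree distributions, overlapping
pathways/complexes of realistic depth, expression batch effects,
annotation noise. Passing tests therefore demonstrate that each
algorithm recovers the structure it targets when that structure is
present, not that real databases satisfy these assumptions.

## Problem sizes and known limitations

The test and demonstration problems use the 400-gene bundle above
(integrated network ≈ 230 genes), a 24-gene prioritizer unit problem,
5000 observations for logistic parameter recovery and a 2000-node graph
for ranking AUC; the exhaustive centrality cross-check covers all 996
connected graphs on 2–7 nodes against brute-force path and clique
enumeration.

On the default bundle the final essential set recovers 15 of the 28
unknown planted disease genes (54 %). This is a ceiling effect of the
top-decile intersection, not a ranking failure: all 40 disease-module
genes occupy the top 43 of 228 ranks, but the decile holds only ~23
slots and the 12 known genes legitimately compete for them, capping
expected recovery of unknowns near 57 % however good the ranking. Users
who want higher recall should lower `score_cut` or consume the ranking
directly.

Other limitations: dense MCL and dense feature matrices bound practical
network size to ~10⁴ nodes; the herb-network export uses node names
verbatim, so names must not collide across layers; GO-style ontology
structure is not modelled (generic gene-set enrichment covers the
computation).
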