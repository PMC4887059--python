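# Methods

This note records the models implemented in `stagenet`, the defaults and
why they were chosen, what the synthetic scenarios do and do not emulate,
and the numerical conventions that make every result deterministic.

## The screening funnel

The unit of analysis is the tumour stage. For each stage a set of
driver-prediction tools emits gene calls; the funnel applies, in order:

1. **Consensus**: keep genes called by at least `min_tools` tools
   (default 3 of 8). Tool calls are treated as sets; a tool's internal
   scores are not used.
2. **Stage subtraction**: remove the *immediately preceding* stage's
   consensus set (`subtract_mode="previous"`). The alternative reading —
   subtracting the first stage from every later stage — is preserved as
   `subtract_mode="stage1"`. Subtraction uses the preceding stage's
   *consensus* (pre-screening) set, since screening is applied after
   subtraction.
3. **Background screen**: remove drivers obtained when the whole cohort is
   pooled regardless of stage. When no background list is supplied it is
   computed from the pooled predictions: per tool, the union of its calls
   over all stages, then the same ≥ `min_tools` consensus. Whether a
   pooled background should use consensus or union is genuinely open; the
   consensus reading keeps the two screens symmetric and is the default.
4. **Census screen**: remove genes in a curated known-cancer-gene list.

Each step is a set difference, so the funnel is monotone by construction;
this invariant is property-tested on random inputs.

## Network reconstruction

Stage networks are built by local seed expansion of a weighted
interactome: every non-seed gene is scored by the total weight of its
edges to the seed set, the top `n_partners` genes (ties broken
lexicographically) are added, and the network is the interactome subgraph
induced on seeds plus partners. Seeds absent from the interactome are kept
as isolated flagged nodes. Edges can be restricted to a configured set of
interaction types (physical / ppi / predicted).

`n_partners` defaults to 20, the conventional "related genes" count of
interactive seed-expansion services. The synthetic study conditions use 80
(`ScenarioConfig.n_partners`), which reproduces the roughly 1:3
seed-to-partner ratio of the real stage networks this pipeline emulates
(about 27 seeds expanding to about 109 nodes).

**Degree-distribution fit.** The degree histogram (raw counts, zero-degree
nodes excluded) is fitted two ways: OLS of log₁₀ count on log₁₀ degree
(the power law) and OLS of count on degree (the linear alternative); a
higher power-law R² indicates fat tails, i.e. the presence of hubs. A
zero-variance log-response (all counts equal) makes R² undefined; it is
reported as 1.0 with a `degenerate` flag rather than NaN so downstream
comparisons never see missing values.

**Topology summary.** Node/edge counts, connected components, mean local
clustering (nodes of degree < 2 contribute 0), and the diameter and mean
shortest-path length of the largest component. Multi-component networks
are permitted (with a warning); the builder never forces connectivity.

## Centrality and hub calling

All three metrics use unweighted shortest paths — edge weights carry
evidence provenance, not distance — matching the convention of the
Cytoscape centrality plugins this mirrors.

* **Betweenness**: Brandes' exact accumulation; each unordered pair
  counted once; no normalization (ranking-invariant).
* **Closeness**: `(reachable − 1) / Σ distances`, computed within the
  node's component; isolated nodes score 0.
* **Bottleneck**: for each root *s*, a deterministic BFS shortest-path
  tree is built with each node's parent chosen as the lexicographically
  smallest equal-distance predecessor. A non-root node is a bottleneck for
  *s* when its subtree size strictly exceeds *n_s*/4, where *n_s* counts
  reachable nodes excluding the root; its score is the number of electing
  roots. Bottleneck centrality is a definition family: the tree tie-break,
  the strictness of the comparison and whether *n_s* counts the root all
  vary between implementations. The choices here make the score
  deterministic and are switchable (`strict`, `count_root`).

Hubs are the intersection of the three top-`k` lists (default k = 15, ties
broken lexicographically so exactly k genes are ranked); hub drivers are
hubs that are also stage driver seeds. `verify_tables` applies exactly
this logic to externally transcribed ranking columns, which is how the
bundled published tables are checked.

## Overlapping module decomposition

A deterministic community-landscape method in the spirit of overlapping
module detectors built on influence functions:

* **Influence**: personalized random-walk-with-restart over the
  degree-normalized adjacency (restart 0.15, iterated to 1e-8); row *i* is
  node *i*'s stationary spreading vector. Verified against a dense linear
  solve in tests.
* **Landscape height** of a node = total incoming influence.
* **Centers**: nodes whose height is ≥ all neighbours' with strict excess
  over at least one (or isolated nodes). A perfectly flat maximum plateau
  (e.g. a complete graph) would otherwise yield no center; it contributes
  its lexicographically smallest member. Plateau members that individually
  have strict excess over outside neighbours each remain centers — two
  equal-degree cliques joined by one bridge edge give one center per
  clique.
* **Memberships**: node *j*'s membership in module *c* is the influence of
  center *c* on *j*, normalized over centers (rows sum to 1).
* **Effective size**: participation ratio (Σm)²/Σm² of a module's
  membership column — the number of nodes the module effectively contains.
  Reported member lists use a membership threshold of 0.3.

The exact algorithm family behind the original module tables is
unspecified and parameter-dependent; this decomposition reproduces their
qualitative output (overlapping modules, centers, effective sizes) while
being fully specified, deterministic and label-permutation-equivariant.
Exact reproduction of published module tables is therefore not a target.

## Enrichment

One-sided over-representation only: `P(X ≥ k)` for X hypergeometric
(universe N, term size K, annotated network genes n), computed with
scipy's log-space survival function and verified against exact rational
enumeration for all small universes (N ≤ 60). The universe defaults to all
genes in the annotation collection ("complete annotation"); a reference
set can be supplied. Terms are tested only when at least one network gene
carries them, and the Benjamini–Hochberg step-up correction runs over the
tested terms (three GO namespaces should be supplied as separate
collections and are then corrected independently). The ">20 %" flag marks
terms with k/K > 0.2.

Because the hypergeometric test is discrete it is conservative: under a
simulated null its rejection rate at p < 0.05 sits slightly below 0.05.
The calibration test uses 200 replicates of one random 150-gene term
against one random 150-gene network in a 2000-gene universe — large
enough counts that the attainable level stays within the 99 % binomial
band around the nominal level.

## The synthetic scenario generator

`ScenarioConfig` defaults describe the study conditions the pipeline
emulates: 4 stages, 8 tools, a 1000-gene interactome, tens of true drivers
per stage (30/25/25/25 new stage-specific drivers plus a 20-gene pan-stage
core and 25 % carryover between consecutive stages), tool sensitivity 0.9
and about 5 false positives per tool per stage (`tool_fpr` = 0.005).

* **Interactome**: preferential attachment (2 edges per new node) from a
  small connected core, giving a scale-free backbone (log-log R² ≥ 0.7 at
  2000 genes). Novel drivers are drawn from the peripheral 90 % of the
  attachment order: mega-hub housekeeping-like genes are not plausible
  novel stage drivers, and planting modules on them would confound the
  landscape.
* **Planted hub drivers**: per stage after the first, 3 module centers are
  chosen among that stage's new drivers. Each center is wired to a 12-gene
  dense neighbourhood (4 same-stage driver members, disjoint across the
  stage's modules, plus 8 pool genes; member–member edge probability 0.8)
  and to an 18-gene fringe whose members touch the center and a geometric
  number of module members. Planted edges carry confidence weight 2.0 —
  curated interactions rest on more evidence than background links — which
  is what lets weighted partner scoring assemble the module in the stage
  network. The fringe gives centers the degree excess, subtended
  neighbourhood and smooth low-degree tail of real hubs.
* **Pooled background**: tools are re-run on the "pooled cohort": the
  pan-stage core is seen at full sensitivity, stage-specific drivers at
  sensitivity × `pooled_dilution` (default 0.1) — any one stage's samples
  are a minority of the pool, so its specific drivers rarely reach
  consensus there. Without this dilution the pooled background would
  swallow every stage driver and the funnel would always end empty.
* **Census**: drawn from genes outside all truth sets, so the novelty
  filter cannot destroy planted structure; `census_overlaps_truth=True`
  makes it swallow half of each stage's non-center novel drivers instead,
  for testing the filter.
* **Annotations**: 50 random terms (10–40 genes) plus one planted term per
  stage holding 8 genes of the stage's first module.

Everything is deterministic given the scenario seed (per-component
generators derived from it), and `generate_scenario` writes byte-identical
bundles on re-runs.

**What the generator does not emulate**: sample-level mutation data (tools
emit gene sets directly), correlated tool errors (real tools share
signals, so consensus counts are optimistic here), gene-length or
mutation-rate biases in false positives, literature-biased interactome
degree, and GO term overlap structure (terms are near-independent draws).
Passing recovery tests therefore shows the pipeline's logic is sound under
its stated error model, not that real-data outputs would reach the same
accuracy.

Under the default scenario the pipeline recovers ≥ 80 % (typically 100 %)
of planted hub drivers, every planted module center, and a power-law R²
above the linear R² for every stage network.

## Problem sizes and determinism

Exhaustive oracle checks run on all 771 labeled connected graphs with ≤ 5
nodes plus 100 random graphs with ≤ 12 nodes — sizes at which brute-force
path enumeration is exact and fast; the hypergeometric oracle sweeps
universes up to N = 60 on a stride grid. The default scenario (1000 genes,
~105-node stage networks) keeps a full end-to-end run under a few seconds.
All randomness flows through explicit seeds; ranking and tie-break rules
(lexicographic throughout) remove every source of platform-dependent
ordering.

## Known limitations

* Gene identity is the uppercased symbol string; no alias resolution.
* The bottleneck dialect (tree tie-break, strictness) matches no single
  published implementation exactly; rankings from other tools can differ
  on tie-heavy graphs.
* The XGMML reader supports the Cytoscape dialect subset it needs (node
  labels, edge endpoints, flat attributes); exotic documents are read with
  warnings, not rejected.
* GO annotations must arrive pre-propagated; no ontology-graph handling.
* Closeness is computed per component, so very small components can crowd
  the top-k list in fragmented networks; the expansion defaults are chosen
  to keep stage networks dominated by one giant component.
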