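# Methods

## Interactome model

The interactome is an undirected simple graph over opaque, case-sensitive
gene identifiers.  Physical binding has no direction, so duplicate and
reversed edge-list lines collapse to one edge and self-loops are dropped
(with a logged count).  The full graph is used as-is — no restriction to
the largest connected component; unreachability is represented by an
explicit sentinel (`UNREACHABLE`, +inf) that propagates through `min()` as
the largest element, and is handled downstream rather than imputed.  Genes
in a query or disease set that are absent from the graph are dropped with
a logged count; a set that maps to nothing raises.

Degree bins for degree-matched sampling merge ascending degree classes
until every bin holds at least `min_occupancy` nodes (default 100, the
common practice for degree-preserving nulls on interactomes of ~10⁴
nodes; configurable because small synthetic graphs need smaller bins).  A
trailing undersized class is merged into its predecessor, so bins always
partition the node set.

## Proximity statistic

For query set *Q* and disease gene set *D*, the observed distance is the
mean over *q* ∈ *Q* of the minimum BFS distance from *q* to *D*
("closest" distance).  Query proteins that reach no disease gene are
excluded from the mean and counted, never assigned a pseudo-distance —
imputation would bias *z* invisibly.  A multi-protein query is combined by
averaging each protein's minimum distance; this is the natural set-level
extension of the closest measure and is recorded in the run metadata of
every output.

The null model (default) redraws the disease side: `n_random` = 1000
uniform without-replacement gene sets of size |*D*|.  Alternatives are
selectable because the two are not equivalent and both appear in the
literature: `randomize_side="query_proteins"` redraws the query side
instead, and `matching="size_and_degree"` draws each replacement from the
donor's degree bin (falling back to uniform, with a warning, when a bin is
exhausted).  z uses the sample SD (*n*−1); a degenerate null (SD = 0)
yields z = 0 when the observed equals the null mean and a signed infinity
otherwise.  p = Φ(z) one-sided (sentinel infinities map to 0/1);
Benjamini–Hochberg adjustment (statsmodels `fdr_bh`) is applied within
each query across its diseases, flagged at α = 0.25 by default.

Determinism: replicate *i* of a pair uses RNG substream `seed + i`; pair
seeds are derived as `master_seed + 100003·pair_index`.  Identical inputs,
config and seed give bit-identical tables.

## Diseasome layers

All four layers share one disease node set (the post-redundancy-filter
disease–gene map); diseases missing from the symptom or comorbidity source
stay in the node set with degree 0 rather than shrinking the averaging
denominator.  All thresholds are strict inequalities (*n* > 0, *z* > 0,
*J* > 0.5, RR > 1) — boundary cases (a symptom score of exactly 3.5, RR
exactly 1) produce no edge.

The vocabulary redundancy filter is a greedy pass over diseases sorted by
descending gene-set size, ties broken lexicographically; a disease is
dropped iff its Jaccard index with an already-kept disease exceeds the
threshold (default 0.5).  The ordering is an explicit determinism choice:
with near-duplicate terms, *which* of the pair survives is otherwise
arbitrary, and keeping the larger set retains more information.

Interaction counting: the score of a disease pair counts distinct graph
edges with one endpoint in each gene set; an edge with both endpoints in
the intersection counts once; symmetric by construction.  The null draws
1000 random set pairs of matched sizes uniformly from the graph's nodes
and the edge criterion is z > 0 at the default.  Symptom similarity uses
Jaccard on TF-IDF-thresholded symptom sets; cosine similarity on the raw
TF-IDF vectors is a plausible alternative reading but changes the edge
semantics, so the set-based rule is the default and only implemented
variant.

## Centrality

Degree is the raw within-layer edge count, not normalized — with ~10
diseases in a cluster the integer degrees are the interpretable quantity.
The cross-layer score is the arithmetic mean of per-layer degrees; rank
ties are broken by disease name ascending and reported explicitly.  The
robustness check recomputes the mean after removing one layer (typically
the interactome layer, whose data incompleteness is the usual worry).

## Synthetic data

The generators emulate the statistical shape of the real inputs, not
their content:

* **Graph** — preferential attachment (3-clique seed, `attachment` edges
  per new node; edge count C(m0,2) + (n−m0)·m) gives the heavy-tailed
  degree distribution of real interactomes; an Erdős–Rényi mode exists for
  calibration studies where degree heterogeneity would confound a
  size-matched null.
* **Modules** — grown by random walk with restart; `module_locality` (the
  probability the next gene comes from the module's graph neighborhood)
  tunes modules from uniform random sets (0) to connected subgraphs (1).
  Pairwise overlaps are forced exactly by shared seed genes, and growth
  only claims genes no other module holds, so `gene_layer` recovers the
  planted overlap matrix exactly.  Default locality 0.5: real disease
  modules are localized but not connected.
* **Query** — drawn from nodes at exactly the configured distance from
  the target module (inside it for distance 0); when too few exist, an
  outside node is re-wired by one added edge to a node at distance d−1.
* **Symptoms** — non-similar diseases get disjoint symptom blocks from
  the vocabulary, so zero planted similarity implies an empty symptom
  layer by construction; a similar pair shares 70% of its symptoms with
  shared symptoms scored strongly on both sides, putting the strong-set
  Jaccard above 0.5.  Scores are uniform on (4, 8) above the 3.5 cutoff
  and (0.5, 3.4) below.
* **Comorbidity** — a configured fraction of pairs draws RR uniform on
  (1.2, 3), the rest on (0.3, 0.9).
* **Hub scenario** — one disease planted central in all four generators:
  one shared gene with every other disease, extra cross-module edges to
  every module (default 8, pushing the wiring z well above 0), forced
  symptom similarity and RR > 1 with all partners.

What passing tests on these fixtures shows: the statistics recover planted
structure of realistic effect size under realistic sparsity, and the
machinery is deterministic and correctly calibrated.  What they do not
show: performance under annotation bias, study-driven degree inflation of
disease genes, or identifier-mapping noise — properties of real curated
sources that the generators deliberately do not model.

## Calibration and recovery studies

`netmed.benchmarks` packages three studies (also run by
`scripts/acceptance.py`):

* **Null calibration** — 200 trials on 200-node Erdős–Rényi graphs
  (p = 0.03), disease set of 20 and query of 3 drawn uniformly *with
  overlap allowed*, so the observed statistic is exchangeable with the
  1000 null replicates; z should then be approximately standard normal.
  (Excluding the query from the disease set would bias z positive, since
  null sets may contain query proteins.)
* **Planted-proximity recovery** — 50 scenarios (500 nodes, 10 diseases,
  20-gene target module, 3-protein query at distance 1); the planted
  disease should attain the minimum z in ≥ 90%.
* **Planted-hub recovery** — 50 hub scenarios; the hub should rank first
  in cross-layer average degree in ≥ 90%.

Problem sizes (500-node graphs, 10 diseases, 1000 null replicates, 50
seeds) were chosen so each study finishes in well under two minutes on one
CPU while keeping the Monte-Carlo error of a recovery rate below ~5
percentage points.

## Numerical and degenerate-input conventions

* Distances are integers; UNREACHABLE is +inf and never enters means.
* z with constant null: 0 if the observed equals the null mean, else ±inf
  (mapped to p = 0/1).
* Jaccard of two empty sets is undefined and raises; a disease with an
  empty filtered symptom set simply has no symptom edges.
* BH on an empty p-value list returns empty lists; per-pair proximity
  failures become NA rows with a reason, never abort the table.
* All sampling uses numpy `default_rng` with derived integer seeds below
  2³¹; per-replicate substreams make results independent of chunking.

## Known limitations

* Published proximity z-scores are not reproducible here: they depend on
  the original curated interactome and OMIM/GWAS disease-gene sets, which
  are not redistributable.  The package validates the machinery on planted
  synthetic ground truth instead, and ships the published summary tables
  only as arithmetic fixtures.
* The interaction-layer null randomizes set membership but not graph
  topology; with strongly localized modules the z > 0 criterion is
  deliberately permissive (roughly half of random pairs pass), matching
  its role as a "non-spurious relationship" filter rather than a
  significance test.
* Exact planted gene overlaps constrain module growth (modules cannot
  share genes beyond the overlap matrix); realized modules are therefore
  slightly more disjoint than real disease modules, which share genes
  promiscuously.
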