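# Methods

## Data model and conventions

The pipeline's currency is a simple undirected graph (`networkx.Graph`)
whose nodes are non-empty string identifiers with a `role` tag (component,
target, interactor, seed, generic).  Self-loops are dropped on ingestion
with a logged count and duplicate edges collapse, because every downstream
statistic (the six centralities, MCODE's density arithmetic) assumes a
simple graph.  Edges serialize under a canonical lexicographic pair
ordering, so write/read round-trips are exact set equalities and identical
runs produce byte-identical artifacts.

Gene symbols are uppercased and whitespace-stripped on ingestion
(idempotent), since disease-gene databases mix case conventions; generic
interactome identifiers are left case-sensitive, as interactome IDs may be
case-meaningful.  Identifier mapping beyond a user-supplied two-column join
is out of scope.

## ADME screening

Components are kept when OB ≥ `ob_min` (percent, default 20) and DL ≥
`dl_min` (unitless, default 0.18), both inclusive.  Records with a missing
OB or DL fail the numeric filter — screening is on stated values only, a
missing measurement is not a zero.  Curation-based retention is an explicit
`manual_keep` table flag rather than a hard-coded name list: which
components a study keeps for their reported pharmacology is data, not
algorithm.  The filter is idempotent and monotone in both thresholds.

## Target mapping

Disease targets from several sources are unioned after normalization; the
common-target set is the intersection with the formula's predicted targets.
The component–target bipartite network has one node per distinct component
and target and one edge per distinct pair.  Candidate components are those
with degree at least a threshold; the default threshold is the interpolated
median of the *component-node* degrees (target nodes excluded), and the
comparison is ≥, so with heavily tied degree distributions well over half
the components can qualify.  An explicit numeric threshold is accepted.

## PPI assembly

Seed expansion takes every interactome node within `max_hops` (default 1)
of a seed and, by default, the full induced subgraph on that node set —
neighbor–neighbor edges included, which is what lets a couple of hundred
seeds grow into a network of thousands of nodes against a real interactome.
Seeds absent from the interactome are kept as isolated seed-role nodes and
logged, so the seed accounting stays visible.  With `max_hops=0` the result
is the induced subgraph on the seeds themselves.

Two expanded networks are merged by **intersection** (common nodes, common
edges) by default — the merged result being smaller than either input is
only coherent under intersection semantics — with union available as an
option.  Nodes isolated by the edge intersection are dropped by default
(`drop_isolated`); the screen's medians are therefore computed without
them, which is documented here because it shifts every median-derived
cutoff.

## Centrality statistics

Conventions (all on unweighted undirected graphs):

- **BC** unnormalized, summed over unordered pairs, per connected
  component; a star center with 4 leaves scores C(4,2) = 6.
- **CC** = (nodes reachable)/(sum of distances to them), 0 for isolated
  nodes.  This "reachable" normalization keeps CC in [0, 1] on disconnected
  networks without a Wasserman–Faust small-component penalty.
- **EC** is computed by shifted power iteration on A + I (same principal
  eigenvector as A, but a guaranteed spectral gap, so bipartite components
  cannot oscillate), L2-normalized over the largest connected component and
  0 elsewhere.  Restricting to one component is deliberate: a principal
  eigenvector has no canonical relative scaling across components.  A
  per-component mode normalizes each component separately.  Tolerance
  1e-10 on the max-norm update step, 1000 iterations, with a convergence
  error reporting the residual otherwise.
- **LAC** averages, over v's neighbors, their degree inside the subgraph
  induced on N(v).
- **NC** sums edge clustering coefficients ECC(u,v) = z/min(deg u −1,
  deg v −1) over incident edges, with the denominator-zero convention
  ECC = 0 (a degree-1 endpoint supports no triangle).  The alternative
  (z+1)/min(·) variant used by some implementations is available via
  `plus_one`; the default is the plain-z convention.
- **SC** (subgraph centrality) and **IC** (information centrality) are
  implemented but off by default; the screening chain uses the six
  measures above.

Degree, betweenness and closeness delegate to networkx with the flags that
realise these conventions; eigenvector iteration, LAC and NC are
implemented here.  The test suite checks all five non-trivial measures
against independent brute-force oracles (explicit shortest-path
enumeration, dense eigendecomposition, induced-subgraph counting, triangle
enumeration) on hundreds of random graphs of ≤ 15 nodes at 1e-8.

## Two-stage core screen

Stage 1 keeps nodes with DC ≥ `multiplier` × median DC (interpolated
median over all nodes, default multiplier 2, inclusive ≥) and induces the
subgraph.  On any k-regular graph stage 1 is empty — an algebraic
consequence of k < 2k — which the tests assert.

Stage 2 **recomputes all six measures on the stage-1 subnetwork** and by
default sets each cutoff to that measure's interpolated median there; core
nodes must *strictly* exceed all six cutoffs simultaneously.  Recomputing
on the reduced network is the only reading under which a stage-2 degree
cutoff can exceed the stage-1 entry threshold, as published screens of this
family show.  The median rule is the convention of the topological
screening literature; since published runs print their cutoffs without
stating the rule, an explicit-cutoff mode reproduces any externally given
values verbatim.  Strictness means a vertex-transitive stage-1 network
yields an empty core (no node strictly beats its own constant), also
asserted in the tests.

## MCODE

Vertex weight = (core number k of the highest k-core of the closed
neighborhood) × (density of that k-core); nodes under `degree_cutoff`
(default 2) weigh 0.  Complexes grow greedily from the highest-weight
unclustered node, admitting neighbors with weight ≥ seed weight × (1 −
VWP), VWP default 0.2, depth-limited by `max_depth`; a node joins at most
one cluster.  Clusters lacking a 2-core are discarded; `haircut` (default
on) iteratively prunes members with fewer than two connections into the
cluster; `fluff` (default off) adds boundary nodes whose
closed-neighborhood density exceeds `fluff_density` and may share them
between clusters.  Scores are density × size of the final member set; all
ties (seed choice, cluster order) break on node-identifier order, making
the procedure deterministic.  If the haircut prunes the expansion origin,
the reported seed is reassigned to the highest-weight remaining member so
the seed always belongs to its cluster.  Defaults mirror the published
plugin defaults.

## Enrichment

p_raw = P(X ≥ k) under Hypergeometric(N, K, n), via `scipy.stats.hypergeom`;
EASE mode replaces k by k−1 (floor 0 ⇒ p = 1), the conservative DAVID-style
score.  The Bonferroni multiplier counts only terms with non-zero overlap,
matching DAVID-style reporting; a total-term multiplier is a flag away.
The background defaults to the union of all annotated genes and can be set
explicitly (e.g. to the interactome size) — with an annotation-union
background, unannotated query members are dropped and logged.
Significance filtering is strict (< α) on either the Bonferroni or the raw
column.

## Synthetic data: what it emulates, and what it does not

Each generator is a pure function of (parameters, seed); a pipeline-wide
seed fans out to per-stage child seeds via `numpy.random.SeedSequence`
spawn keys, so one integer reproduces an entire fixture byte-for-byte.

- **Components**: the pass fraction controls exactly how many records draw
  OB ~ U(20, 60) and DL ~ U(0.18, 0.5); the rest fail at least one
  criterion (a few via missing values), and a chosen number of failing
  records carry the curation flag.  Uniform ADME distributions are a
  stand-in — real component tables are not uniform — so the generator
  validates the *filter*, not ADME science.
- **Component–target pairs**: truncated discrete power-law degrees
  (exponent 2.2) rescaled to a requested mean, targets drawn uniformly per
  component; any uncovered target is attached to the highest-degree
  component so the realized target universe is exact.  Real ligand-based
  predictions correlate targets across chemically similar components; this
  generator does not.
- **Disease lists**: exactly round(overlap_fraction × n) members come from
  the formula target set, the rest avoid it, so the common-target count is
  planted, not approximate.
- **Interactome**: preferential attachment (m per arrival, clique start ⇒
  exactly C(m,2) + m(n−m) backbone edges) gives the heavy-tailed degrees of
  real interactomes but not their true degree sequence or clustering.
  Planted modules draw internal edges with p_intra over disjoint node
  sets; backbone edges *between two different modules are removed*
  (planted-partition semantics) so module membership is a well-posed
  ground truth — without this, a single random backbone bridge between two
  planted cliques carries full clique-level vertex weights and the greedy
  expansion correctly (per the algorithm) merges them, making "recover the
  planted modules" an ill-defined ask.  Modules remain wired to the
  background.  Hubs are drawn from the first module when one exists, so a
  planted hub is dominant on triangle-based statistics (LAC, NC) as well
  as on degree and shortest-path statistics.
- **Annotations**: random term sizes in a range; the spiked term is
  rebuilt to contain a `strength` fraction of a designated query, so at
  strength 1 it attains the minimal p for that query.

The study-shaped preset fixes the conditions the pipeline is exercised
under: 600 components across four herbs (230/85/280/5) with pass fraction
0.22 plus 9 curated keeps (→ 141 bioactive), 186 formula targets over 118
components at mean degree ~21, 546 disease targets sharing exactly 52, a
1500-node m=3 interactome with a 40-node p=0.6 module around one
degree-300 hub plus two 12-node p=0.9 modules, and 50 annotation terms
with the hub module spiked into one of them at strength 0.9.  The
interactome is two orders of magnitude smaller than a merged six-database
human interactome; the preset preserves the *shape* of the analysis (count
trail, screening behavior, module recovery), not the published network
sizes, and the problem sizes above are the ones every test and the
acceptance script use.  Passing on this fixture shows the chain's logic
and determinism, not that any particular biological conclusion transfers.

## Pipeline

All stage artifacts are materialized (TSV/GraphML/JSON) — a multi-stage
screen should be auditable — and the report's count trail is re-derivable
from them.  Reports contain no timestamps; identical config + inputs +
seed reproduce every artifact byte-for-byte.  A stage failure aborts with
the stage name, retaining partial artifacts.  An *empty* result (e.g. a
multiplier so large stage 1 keeps nothing) is not an error: downstream
stages report empty and the run completes.

## Known limitations

- No weighted or directed network variants; interaction confidence scores
  are ignored on ingestion.
- Enrichment implements Bonferroni only (by design — the screening
  tradition this follows reports Bonferroni and raw p), no FDR.
- The expansion policy is hop-based; no degree-normalized or
  confidence-weighted expansion.
- MCODE is the only clusterer; no MCL/Louvain comparison.
- The synthetic interactome's clustering structure is cruder than real
  PPI data; conclusions about recovery rates on real interactomes should
  be drawn from real interactomes.
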