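# Methods

## Model and assumptions

`stagewalk` operates on four stage-specific molecular networks over a
shared identifier space. Each network is undirected and simple, vertices
are typed (gene, miRNA, lncRNA), and only four endpoint-kind
combinations are admitted: gene–gene, miRNA–lncRNA, gene–miRNA,
gene–lncRNA. Identifiers are opaque, case-sensitive strings; no symbol
normalization is attempted. Vertices present in the type map but absent
from every edge are kept as isolates — they may still start walks, and
dropping them silently would mask input errors. Module identity is never
assumed across stages: S1M1 and S2M1 are distinct nodes whose
relationship, if any, is expressed by an inter-stage Jaccard edge.

## The walk statistic

For a stage network G and configuration (N, R, β, q):

- From every vertex, R independent walks of up to N − 1 uniform-random
  neighbor steps are run. Walks are not self-avoiding; every visit is
  recorded. A vertex with no neighbors ends its walk early (truncated);
  truncated walks are not restarted, so their undistributed weight is
  simply lost.
- The visit at step t contributes N − t, so a complete walk distributes
  exactly N(N+1)/2 raw weight (a conservation identity the test suite
  checks exactly).
- Each contribution to vertex v is divided by the penalty
  (deg(v)/d̄)^β, with d̄ the mean degree over non-isolated vertices and
  penalty 1 for isolates. Aggregated weights are divided by R so tables
  are comparable across replicate counts.
- Vertices with weight strictly above the empirical q-quantile
  (numpy linear interpolation) of the stage's weight distribution are
  selected. With all weights equal, nothing is selected.

Determinism: each walk draws from its own substream keyed by
(master seed, stage, start vertex, replicate) through BLAKE2b, so
results are independent of execution order and exactly reproducible.

### Choice of β and the selection quantile

A random walk visits vertices roughly in proportion to degree, so some
penalization is needed to keep hubs from dominating. Full degree
correction (β = 1) overshoots, for a structural reason: the constant
start-weight N that every vertex pays to itself is also divided by the
penalty, handing degree-1 peripheral vertices a d̄/deg boost that
*inverts* the ranking on the benchmark fixture (background vertices
296 ± 222 vs module vertices 194 ± 9). β = 0 leaves the hub bias in
place. The default β = 0.5 dampens hub advantage while preserving the
locality signal (module 232 ± 26 vs background 166 ± 96 on the
benchmark); both failure directions remain reachable through config.

The selection quantile defaults to the median (0.5). A quantile of x
caps the selected set at ~(1 − x)·n vertices; any choice near 0.8 would
make it arithmetically impossible to form K modules of ≥ 5 members
whenever K·5 exceeds 0.2·n, as on the benchmark. The median is the
natural uninformative split of a weight distribution expected to be
bimodal (module vs background) when the method's premise holds.

## Module screening

For selected vertices u, v, let A and B be their closed neighborhoods
intersected with the selected set. The pair score is |A∩B|/|A∪B|
(well defined: the union always contains u and v). Pairs scoring
strictly above the overlap threshold are retained; retained pairs are
merged transitively (union-find), and each merged vertex list is split
into the connected components it induces on the original stage network.
Components of ≥ `min_module_size` (default 5) vertices become modules,
numbered M1… by descending size with ties broken by smallest member id;
smaller fragments are logged and dropped.

Two calibration decisions matter:

- **What a passing pair contributes** (`union_mode`). The default is the
  pair {u, v} itself, making clusters the connected components of the
  pairwise-overlap relation — the shared-nearest-neighbor reading.
  Contributing the full neighborhood union instead (also available) is
  strictly more aggressive: any selected neighbor of u enters u's
  retained sets, so one spurious background edge between two dense
  regions chains them into a single cluster; on the benchmark this
  collapses all planted modules into one.
- **The overlap threshold** (default 1/3). An adjacent pair with *no*
  shared selected neighbor still scores 2/|A∪B|, so thresholds at or
  below ~0.2 accept bare adjacency whenever neighborhoods are small, and
  single random inter-module edges pass the screen. Requiring a score
  strictly above 1/3 means adjacency alone never suffices once the two
  neighborhoods span ≥ 6 vertices; merging demands genuinely shared
  neighborhood structure. Intra-module pairs on the benchmark score
  ~0.4–0.7.

Restricting neighborhoods to the selected set means an unselected
low-weight vertex can never re-enter a module. When removing such a
vertex disconnects a candidate cluster, the component split handles the
two halves independently — each survives or falls by the size rule.

## Stage linking and enrichment

Same-stage module pairs are linked by the raw count of stage-network
edges crossing between them (zero counts suppressed). Adjacent-stage
pairs are linked by the Jaccard coefficient of member sets; every
positive value is kept in the global module network, while the stricter
inclusive J ≥ 0.1 cut belongs to core-evolution extraction. Non-adjacent
stage pairs are never linked.

Enrichment is the upper-tail hypergeometric probability
P(X ≥ k) for drawing |module ∩ universe| ids from the universe with
|term| successes — the standard over-representation test. The universe
defaults to the union of all GMT members and can be overridden by an
explicit universe file. By default only gene-kind members are tested
(annotation collections are gene-centric); a flag admits all kinds for
fully synthetic runs. BH-FDR correction is applied across all
(module, term) tests within a stage, matching per-stage screening; a
global-correction flag exists. Terms pass at q ≤ 0.05.

The design comparison feeds the same test three input shapes per stage —
all stage vertices (Design1), pooled selected vertices (Design2), and
per-module with the minimum q per term (the modular design) — and
tabulates Q′ = −ln q, with 0 encoding absence or q = 1.

## Comprehensive and core networks

Function nodes are instantiated per (stage, term); function–function
edges inherited from the term-level network are drawn within each shared
stage, keeping the stage structure intact, while cross-stage function
links appear only as explicit evolution edges in the core network.
Module degree for core selection counts all incident edge classes
(module–module, module–function); the inclusive threshold is degree ≥ 5.
`degree_summary` reports the fraction of modules below threshold next to
the analytic standard-normal one-sigma mass (computed from the
distribution, ≈ 0.6827), the reference that motivates the rule. Core
functions are function nodes adjacent to at least one core module. The
core evolution network is the induced subgraph on core nodes with
inter-stage module edges filtered to J ≥ 0.1 (inclusive) and
function-evolution edges between adjacent stages for identical terms or
terms whose gene sets reach the same Jaccard bound; both linking rules
are individually toggleable.

## The synthetic benchmark

`SyntheticSpec` defaults define the standard study conditions: 4 stages,
K = 4 planted modules of m = 12 vertices, b = 40 background vertices,
intra-module edge probability p_in = 0.6, background probability
p_out = 0.02, drift ρ = 0.25 (each module resamples ⌈ρ·m⌉ members from
background genes between adjacent stages), generator seed 7. Planted
members are genes; miRNA/lncRNA mass lives in the background
(fractions 0.4/0.3/0.3), so the gene-only enrichment path is exercised
realistically while intra-module edges always satisfy the whitelist.
Candidate background edges with forbidden endpoint kinds are rejected
outright — a fixed pair cannot be "resampled" into a legal kind — which
slightly lowers the effective background density among non-gene
vertices. The GMT collection holds one gene set per module lineage (the
union of its members across stages) plus 15 random decoy sets.

What the generator does *not* emulate: expression-level noise, degree
heterogeneity within modules, overlapping ground-truth modules,
incomplete or biased annotation, and realistic network sizes. Passing
the recovery tests therefore shows the algorithm behaves as designed in
its intended regime, not that it would recover modules in noisy
experimental networks of thousands of vertices.

Recovery is scored as the Adjusted Rand Index between recovered module
labels and planted lineages *over the assigned vertices* (background as
its own truth label), with coverage reported separately — the quantile
screen bounds coverage by construction, so an all-vertex ARI would
conflate purity with the deliberate screening rate.

## Numerical and degenerate-input conventions

- Quantile: numpy's default linear interpolation; selection is strictly
  greater, so constant weight tables select nothing.
- Jaccard of two empty sets is 0 by convention.
- Walks from isolated vertices yield a single visit of weight N.
- p-values are required to lie in (0, 1]; q-values come from the
  standard BH step-up with monotonicity enforcement.
- Empty gene sets are skipped with a warning; duplicate GMT term ids are
  an error.
- Module numbering ties break lexicographically on the smallest member
  id, making every artifact byte-reproducible under a fixed seed.

## Known limitations

- The walk stage is O(|V| · R · N) per stage in pure Python; it is
  comfortable at benchmark scale (~10⁵ steps/s) but would need batching
  or compilation for networks with 10⁵+ vertices.
- Truncated walks lose their remaining weight, slightly deflating
  weights in fragmented networks.
- Modules within a stage are disjoint by construction; overlapping
  within-stage community structure is out of reach of the screen.
- The enrichment surrogate ignores annotation-term hierarchy (no GO DAG
  ancestry), and treats gene sets as flat.
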