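# Methods

## Model and procedure

`pathcrosstalk` implements over-representation analysis (ORA) and the
downstream network summaries that turn a flat enrichment table into a
pathway-level systems view.

**Enrichment.** The overlap k between a query of n genes and a gene set
of K genes, both drawn from a universe of N genes, is scored with the
upper-tail hypergeometric probability P(X ≥ k) — the observed count is
included in the tail, matching the convention of the MSigDB "Compute
Overlaps" tool. The tail is accumulated in log space as a
log-sum-exp of log-pmf terms: printed p-values in GO screens of large
gene lists reach 10⁻⁶¹ and below, and a plain summation underflows long
before the log does. Tails forced to 1 by pigeonhole
(k ≤ K + n − N) are returned exactly.

Multiple testing uses Benjamini–Hochberg step-up q-values
(qᵢ = min over j ≥ i of m·p₍ⱼ₎/j, capped at 1). The number of tests m is
a parameter and may exceed the number of rows at hand, because published
screens often retain only the smallest-p rows of a larger collection.
This is also why `bh_adjust` is written here rather than delegated to a
library routine (library implementations fix m to the row count); the
m = row-count case is cross-checked against `statsmodels.multipletests`
in the test suite. Selection keeps rows with q strictly below the FDR
threshold, truncated to the first `top_k` ranks (defaults 0.05 and 50).
Ties are broken everywhere by p ascending, then name ascending, so every
output is deterministic.

**Universe calibration.** The background size N is the most consequential
and least-reported ORA parameter. `calibrate_universe` back-solves an
integer N from printed (K, k, p) rows by minimizing the summed squared
log₁₀-p residual over a coarse (step 50) then fine (step 1) grid. On the
bundled GO BP reference rows (query n = 659) it recovers N = 45,956 —
the MSigDB v4.0 gene universe — and reproduces every reference p to
printed precision, including the held-out top row
(K = 385, k = 75 → 2.08 × 10⁻⁶¹). The result carries the interval of
equally good N (within two-significant-figure rounding) and is flagged
ambiguous when that interval has more than one element; a single row is
always ambiguous.

**Redundancy merging.** Curated databases name many near-duplicate
pathways. With overlap ratios r_A = |A∩B|/|A| and r_B = |A∩B|/|B|, a
pair is linked when max(r_A, r_B) ≥ Max and min(r_A, r_B) ≥ Min
(defaults 0.85 / 0.10). Linked groups merge transitively into
collections; the collection inherits the dominant (minimum) member
p-value and the union of member genes. The published description of the
Max/Min merge does not pin down which ratio each threshold binds or
whether merging iterates, so this package makes a concrete choice:
larger-ratio-vs-Max, smaller-ratio-vs-Min, with linking **iterated on
the merged unions to a fixpoint**. The iteration makes the operation
idempotent and order-independent by construction (a single pass is not:
a merged union can newly exceed the thresholds against a third set).
On the bundled 50 enriched KEGG sets this reproduces exactly the
published component structure — one 10-member cancer collection, one
2-member cardiac collection, 38 singletons.

**Crosstalk network.** KEGG draws the name of an interacting pathway
inside a pathway's map; each embedded cross-reference is evidence of
functional interaction. Edges are undirected (a reference in either
direction counts — the published interaction matrix is symmetric),
repeated references collapse to one edge, references among members of
one collection are internal, and a pathway referencing any member
interacts with the collection. References whose context is
`listed_only` (names merely listed in a map, e.g. cancer subtypes at the
foot of the pan-cancer map) and explicit (source, displayed) exclusion
pairs are ignored, generalizing the published cancer-listing rule to
data rather than hard-coded names. Degree is the interaction count;
hubs are ranked by degree descending, name ascending. Degrees are not
normalized against background interaction frequency, mirroring the
original analysis's explicit choice.

**Annotation.** Participation counts, pairwise overlap genes and
class/group summaries are straight tabulations of the membership matrix
(query genes × entries). Percentages are rounded half-up to one decimal
(9/40 prints as 22.5). The grouping scheme and the compound
(entity) annotation are data inputs, not code: the bundled assignments
ship as fixtures and users supply their own.

## Bundled reference scenario

`datasets.py` packages the SFARI autism study conditions: the 667-symbol
query (8 marked absent from the universe, leaving 659), the 40-entry
network with published per-entry ASD-gene counts, p-values, degrees and
groupings, GO BP/CC/MF reference screens, the 34 published per-gene
participation counts, the 41-gene neuroactive ligand-receptor list and
the 8-gene MAPK∩calcium overlap.

Gene-level and pair-level details beyond those summaries are not public,
so three objects are **synthetic reconstructions**, each deterministic
and labelled as such:

* the membership matrix is built by a constraint-satisfying placement
  that reproduces every published marginal exactly (column sums, the 34
  participation counts, the neuroactive column, the 8-gene overlap) and
  keeps all other genes at ≤ 3 entries;
* the 50 gene sets realize the published names and query contents with
  synthetic filler genes arranged so the Max/Min merge yields exactly
  the published collections (the non-dominant members' p-values, and the
  identification of "Pathways in cancer" / "Dilated cardiomyopathy" as
  dominant members, are synthetic choices);
* the interaction matrix is a canonical Havel–Hakimi realization of the
  published degree sequence; which eight of the 667 symbols the universe
  lacks, and which 23 entries the Ca²⁺ ion participates in, are likewise
  synthetic choices pinned to the published totals.

Consequently, tests against this scenario validate the pipeline's
bookkeeping and statistics under the published marginals — they do not
certify gene-level agreement with the original databases, which would
require the exact MSigDB v4.0/KEGG snapshots.

## Synthetic-data generator

Generators are pure functions of (config, seed); per-stage RNGs are
spawned from the scenario seed with fixed stage tags, so stages are
independently reproducible and identical seeds give identical bytes.

* **Pathway databases**: M sets with sizes uniform (or log-uniform) in a
  configured range (default 50–300) over an N-gene universe (default
  20,000, a human-genome-scale background). Planted redundancy clusters
  are star-shaped: satellites share round(r_major · size) genes with a
  hub sized to realize r_minor, so realized ratios sit within ±0.05 of
  target (integer rounding aside, they are exact).
* **Queries**: n genes (default 500, comparable to a large disease gene
  list). Genes of a set planted at fold ρ are included independently
  with probability min(1, ρ·n/N); the rest of the query is a uniform
  draw from the remaining universe. At ρ = 1 no tilt is applied, so the
  null is exactly uniform — the discreteness-randomized p-values of a
  fixed set pass a Kolmogorov–Smirnov uniformity test over 2,000
  replicates.
* **Cross-references**: ordered pairs at a configured density; a planted
  hub receives exactly its target degree and no other record touches it.

The generator emulates membership overlap structure only: symbols are
synthetic, set sizes are modest, and there is no annotation bias,
gene-length effect or correlated curation noise, so passing recovery
tests demonstrate statistical correctness of the machinery rather than
robustness to real-database artifacts.

## Numerical and design choices

* Symbols are normalized by trimming and uppercasing only; no
  alias/HGNC resolution (identifier mapping is out of scope).
* Enrichment uses the full query size n for every collection; whether
  published screens restrict n per collection is unknowable from the
  printed tables, and the calibration results are consistent with a
  single n.
* Degenerate inputs fail loudly: empty queries, empty collections,
  parameter-order violations, asymmetric adjacency matrices and
  uncovered grouping entries all raise typed errors naming the cause.
* GMT writing sorts member genes, network exports sort edges, and all
  report percentages round half-up, so repeated runs are byte-stable.

## Problem sizes used in tests

The statistical suite runs at deliberately compact sizes: uniformity
uses 2,000 simulated queries of 200 genes from a 5,000-gene universe;
single-set rank recovery uses 200 replicates at (N = 20,000, K = 100,
n = 500, ρ = 5); full-pipeline recovery (3 planted sets at ρ = 5, one
planted 3-set cluster, one planted hub) uses 100 replicates at
(N = 20,000, M = 16, n = 600), recovering all planted structure in
≥ 90 of 100 replicates (100 of 100 at these settings). The exhaustive
enumeration oracle covers every hypergeometric parameter combination
with N ≤ 12.

## Known limitations

* The merge rule is one concrete reading of the Max/Min thresholds; the
  original redundancy-control package may sequence merges differently.
  The choice here is validated against the published 50 → 40 component
  structure, not asserted as implementation-faithful.
* Cross-reference direction is collapsed to undirected edges; analyses
  that need the asymmetry of "A's map displays B" should consume the
  record table directly.
* Hub degree is raw, unnormalized interaction count; highly connected
  pathways in general (signaling hubs) will rank high in any network
  built this way.
* Entity participation depends entirely on the user-supplied compound
  annotation; the bundled Ca²⁺ map is a synthetic stand-in pinned to a
  published total.
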