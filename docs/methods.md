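# Methods

## Problem setting

Bacterial genome annotations plus TF binding motifs support a genome-scale
*affinity* transcriptional regulatory network: the set of all statistically
significant TF-family → operon binding-site predictions. Affinity
over-represents true regulation, both from scanner false positives and
because a bindable site need not be used under a given condition. This
package implements a parsimony-based selection on top of the affinity
network: an arc is kept only if it participates in a minimum-weight V-shape
connecting two metabolic operons of the same pathway category, i.e. only if
it helps explain the coordinated expression of a pathway. The surviving
sub-network (the co-regulatory network) is then analyzed topologically.

## Operons and promoters

Two consecutive genes join an operon iff they lie on the same contig and
strand and the count of bases strictly between them (`start(next) −
end(prev) − 1`) is below the threshold (default 50 bp). Overlapping
same-strand genes have a negative gap and merge trivially. Intergenic
regions strictly longer than the threshold are promoter regions for every
flanking operon whose 5′-most gene abuts them: tandem regions serve the
downstream operon only, divergent regions serve both, convergent regions
serve neither and are logged but not emitted. A gap of exactly the
threshold therefore splits the operon *and* is not a promoter: the two
rules ("< 50" to join, "> 50" to be a promoter) are both applied literally
and such regions are logged. Contig-end flanks longer than the threshold
count as promoters (draft-genome pragmatism; logged). Coordinates are
1-based inclusive everywhere (GFF3 convention), and promoters are never
truncated to a fixed window — the whole intergenic region is scanned.

## Exact match p-values

Each PSSM column is converted to integer log-odds scores
`round(s · log2((p + c·bg) / ((1+c)·bg)))` with scale `s = 1000`
(configurable; the integer granularity bounds rounding loss) and
pseudocount `c = 0.01`. The null distribution of the window score under the
0-order background is computed by exact convolution of the per-position
score distributions, giving a tail table P(S ≥ x) that is non-increasing,
equal to 1 at the minimum achievable score and 0 above the maximum. The
table is validated against full 4^w enumeration in the tests. Ambiguous
bases (N) contribute the background-expected score of their position, which
keeps the DP exact for ACGT sequences and degrades gracefully otherwise.
Both strands are scanned at every offset; a window matches iff its exact
p-value is ≤ the threshold (a p equal to the threshold matches). No
multiple-testing correction is applied across offsets: thresholds are
per-occurrence, as in standard motif scanner defaults.

Two thresholds coexist deliberately: the scan threshold (default 1e-4) and
a "confident" class at 1e-5. The downstream final filter removes selected
arcs with original p > 9e-5. Keeping both as distinct configuration fields
lets either convention be reproduced without re-scanning.

## Arc weights and V-shapes

Affinity arcs are sorted by (p-value, source, target) — the stable tie
break — and split into `k = 4` contiguous groups, remainder to the lowest-p
groups, weighted 1/2/4/8 ascending. Weights are computed over the whole
affinity network (computing them only over V-shape-reachable arcs is a
plausible alternative; the choice is exposed by simply passing a subgraph).

A V-shape for targets (A, B) is two directed paths from one apex C, ending
at A and B, sharing no node other than C; its weight is the sum of its arc
weights, combining "few arcs" and "low p-values" into one parsimony
criterion. Minimum-weight V-shapes are computed exactly per candidate apex
by 2-unit min-cost flow on the node-split transformation: every node other
than C, A, B becomes an in/out pair joined by a capacity-1, cost-0 edge;
original arcs get capacity 1 and cost = weight; arcs out of A or B and into
C are dropped (targets are endpoints only; the apex is a pure source).
Node capacities make the 2-unit flow decompose uniquely into two
node-disjoint simple paths. Only nodes with out-degree ≥ 2 can be apexes
(the two paths must leave C on distinct arcs). A shortest-path lower bound
(distance-to-A + distance-to-B, ignoring disjointness) prunes and orders
the apex loop.

"All minimum-weight V-shapes" is realized as arc membership in ≥ 1
optimum: for every apex achieving the global optimum W*, the flow is
re-solved with the candidate arc forced to carry one unit (standard
lower-bound transformation: remove the arc, shift one unit of demand across
it, add its cost); the arc is optimal iff the forced cost equals W*.
Explicit enumeration of V-shapes can be exponential and is provided only as
a test oracle for graphs of ≤ 12 nodes. Both routes agree on 100 random
digraphs in the tests.

Selection iterates over unordered same-category operon pairs (the V-shape
definition is symmetric in A and B); pairs with no connecting V-shape
contribute nothing and are logged. Every selected arc records its
provenance — the (category, pair) instances that selected it.

## Final assembly

Selected arcs with original p above the final threshold are removed (a p
exactly at the threshold is retained). Operons coding TFs are replaced by
their family node; parallel arcs created by the collapse merge keeping the
minimum p; isolated nodes are dropped. Counts are reported split by node
and arc kind, at both operon and family resolution, since the two
resolutions differ whenever a family is encoded by several operons.

## Topology suite

- **Cycles**: Johnson-style exact enumeration (networkx `simple_cycles`),
  capped (default 10,000) because the downstream exact feedback-arc-set
  machinery presumes a near-hierarchical network.
- **Minimum feedback arc sets**: exact minimum hitting set over the
  enumerated cycles by branch-and-bound (branch on the smallest uncovered
  cycle); *all* optima returned, truncated at 1,000. Each returned set is
  verified acyclic post hoc in tests.
- **Levels**: longest-path layering on the graph minus a chosen feedback
  arc set; level(v) = 1 + max level over non-feedback in-neighbors, sources
  at level 1, so every non-feedback arc strictly increases the level. The
  level count depends on which minimum feedback arc set is removed, so it
  is reported per choice rather than asserted unique.
- **Tree distance**: |arcs| − size of a maximum branching (Edmonds with
  unit weights) on the TF–TF subgraph — i.e. the minimum number of arc
  removals to reach an acyclic, in-degree ≤ 1 subgraph. "Tree" is read as
  branching/forest: an n-node graph keeps at most n − 1 arcs, the spanning
  branching case. The percentage is rounded to 1 decimal.
- **Primary regulators**: TF family nodes with in-degree 0.
- **Reachability table**: cell (category S, regulator R) counts category-S
  operons reachable from R by any directed path (direct binding or
  cascade); the TOTAL row holds per-category operon counts, with
  multi-category operons counted per category. Rows ascend by category
  size, columns descend by total reach.
- **Exclusivity table**: an operon counts under primary P iff P is the only
  primary that reaches it; per-category totals are formatted "n (p%)" with
  nearest-integer percentages.
- **Minimal controlling sets**: exhaustive search in increasing cardinality
  over candidate regulators (bounded at 20 candidates) for the smallest
  subsets whose joint reachability covers a category; uncoverable
  categories are reported infeasible, not fatal. Both candidate pools are
  computed — primaries only, and all TFs — since either reading of
  "minimum sets of transcription factors" is defensible. A greedy set-cover
  bound cross-checks the exhaustive optimum in tests.

## Synthetic data

The generator emulates the features the pipeline depends on, not real
genome composition. Defaults, fixed a priori:

- **Operon structure**: intra-operon gaps uniform on [1, 49] bp,
  inter-operon gaps uniform on [60, 500] bp, gene lengths uniform on
  [300, 900] bp, i.i.d. background sequence. True operon membership is
  emitted alongside.
- **Motifs**: one dominant base per column with probability 0.88
  (≈ 1.2 bits/column, so width-10 motifs carry > 10 bits). Planted sites
  are sampled from the emitting PSSM and resampled (≤ 100 times) until
  their exact p-value passes the scan threshold, then spliced into a
  promoter of the target operon at a recorded offset and strand.
- **Planted networks**: a TF DAG whose first k nodes are designated
  primaries (in-degree 0 preserved), exactly `n_cycles` back-arcs (each
  verified to raise the simple-cycle count by one), category-labelled
  operon leaves with one dedicated apex TF per category, signal arc
  p-values log-uniform on [1e-8, 1e-5] and decoys log-uniform on
  [1e-5, 1e-4]. Decoys are generated in equal number to all signal-range
  arcs so the p-value quartiles place signal in the weight-1/2 classes and
  decoys in 4/8; any V-shape through a decoy then costs ≥ 5 while planted
  V-shapes cost ≤ 4, making the planted arcs the unique optima by
  construction — the recovery experiments measure whether the
  implementation finds them, not whether the construction is ambiguous.

What passing these closed-loop tests does *not* show: performance on real
genomes with skewed base composition, overlapping regulons, weak or
variable-width motifs, or operon structure that violates the fixed distance
rule. The generator shares the scanner's background model, so recovery
rates here are upper bounds on field performance.

Analysis scripts use seed 11 and a genome of 8 TF families plus 12
metabolic operons across the six pathway categories (~30 genes); the
recovery experiments use 10–20 seeds with 12 TF families and 18 operons.
These sizes make every exact optimization run in seconds while still
exercising multi-level cascades, shared promoters on divergent operons,
family collapsing, and cycles.

## Degenerate inputs and tie-breaks

Empty motif files parse to an empty list with a warning; an empty
co-regulatory network renders a report stating no co-regulation was found.
Zero motif probabilities with zero pseudocount are fatal (infinite
log-odds). Equal p-values in weighting are broken by arc id for
determinism. `assign_weights` on fewer arcs than classes puts one arc per
lowest class. Histogram bins are right-closed, so a p-value exactly on a
bin edge falls in the lower bin.

## Known limitations

- The exact p-value DP is per-occurrence; no q-values across scans.
- Higher-order background models are not implemented (0-order only).
- The all-optima enumerations (feedback arc sets, controlling sets) are
  exact but exponential in the worst case; caps with explicit counts guard
  pathological inputs.
- GraphML output stringifies node kinds and keeps only numeric arc
  attributes; provenance survives only in the TSV dialect.
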