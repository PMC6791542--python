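# Methods

## Cavity representation

Every cavity — whether a surface cleft, a tunnel (one surface entry), a
pore (two entries) or a type-agnostic detection — is a cluster of
spheres ("pseudo-atoms"), each with a center and a positive radius in Å.
This is the least common denominator of cavity detection outputs:
Voronoi-ball methods emit variable-radius spheres, grid methods emit
grid points whose natural radius is half the grid spacing. A cavity set
holds all cavities of one protein from one source, in source order;
ground-truth cleft lists typically arrive sorted by decreasing volume
and are deliberately never re-sorted, so row/column indices in reports
match the source numbering. Protein identifiers are normalized to
lowercase on ingest because upstream files mix cases.

## Overlap measure

The similarity of a predicted cavity c and a ground-truth cavity C is a
center-counting Jaccard index: with A = #{centers of c inside the sphere
union of C} and B the converse,

    J(c, C) = (A + B) / (|c| + |C|).

Counting centers (rather than intersecting volumes) is cheap, robust to
radius conventions, and gives the two anchor identities one wants from
an intersection-over-union: J = 1 exactly when every center of each
cluster lies inside the other (congruence) and J = 0 exactly when no
center of either lies in the other (disjointness). The mutual
formulation is one symmetric convention among the possible center-count
definitions ("whose centers count" is underdetermined by the identities
alone); it is the package's normative choice and is documented rather
than claimed to coincide with any particular third-party implementation.
Duplicate centers count with multiplicity, since input formats carry one
record per pseudo-atom.

Sphere-inclusion is boundary-inclusive with a default tolerance of
1e−9 Å, which makes points at exactly one radius from a center
classify identically regardless of floating-point summation order. A
k-d tree over sphere centers prunes the inclusion test; candidates are
then checked against individual radii with the same comparison the
naive loop uses, so the accelerated path is decision-identical to brute
force (asserted by oracle tests, and measured as `jaccard_oracle_max_abs_diff`
in the acceptance run).

A directional variant, `coverage_of_ground_truth`, reports the fraction
of a ground-truth cavity's centers reached by a prediction; it feeds
textual coverage reports.

## Classification and repetition removal

The per-protein overlap matrix (rows = predicted, columns = ground
truth) classifies directly: TP = rows with a hit, FP = all-zero rows,
FN = all-zero columns. A hit is any overlap strictly greater than the
`min_overlap` threshold, default 0 — a nonempty center intersection
counts. The threshold is exposed because real pipelines may want
stricter hits; raising it only reclassifies weak hits, it does not alter
the matrix values.

Repetitions (one cavity overlapping several counterparts) are resolved
by global greedy matching: repeatedly keep the largest remaining nonzero
value and zero the rest of its row and column, ties broken by lower row
index then lower column index. Greedy-by-value reproduces the intuitive
"keep each cavity's best match" rule, is order-independent for distinct
values, idempotent, and yields at most one nonzero per row and column.
Whether a tie should instead break by cavity volume is unknowable from
the rule's usual informal statements; the index tie-break is pinned for
reproducibility. A Hungarian assignment maximizing total overlap is an
explicit non-goal: the benchmark semantics are best-match retention, not
global optimization.

Classification conserves totals (TP + FP = m; matched columns + FN = n)
and removal is monotone (TP can only fall, FP and FN only rise); both
are property-tested and re-measured by the acceptance script over 1000
random matrices.

## Metrics

Precision TP/(TP+FP), recall TP/(TP+FN), F-score 2·TP/(2·TP+FP+FN). F is
always computed from raw counts — never from rounded p and r — and
agrees with the harmonic mean of the unrounded p and r whenever both are
defined and nonzero. A zero denominator yields an explicit undefined
marker (`None`, rendered "NA"), not 0 and not an exception: a protein
with no predictions has undefined precision, and collapsing that to 0
would silently poison aggregates. Aggregation across proteins and
groups is micro-averaging (sum counts, then compute once); the bundled
published benchmark tables are consistent with summed counts and not
with averaged per-protein metrics, which is why micro was chosen.
Reports round half-away-from-zero to 2 decimals; CSV carries 4.

Of the 72 published metric cells bundled in `cavitybench.benchmarks`,
70 are reproduced exactly at 2-decimal rounding from their own printed
counts. Two are not, and are flagged in
`PRINTED_METRICS_KNOWN_DISCREPANT` rather than matched: the
with-repetitions Fpocket apo F (printed 0.86, counts give 0.8671 → 0.87)
and the without-repetitions Fpocket apo+holo precision (printed 0.45,
counts give 0.4553 → 0.46). The package reports computed values.

## True-negative estimate

True negatives — cavity-like regions absent from both ground truth and
prediction — are estimated geometrically: convex hull of the protein
atom centers (scipy ConvexHull/Delaunay; fewer than 4 non-coplanar
centers is an error), axis-aligned grid sampling of the hull's bounding
box at `grid_spacing` (default 1.0 Å), rejection of points outside the
hull or inside any sphere of the union (protein atoms + both cavity
sets), then DBSCAN on the survivors with eps = 2 × spacing and
min_pts = 4, noise discarded. Clusters come back as NOTYPE cavities of
grid-point spheres with radius spacing/2. The hull is taken over atom
centers, not sphere surfaces — the convex-hull difference is already a
coarse proxy for "inside the protein", and center-hulls keep the
procedure deterministic and parameter-free. The estimate is clearly an
estimate: its parameters are exposed, and it is excluded from p/r/F,
which do not depend on true negatives.

## Soup clustering

Methods that emit unlabeled pseudo-atoms are clustered by DBSCAN over
sphere centers (radii ignored; scikit-learn backend). Core points need
min_pts neighbours within eps, self included. Border points reachable
from several clusters go to the cluster discovered first in input-order
scanning — DBSCAN's classical ambiguity, pinned for reproducibility;
tests therefore compare core/noise labels and core-point partitions
against a naive density-reachability implementation, tolerating border
reassignment. Defaults when the grid spacing is known: eps = 2 × spacing
(so face- and diagonal-adjacent grid nodes connect), min_pts = 4. These
are documented defaults, tunable per run; no universal values exist
because each method's grid density differs.

## Synthetic fixture generator

The generator emulates the error modes a benchmark must detect — missed
cavities (drop), hallucinated ones (spurious), fragmented detections
(split) and positional noise (jitter) — while keeping the expected
TP/FP/FN exactly computable:

* Cavity sites sit on a cubic lattice with pitch `min_separation`
  (default 30 Å), assigned to truth/spurious roles by a seeded
  permutation; the spec validates that the pitch exceeds the maximal
  blob extent plus sphere reach plus jitter, so non-planted overlaps are
  geometrically impossible.
* Each cavity is a blob of 4–10 spheres (radii 1–2 Å) at Gaussian
  offsets truncated to a ball of twice the maximum radius — roughly the
  size and granularity of a small binding pocket represented by
  pseudo-atoms.
* Jitter displaces each surviving atom by a Gaussian (default sd
  0.25 Å) truncated at 0.9 × that atom's own radius, so a jittered
  center always stays inside its parent sphere and every planted overlap
  is strictly positive. This truncation is what turns "recovery with
  high probability" into "recovery exactly, for every seed": the planted
  counts are a theorem of the construction, not a statistical outcome.
* A split cavity contributes its two half-clusters; both overlap the
  parent, creating a genuine repetition whose with/without-repetitions
  counts differ in the planted way.

Deliberately not emulated: realistic protein geometry, cavity shape
anisotropy, density gradients, partial-overlap ambiguity between
adjacent cavities, and method-specific error correlations. Passing the
planted-recovery property therefore shows the pipeline's bookkeeping is
exact under unambiguous geometry; it does not certify ranking behavior
on real, crowded protein surfaces, where overlap values are continuous
and threshold choices matter.

## Problem sizes and determinism

Test and acceptance workloads are sized for interactive runs: 100
fixture seeds across the degradation grid, 1000 random matrices, 500
random cavity pairs, 25 DBSCAN instances up to 200 points, 50 XML
round-trips, and an 11³ grid for the hollow-cube check — large enough
to exercise every branch, small enough to finish in seconds. All
randomness flows from explicit seeds (numpy `default_rng`); file output
is byte-deterministic (fixed attribute order, 3-decimal coordinates,
4-decimal CSV cells), so identical inputs give identical artifacts.

## Known limitations

* The center-counting Jaccard ignores sphere volumes; two cavities with
  interpenetrating unions but mutually external centers score 0.
* The XML dialect is this package's own normative format, not a
  byte-compatible reimplementation of any upstream dataset's files.
* The PDB-like parser is tolerant by design (fixed columns, then
  whitespace fallback) and will accept files a strict PDB parser would
  reject; the `ParseReport` records what was skipped.
* The true-negative estimate depends on grid spacing and DBSCAN
  parameters and over-counts near the hull boundary, where convexity is
  a poor proxy for the molecular surface.
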