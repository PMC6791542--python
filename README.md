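# cavitybench

Benchmarking toolkit for **protein cavity detection methods**. Pocket,
tunnel and pore prediction programs (Fpocket, GHECOM, KVFinder,
GaussianFinder, …) each describe the cavities of a protein in their own
output format, which makes method-to-method comparison against a
ground-truth cavity set (e.g. cleft/tunnel/pore annotations derived from
structural databases) laborious. `cavitybench` standardizes every source
into one representation — a cavity as a **cluster of spheres**
(pseudo-atoms with center and radius, in Å) — and scores predictions
against ground truth with statistical classification metrics. It is a
library first, with a thin `cavitybench` command-line front end for
batch runs.

## The model

For one protein, let c₁…c_m be the method's cavities and C₁…C_n the
ground-truth cavities. Each pair is scored by a center-counting Jaccard
index

J(c, C) = (A + B) / (|c| + |C|),

where A is the number of pseudo-atom centers of c inside the sphere
union of C and B the converse; J = 1 for congruent clusters, 0 for
disjoint ones. The m×n **overlap matrix** of Jaccard values classifies
detections:

* **TP** — rows with at least one nonzero entry (the cavity hits some
  ground-truth cavity),
* **FP** — all-zero rows, **FN** — all-zero columns.

A cavity overlapping several counterparts is a *repetition*; optional
**repetition removal** greedily keeps each largest remaining overlap and
zeroes the rest of its row and column, producing a one-to-one matching
(TP can only drop, FP/FN only rise). Counts micro-aggregate across
proteins and groups (apo/holo), and performance is

p = TP/(TP+FP),  r = TP/(TP+FN),  F = 2·TP/(2·TP+FP+FN),

with `NA` when a denominator vanishes. True negatives — undetected,
unannotated cavity space — are optionally estimated by grid-sampling the
protein's convex hull, subtracting all atom and pseudo-atom spheres, and
clustering the remainder with DBSCAN; they never enter p, r or F.

Unlabeled pseudo-atom "soups" from grid-based methods are first
assembled into cavities by DBSCAN over sphere centers, and parsers are
provided for per-pocket PQR files, PDB-like pseudo-atom files (grouped
by residue number or not), tunnel/pore profile XML, and script files
with embedded dummy-atom clusters. Everything converges on a small
cavity-set XML dialect (documented in `src/cavitybench/io.py`).

## Worked example

```python
from cavitybench import FixtureSpec, evaluate_pair, generate_fixture

spec = FixtureSpec(seed=42, n_truth=5, drop_fraction=0.2,
                   spurious_count=2, split_fraction=0.25, jitter_sd=0.25)
truth, predicted, planted = generate_fixture(spec)
result = evaluate_pair(predicted, truth)
```

This plants one missed cavity, two spurious blobs and one cavity split
into two halves, then runs the full pipeline
(`python examples/05_synthetic_benchmark.py`):

```
protein synth0042: 5 true cavities, 7 predicted
    with repetitions: TP=5 FP=2 FN=1 (planted TP=5 FP=2 FN=1)
 without repetitions: TP=4 FP=3 FN=1 (planted TP=4 FP=3 FN=1)
```

With repetitions both halves of the split cavity count as hits (TP=5);
removal keeps only the better half, turning the other into a false
positive (TP=4, FP=3). The missed cavity is the FN, the two spurious
blobs the baseline FPs — exactly the planted outcome.

The other scripts in `examples/` each demonstrate one capability
(Jaccard overlap, repetition removal, metric tables from published
benchmark counts, soup clustering, true-negative estimation) and print a
line explaining their numbers.

## Command line

```sh
cavitybench convert  --format pqr --protein-id 1a4u --out 1a4u.xml pocket*.pqr
cavitybench cluster  --eps 1.2 --min-pts 4 --default-radius 0.3 \
                     --protein-id 1a4u --out 1a4u.xml soup.pdb
cavitybench fixtures --seed 7 --out fixtures/
cavitybench evaluate --truth-dir truth/ --pred-dir pred/ --out results/
cavitybench report   results/counts.csv --groups groups.csv
```

`evaluate` matches proteins across directories by lowercase filename
stem and writes per-protein overlap CSVs plus counts and aggregate
metrics, in both with- and without-repetitions variants.

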