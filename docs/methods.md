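# Methods

This note documents the models, conventions and numerical choices behind
`taxocut`, in the order the pipeline runs them.

## Similarity model

Two barcodes are compared by their best **local alignment** under
megablast-style scoring: match +2, mismatch −3, gap open 5, gap extend 2
(all configurable via `AlignmentParams`). Percent identity *s* is
identities divided by all alignment columns, gap columns included, which
matches the conventional tabular "pident" of heuristic search tools. The
alignment backend is Biopython's `PairwiseAligner`; its optimality is
cross-checked in the test suite against an independent quadratic Gotoh
dynamic program.

The **minimum-alignment-length adjustment** turns (s, l) into the score
`s` if `l >= m`, else `s * l / m`, clamped to [0, 1]. Defaults for *m* are
400 nt for full-length markers (ITS, LSU) and 50 nt for the short ITS1 and
ITS2 sub-regions. Conventions where the alignment literature is silent:

- *Ambiguity codes* (N, R, Y, …) score as mismatches, even against
  themselves; identity counts only exact A/C/G/T(/U) matches. This is
  conservative: an N-rich sequence can only lose similarity.
- *Symmetry* is guaranteed by canonically ordering the two sequences
  before aligning, so co-optimal alignments cannot make
  `pair_similarity(a, b)` differ from `pair_similarity(b, a)`.
- *Sparse storage*: pairs scoring below the `floor` (default 0.5) are
  dropped from similarity matrices. Every analysis sweeps thresholds well
  above 0.5, so this bounds memory without touching results; operations
  that need a value for a missing pair (variation statistics, realized
  bounds) use the floor itself and document the convention.
- *Imported searches* (12-column tabular format) keep the best-bit-score
  row per direction and symmetrise by taking the maximum of the two
  directions, the least destructive total rule.
- Self-similarity is defined as 1 and never stored.

## Clustering and the F-measure

Clustering at threshold *t* is **single linkage**: connected components of
the graph with an edge wherever the stored score is ≥ *t* (inclusive).
Cluster ids are the lexicographically smallest member, making results
independent of input order. The clustering F-measure weights each
ground-truth class by size and gives it the best harmonic mean of
precision and recall over all clusters; it is 1 exactly when clusters
coincide with classes. Evaluation is restricted to sequences annotated at
the evaluation rank — unannotated rows cannot contribute ground truth.

**Indistinguishable species complexes** are the species that co-cluster at
similarity 1.0 (exact, after adjustment). Clusters spanning ≥ 2 species
each yield a complex; complexes sharing a species (possible when a
species' sequences split over clusters) are unioned. Deduplication keeps
the alphabetically first species of each complex unless overridden —
determinism matters more than the particular choice.

## Cutoff prediction

The sweep evaluates the F-measure at every grid threshold (default
0.70–1.00 in steps of 0.001 at species rank; the start widens to 0.50 at
genus rank and above, where optimal cutoffs routinely fall below 0.7). The
predicted cutoff is the **smallest** grid threshold attaining the maximal
F — the inclusive choice is stable on plateaus, where any value in a range
separates the groups equally well. The sweep is implemented as one
descending pass with an incremental union-find (each edge merged exactly
once); a test asserts each curve point equals an independent
`cluster_at` + `clustering_fmeasure` evaluation.

**Local prediction** repeats the sweep inside every group at a scope rank
that passes the eligibility filter: more than `min_seq` sequences
(strictly; default 30), at least `min_groups` level-rank groups (default
5), and no level-rank group holding more than `max_dominance` of the
sequences (default 70%). Ineligible groups are skipped and logged with the
failed criterion. **Best-cutoff** lookup walks a taxon's own entry and its
ancestors' entries up to the global one and returns the highest-confidence
entry, ties going to the most specific; the chosen source is recorded in
`fallback_from`.

Degenerate inputs: an empty ground truth or one where all sequences share
a single group is an error (no threshold can be ranked); a truth of all
singletons yields the sweep start (every threshold is optimal, the
smallest is returned).

## Classification

A query's best hit (highest adjusted similarity; ties to the smallest
reference id) proposes a full lineage. The assignment walks species →
phylum; at each rank the applicable cutoff is the best-cutoff chain
started from the hit's taxon at the rank above (species cutoffs are looked
up under the hit's genus, then family, …, then the global entry). The
deepest rank whose cutoff the score reaches is accepted and all names
below it are blanked. Only the single best hit is consulted; top-k
consensus is out of scope. Merging classifications from several reference
sets keeps, per query, the deeper accepted rank, then the higher score,
then the source label sorting first — depth is preferred because a
taxon-focused reference with well-calibrated (often lower) cutoffs should
not be overruled by a stricter general reference.

## Synthetic data generator

The generator emulates the statistical structure of a curated barcode
collection, not its biology:

- a seven-rank hierarchy whose per-parent counts are fixed integers or
  (low, high) ranges sampled with a power-law skew, producing the strong
  imbalance (a few dominant genera) real collections show;
- one random ancestral sequence per phylum; each split introduces an
  expected substitution fraction from the **divergence ladder** (defaults:
  species 0.005, genus 0.05, family 0.12, order 0.18, class 0.25 —
  strictly increasing with rank height), with 10% of edits as single-base
  indels and substitutions drawn with a 2:1 transition:transversion bias;
- strains add binomial intra-strain noise (default 0.002/site);
- rank splits use a deterministic edit count `max(1, round(rate * L))` so
  every split realises divergence — otherwise a Poisson zero could make
  two sister species identical by accident and silently break planted-gap
  fixtures;
- planted complexes copy one species' sequences verbatim onto a sister
  species; a configurable fraction of rows gets the family blanked to
  model missing annotations;
- queries are contiguous fragments of a random strain of their species
  with substitutions at a per-base error rate; the origin map is the
  ground truth for recovery tests.

Marker regimes: "long" (450–800 nt, m = 400) and "short" (150–300 nt,
m = 50). All randomness derives from one master seed; identical seeds give
byte-identical output.

What the generator does **not** model: rRNA secondary structure,
intragenomic ITS copy heterogeneity, PCR chimeras, length-variable
indel-rich evolution. Passing tests therefore show that the *machinery*
(scoring, clustering, sweeping, gating) is correct under controlled
identity structure, not that any particular real marker resolves any
particular real group.

## Fixture calibration and problem sizes

Cutoff-recovery fixtures must realise an identity gap (max between-species
similarity < min within-species similarity). The gap is well posed only
when the species-level ladder spacing dominates the strain noise; with the
default ladder (0.005 spacing, 0.002 noise) a one-to-two-edit fluctuation
on a 150–220 nt sequence (~0.6–1.3% identity) crosses the spacing, so the
test and acceptance fixture family uses species divergence 0.03 with
strain noise 0.0005 (60× spacing). Realized bounds are always measured on
the actual matrix (`realized_bounds`) rather than assumed.

Desk-scale sizes were chosen to keep the full suite and the acceptance
script each under ~10 minutes on one CPU: recovery datasets of ~200–290
sequences at 150–185 nt (20 seeds in the tests, 10 in the acceptance
script), a ~230-sequence study dataset with two planted complexes, and a
~60-sequence long-marker (750–850 nt) reference for classification with
700 nt queries. The 2%-error classification check uses 700 nt queries
because the binomial spread of errors on much shorter fragments regularly
crosses a 0.97 cutoff even when the expected identity is 0.98: at 700 nt
the probability of a query exceeding 3% realised error is ~2%, at 150 nt
it is ~18%.

## Known limitations

- Single-linkage is the only clustering model; centroid/greedy variants
  would give different complexes at 100% similarity for length-variant
  duplicates.
- The sweep grid bounds cutoff precision at the step size (0.001); no
  confidence intervals are attached to cutoffs.
- `best_hit` is exhaustive (no heuristic search index); for large
  reference sets import a precomputed tabular search instead.
- Taxon names are matched as exact strings; synonym resolution and
  spelling normalisation are out of scope.
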