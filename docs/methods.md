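# Methods

## Function filters on the GO graph

Each GO namespace is modelled as a directed acyclic graph with edges
from child to parent terms (`is_a` by default; `part_of` admissible via
the `relations` argument of `parse_obo`). Distances are unweighted edge
counts; no information-content weighting is applied. The distance
between two terms is the minimum over common ancestors *c* of
`dist(a, c) + dist(b, c)`, with `pair_distance(x, x) = 0` and a
distinguished `None` sentinel when two terms share no ancestor (possible
after namespace restriction leaves multiple roots). The sentinel keeps
threshold comparisons total: a sentinel never satisfies any finite
threshold, so such pairs are rejected, not errors.

The function filter takes the minimum pair distance over the cross
product of the source's and target's term sets and retains the triple
iff that minimum is at or below the threshold *t* (default sweep range
0–5; beyond ~3 the filter degrades toward accepting everything). A pair
where either protein has no annotation in the namespace is
**not evaluable** and excluded from every denominator — retention
percentages are always over evaluable triples only.

Annotations are **not** propagated upward to ancestor terms before
filtering. Up-propagation would give every annotated protein the
namespace root, making the `t = 0` shared-term test pass universally;
the pair-distance computation supplies the generalisation instead, in a
controlled, threshold-bounded way.

Obsolete terms are dropped at parse time; annotations referencing them
(or any term outside the graph) are skipped with a logged count. GAF
evidence codes are not filtered — no defensible inclusion policy is
universal, and the behaviour is explicit in `parse_gaf`. `NOT`-qualified
GAF rows are negative statements and never contribute.

When several term pairs achieve the minimal distance, the reported
diagnostic pair is the lexicographically smallest (source term, target
term) — a tie-break chosen purely so output is deterministic and
golden-testable.

## Frequency score

The frequency-score filter ranks motifs by how often they would occur
by chance. We define the score of a pattern with residue classes
`class_1..class_k` in a protein of length L as the expected number of
chance matches under a background composition f:

    score(pattern, L) = max(L - k + 1, 0) * prod_i sum_{a in class_i} f(a)

The default background is uniform (1/20 per residue); a measured
proteome composition can be supplied through
`BackgroundFrequencies`. The functional form is deliberately isolated
behind `frequency_score` so an alternative normalisation (per-residue
probability, database occurrence counts) can be swapped in without
touching the filters. Retention keeps *low* scores: `score <=
threshold`, thresholds of practical interest being 0.02–0.04 for short
patterns in average-length proteins. Match coordinates are 1-based
inclusive; non-canonical residues (B, J, O, U, X, Z) in sequences match
no class, wildcards included.

## Either-or combination

The combined filter retains a triple when either the function filter or
the frequency filter retains it. Its evaluation universe is restricted
to triples evaluable by the **function** component: a triple whose
source or target lacks annotations stays out of the denominators even
if its sequence is available, keeping combined and function-only
percentages comparable. Within that universe a not-evaluable frequency
side (missing sequence) neither rescues nor vetoes: the function
verdict stands. Both sides not evaluable ⇒ not evaluable.

Invert ("exclude") mode swaps retained and rejected among evaluable
triples only — not-evaluable stays not-evaluable — and is an
involution.

## Evaluation

Sensitivity is the percent of evaluable positives retained; selectivity
the percent of evaluable negatives retained (lower is better); the
Discrimination Ratio is their quotient, with a `None` sentinel when
selectivity is zero. Display rounding (whole percents, one-decimal DR
and AUC) happens only in `EvaluationSummary.rounded()`; raw values are
kept everywhere else.

A threshold sweep produces one summary per threshold and *asserts*
non-decreasing sensitivity/selectivity columns — retention sets are
provably nested in either threshold, so a violation indicates a filter
bug, not a data property. ROC curves take each summary's
(selectivity/100, sensitivity/100) as an (FPR, TPR) point, add the
(0,0) and (1,1) anchors, deduplicate, sort by FPR (ties by TPR), and
integrate by the trapezoidal rule. Tie handling is deterministic; no
random jitter is added to smooth curves.

Significance defaults to a one-sided Mann–Whitney rank-sum test
(tie-corrected, via scipy) on per-triple scores — for function filters
the negated minimal pair distance, with the no-common-ancestor sentinel
ranked one unit worse than the largest observed distance; for frequency
filters the negated score. On tie-free scores the rank statistic
satisfies `U / (n1 * n2) = AUC`, which the tests exploit as a
cross-check. A label-permutation test on the AUC is also provided; it
requires an explicit seed and reports the smoothed p-value
`(c + 1) / (n + 1)` where `c` counts permutations whose AUC reaches the
observed one.

## Synthetic benchmark generator

The generator fabricates every input the real pipeline would read and
is a pure function of `SyntheticConfig` (all randomness flows through
one `numpy` generator seeded from `config.seed`; identical configs give
byte-identical fixture files).

* **DAG** — term *i* draws 1..`max_parents` parents uniformly among
  terms 0..*i*−1; term 0 is the single root; acyclic by construction.
  Defaults: 250 terms, ≤2 parents.
* **Annotations** — each of 2,500 proteins receives 3 distinct uniform
  terms; a configurable fraction can be left unannotated to exercise
  the not-evaluable path.
* **Positives** (default 1,000) — distinct target proteins; with
  probability *q* (default 0.6) a positive is *planted*: one target
  term is replaced by a term within pair distance `plant_distance`
  (default 1) of a source term. Sources are drawn from the non-target
  pool so no later planting can disturb an earlier pair's shared term.
  Plantings act on annotations, not graph topology, mirroring how
  functionally related proteins actually share GO terms.
* **Negatives** (default 1,000) — uniform random ordered pairs,
  resampled until disjoint from the positive (source, target) set, with
  a resampling cap of 100× the requested count before erroring.
* **Sequences** — uniform random residues, default length 400
  (a typical protein); each positive's consensus (default length 4,
  with a 20% chance per position of a two-letter class) is implanted at
  a recorded 1-based site, implant windows chosen non-overlapping per
  source.
* **Aliases** — 10% of proteins are referenced in the motif tables only
  through an alias accession while the GAF keeps the canonical form,
  so end-to-end runs exercise alias resolution.

What the generator does *not* emulate: real GO topology statistics
(term counts, fan-out and depth distributions), correlated annotation
patterns between interacting protein families, non-uniform residue
composition, and curation biases in verified minimotif sets. Passing
tests therefore demonstrate algorithmic correctness and calibrated
recovery of a planted signal under idealised conditions — not
performance figures transferable to real databases.

With the default conditions the sweep reproduces the qualitative shape
of real filter evaluations: sensitivity and selectivity both rise with
*t*, the discrimination ratio peaks at small *t* (~4–5 at `t = 1`) and
decays toward 1 by `t = 5`, and the sweep AUC lands around 0.75.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at
1,000 + 1,000 pairs over a 250-term DAG (seconds per run), brute-force
oracle checks on 200 random DAGs of ≤50 terms, and Monte-Carlo
agreement of scan counts with the analytic frequency score over 1,500
random sequences; statistical recovery checks use 3-standard-error
bands. Ancestor-distance maps are cached per term (the graph is
immutable after construction), making the cross-product distance
minimisation over thousands of pairs cheap. Floating-point tolerances:
background compositions must sum to 1 within 1e-9; monotonicity
assertions allow 1e-9 slack; permutation AUC comparisons use a 1e-12
guard against representation noise.

## Known limitations

* The frequency score is one defensible formalisation of
  "expected chance occurrences"; scores tied to database-wide motif
  occurrence counts would need a different backend behind the same
  operation.
* Cross-namespace similarity, information-content measures
  (Resnik/Lin) and annotation enrichment are out of scope.
* The OBO reader (backed by obonet) accepts the common tag subset
  (`id`, `name`, `namespace`, `is_a`, `relationship`, `is_obsolete`);
  exotic header clauses are ignored rather than validated.
* `p`-values from the rank test assume independent triples; shared
  proteins across triples mildly violate this in real data.
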