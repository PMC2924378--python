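# minimotif-filters

Function-based filtering of short linear motif (minimotif) predictions,
with the evaluation machinery to measure how well a filter separates
verified minimotifs from random background.

## The problem

Minimotifs (short linear motifs, SLiMs) are short contiguous peptides —
`YYTM` in Jak2, for instance — that carry a function (binding, a
post-translational modification, trafficking) recognised by a *target*
protein. Scanning a query protein against a library of consensus
patterns predicts candidate minimotifs, but consensus matching is so
permissive that most predictions are false positives.

This package implements a data-driven filter for such predictions: a
predicted triple (source protein, motif, target protein) is retained
only when the source and target share a sufficiently similar function
in the Gene Ontology (GO). Proteins in the same pathway tend to share
biological-process ("cellular function") and molecular-function
annotations, so a prediction whose two proteins have no functional
relationship at all is more likely to be noise.

## The method

GO structures each namespace as a directed acyclic graph with edges
from child terms to parent terms. For a source with term set *S* and a
target with term set *T*, the filter computes

    d(S, T) = min over (a, b) in S x T of
              min over common ancestors c of  [dist(a, c) + dist(b, c)]

where distances are unweighted edge counts, and retains the prediction
iff `d(S, T) <= t` for a distance threshold *t*. At `t = 0` this is
exactly the shared-term test (non-empty `S ∩ T`). A pair where either
protein has no GO annotation in the namespace is *not evaluable* and is
excluded from all totals.

A second, independent filter scores motif complexity: the *frequency
score* of a pattern of length *k* in a source protein of length *L* is
the expected number of chance occurrences

    score = (L - k + 1) * prod_i  sum_{a in class_i} f(a)

under a background residue composition *f* (uniform 1/20 by default);
low-scoring (complex, rare) motifs are retained (typical thresholds
0.02–0.04). The two filters combine on an **either-or** basis: the
combination retains a triple when either component retains it.

Filter quality is reported as

* **sensitivity** — % of verified minimotifs retained,
* **selectivity** — % of random (negative) pairs retained (lower is better),
* **Discrimination Ratio** DR = sensitivity / selectivity,

plus ROC curves ((selectivity, sensitivity) across a threshold sweep,
anchored at (0,0)/(1,1), trapezoidal AUC) and significance tests
(one-sided rank-sum, or a seeded label-permutation test on the AUC).

A fully seeded synthetic generator fabricates ontologies, GAF
annotations, alias tables, sequences and positive/negative minimotif
sets with a *planted* functional signal, so the whole pipeline is
testable without any external database.

## Worked example

Generate a benchmark with 300 verified and 300 random pairs where 60%
of positives are planted to share a function within distance 1, then
sweep the cellular-function filter:

```sh
minimotif simulate --out-dir fx --seed 11 \
    --n-terms 150 --n-proteins 600 --n-pos 300 --n-neg 300
minimotif evaluate \
    --ontology fx/ontology.obo --gaf fx/annotations.gaf \
    --aliases fx/aliases.tsv \
    --positives fx/positives.tsv --negatives fx/negatives.tsv \
    --distances 0,1,2,3,4,5 --seed 7
```

prints (abridged):

```json
{
  "sweep": [
    {"threshold": 0, "sensitivity": 23, "selectivity": 8,  "dr": 3.0},
    {"threshold": 1, "sensitivity": 68, "selectivity": 20, "dr": 3.5},
    {"threshold": 2, "sensitivity": 80, "selectivity": 44, "dr": 1.8},
    {"threshold": 3, "sensitivity": 91, "selectivity": 77, "dr": 1.2},
    {"threshold": 4, "sensitivity": 99, "selectivity": 96, "dr": 1.0},
    {"threshold": 5, "sensitivity": 100, "selectivity": 100, "dr": 1.0}
  ],
  "roc_auc": 0.747,
  "significance": {"method": "rank_test", "p_value": 5.2e-27}
}
```

Read: at `t = 1` the filter keeps 68% of verified minimotifs (the 60%
planted signal plus chance coincidences) but only 20% of random pairs —
a 3.5-fold preference. Loosening the threshold raises sensitivity but
the discrimination decays toward 1 as almost every term pair becomes
"similar". The rank-sum p-value says this separation is nowhere near
chance.

The same machinery is available as a library (`minimotif.filters`,
`minimotif.evaluation`, `minimotif.synthetic`), and `minimotif filter
--invert` implements the "exclude" mode that shows only predictions
*removed* by the filter, for users hunting new functions of a query.

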