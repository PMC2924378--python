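"""Function filters, frequency-score filter, and their combination.

The function filter retains a minimotif when its source and target
proteins share at least one sufficiently similar GO term: the minimum,
over all (source term, target term) pairs, of the common-ancestor pair
distance must be <= the distance threshold t.  At t = 0 this reduces to
a non-empty term-set intersection.  A pair where either protein has no
annotation in the namespace is *not evaluable* and is excluded from all
totals.

The frequency-score filter retains a minimotif when the expected chance
occurrence count of its consensus in the source protein is at or below
a score threshold.  The either-or combination retains a triple when
either component retains it; its evaluation universe is restricted to
triples evaluable by the function component, and inside that universe a
not-evaluable frequency side cannot veto a retention.

Invert ("exclude") mode swaps retained and rejected verdicts among
evaluable minimotifs only, serving users who want predictions with
functions *unrelated* to the query.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .annotations import AliasTable, AnnotationSet, terms_for
from .motifs import BackgroundFrequencies, Minimotif, frequency_score
from .ontology import NO_COMMON_ANCESTOR, OntologyGraph

__all__ = [
    "Verdict",
    "FilterDecision",
    "FilterConfig",
    "FilterResources",
    "FilterSummary",
    "function_filter",
    "frequency_filter",
    "combine_either_or",
    "apply_filter",
]


class Verdict(str, enum.Enum):
    RETAINED = "retained"
    REJECTED = "rejected"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class FilterDecision:
    """Verdict plus the diagnostic quantity that decided it.

    ``min_distance`` is present iff a function filter ran on two
    non-empty term sets (``None`` sentinel = no common ancestor);
    ``score`` iff a frequency filter had a source sequence.
    ``closest_pair`` is the lexicographically smallest (source term,
    target term) pair achieving the minimum distance, for determinism.
    """

    verdict: Verdict
    component: str
    min_distance: int | None = None
    has_distance: bool = False
    score: float | None = None
    closest_pair: tuple[str, str] | None = None

    @property
    def retained(self) -> bool:
        return self.verdict is Verdict.RETAINED

    @property
    def evaluable(self) -> bool:
        return self.verdict is not Verdict.NOT_EVALUABLE


@dataclass(frozen=True)
class FilterConfig:
    """Which filter(s) to run and at what stringency.

    namespace: ``biological_process`` (the "cellular function" filter)
    or ``molecular_function``.  ``distance_threshold`` is the maximum
    allowed common-ancestor total distance t (published sweep 0..5).
    ``mode`` selects function-only, frequency-only, or the either-or
    combination; ``invert`` swaps verdicts among evaluable motifs.
    """

    namespace: str = "biological_process"
    distance_threshold: int = 0
    frequency_threshold: float = 0.02
    mode: str = "function_only"  # function_only | frequency_only | either_or
    invert: bool = False
    max_distance_threshold: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("function_only", "frequency_only", "either_or"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if not 0 <= self.distance_threshold <= self.max_distance_threshold:
            raise ValueError(
                f"distance threshold {self.distance_threshold} outside "
                f"0..{self.max_distance_threshold}"
            )


@dataclass
class FilterResources:
    """Everything a filter run needs besides the minimotifs themselves."""

    graph: OntologyGraph
    annotations: AnnotationSet
    aliases: AliasTable = field(default_factory=AliasTable)
    sequences: Mapping[str, str] = field(default_factory=dict)
    background: BackgroundFrequencies = field(default_factory=BackgroundFrequencies.uniform)


@dataclass(frozen=True)
class FilterSummary:
    """Counts over one run; totals exclude not-evaluable minimotifs."""

    total_evaluable: int
    retained: int
    not_evaluable: int

    @property
    def rejected(self) -> int:
        return self.total_evaluable - self.retained


def function_filter(
    source_terms: Iterable[str],
    target_terms: Iterable[str],
    graph: OntologyGraph,
    t: int,
    component: str = "function",
) -> FilterDecision:
    """Retain iff some source/target term pair lies within distance *t*.

    Either side empty -> not evaluable.  Pairs with no common ancestor
    count as failures (they can never satisfy a finite threshold).
    """
    src = sorted(set(source_terms))
    tgt = sorted(set(target_terms))
    if not src or not tgt:
        return FilterDecision(Verdict.NOT_EVALUABLE, component=component)
    best: int | None = None
    best_pair: tuple[str, str] | None = None
    for a in src:
        for b in tgt:
            d = graph.pair_distance(a, b)
            if d is NO_COMMON_ANCESTOR:
                continue
            # lexicographic tie-break: src/tgt already sorted ascending
            if best is None or d < best:
                best, best_pair = d, (a, b)
    retained = best is not None and best <= t
    return FilterDecision(
        Verdict.RETAINED if retained else Verdict.REJECTED,
        component=component,
        min_distance=best,
        has_distance=True,
        closest_pair=best_pair,
    )


def frequency_filter(
    motif: Minimotif,
    sequences: Mapping[str, str],
    bg: BackgroundFrequencies,
    threshold: float,
    aliases: AliasTable | None = None,
    component: str = "frequency",
) -> FilterDecision:
    """Retain iff the motif's expected chance occurrence count <= threshold."""
    accession = aliases.resolve(motif.source) if aliases else motif.source
    sequence = sequences.get(accession)
    if sequence is None and accession != motif.source:
        sequence = sequences.get(motif.source)
    if sequence is None:
        return FilterDecision(Verdict.NOT_EVALUABLE, component=component)
    score = frequency_score(motif.pattern, len(sequence), bg)
    verdict = Verdict.RETAINED if score <= threshold else Verdict.REJECTED
    return FilterDecision(verdict, component=component, score=score)


def combine_either_or(a: FilterDecision, b: FilterDecision) -> FilterDecision:
    """Retain when either component retains; diagnostics merged.

    Both sides not evaluable -> not evaluable.  One evaluable side is
    decisive on its own: a not-evaluable partner neither rescues nor
    vetoes.  The component label records which side(s) retained.
    """
    if not a.evaluable and not b.evaluable:
        return FilterDecision(Verdict.NOT_EVALUABLE, component="either_or")
    winners = [d.component for d in (a, b) if d.retained]
    verdict = Verdict.RETAINED if winners else Verdict.REJECTED
    component = "either_or:" + "+".join(winners) if winners else "either_or"
    dist_side = a if a.has_distance else (b if b.has_distance else None)
    score_side = a if a.score is not None else (b if b.score is not None else None)
    return FilterDecision(
        verdict,
        component=component,
        min_distance=dist_side.min_distance if dist_side else None,
        has_distance=dist_side is not None,
        score=score_side.score if score_side else None,
        closest_pair=dist_side.closest_pair if dist_side else None,
    )


def _decide_one(motif: Minimotif, config: FilterConfig, res: FilterResources) -> FilterDecision:
    if config.mode in ("function_only", "either_or"):
        fn = function_filter(
            terms_for(res.annotations, res.aliases, motif.source, config.namespace),
            terms_for(res.annotations, res.aliases, motif.target, config.namespace),
            res.graph,
            config.distance_threshold,
        )
        if config.mode == "function_only":
            return fn
        # Combined universe is restricted to function-evaluable triples:
        # an unannotated side leaves the triple out of every total.
        if not fn.evaluable:
            return replace(fn, component="either_or")
        fq = frequency_filter(
            motif, res.sequences, res.background, config.frequency_threshold,
            aliases=res.aliases,
        )
        return combine_either_or(fn, fq)
    return frequency_filter(
        motif, res.sequences, res.background, config.frequency_threshold,
        aliases=res.aliases,
    )


def _invert(decision: FilterDecision) -> FilterDecision:
    if not decision.evaluable:
        return decision
    flipped = Verdict.REJECTED if decision.retained else Verdict.RETAINED
    return replace(decision, verdict=flipped)


def apply_filter(
    motifs: Sequence[Minimotif],
    config: FilterConfig,
    resources: FilterResources,
) -> tuple[list[FilterDecision], FilterSummary]:
    """Run the configured filter over *motifs*.

    Returns one decision per motif (input order) and a summary whose
    totals exclude not-evaluable motifs — matching the reporting
    convention that proteins without GO terms do not enter the
    denominators.  With ``invert`` set, retained and rejected verdicts
    are swapped among evaluable motifs only.
    """
    decisions = [_decide_one(m, config, resources) for m in motifs]
    if config.invert:
        decisions = [_invert(d) for d in decisions]
    evaluable = sum(1 for d in decisions if d.evaluable)
    retained = sum(1 for d in decisions if d.retained)
    summary = FilterSummary(
        total_evaluable=evaluable,
        retained=retained,
        not_evaluable=len(decisions) - evaluable,
    )
    return decisions, summary
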