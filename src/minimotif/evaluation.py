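"""Sensitivity / selectivity / Discrimination Ratio, ROC curves, p-values.

Terminology follows the minimotif-filter literature rather than the
usual classification one:

* **sensitivity** — percentage of verified (positive) minimotifs the
  filter retains;
* **selectivity** — percentage of negative (random-pair) minimotifs the
  filter retains (lower is better);
* **Discrimination Ratio (DR)** — sensitivity / selectivity; above 1
  means the filter prefers verified minimotifs.

A threshold sweep traces (selectivity, sensitivity) points which,
re-read as (FPR, TPR) fractions and anchored at (0,0) and (1,1), form a
ROC curve integrated by the trapezoidal rule.  Significance is assessed
either by a one-sided rank-sum test on per-pair scores (tie-corrected)
or by a seeded label-permutation test on the AUC with +1/(n+1)
smoothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .filters import FilterConfig, FilterDecision, FilterResources, apply_filter
from .motifs import Minimotif

__all__ = [
    "DR_UNDEFINED",
    "EvaluationError",
    "EvaluationSummary",
    "RocCurve",
    "SignificanceResult",
    "evaluate",
    "threshold_sweep",
    "roc_from_sweep",
    "roc_auc_from_points",
    "scores_from_decisions",
    "significance",
    "disjointness_check",
]

#: Sentinel DR when selectivity is zero (nothing negative retained).
DR_UNDEFINED = None


class EvaluationError(Exception):
    """Evaluation cannot proceed (e.g. an empty evaluable side)."""


@dataclass(frozen=True)
class EvaluationSummary:
    """One filter setting's performance on a positive/negative benchmark."""

    n_pos_evaluable: int
    n_neg_evaluable: int
    sensitivity: float  # percent of evaluable positives retained
    selectivity: float  # percent of evaluable negatives retained
    dr: float | None  # sensitivity / selectivity, None when selectivity == 0
    threshold: object = None  # the swept parameter value, if any

    def rounded(self) -> dict:
        """Display form matching the published tables: whole percents,
        one-decimal DR."""
        return {
            "threshold": self.threshold,
            "n_pos": self.n_pos_evaluable,
            "n_neg": self.n_neg_evaluable,
            "sensitivity": round(self.sensitivity),
            "selectivity": round(self.selectivity),
            "dr": None if self.dr is None else round(self.dr, 1),
        }


@dataclass(frozen=True)
class RocCurve:
    """Sorted (FPR, TPR) points with anchors, plus trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float
    parameter: str = ""


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    method: str
    statistic: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def evaluate(
    decisions_pos: Sequence[FilterDecision],
    decisions_neg: Sequence[FilterDecision],
    threshold: object = None,
) -> EvaluationSummary:
    """Sensitivity/selectivity/DR from per-motif decisions.

    Not-evaluable decisions are excluded from both denominators.
    """
    pos = [d for d in decisions_pos if d.evaluable]
    neg = [d for d in decisions_neg if d.evaluable]
    if not pos:
        raise EvaluationError("no evaluable positive minimotifs")
    if not neg:
        raise EvaluationError("no evaluable negative minimotifs")
    sensitivity = 100.0 * sum(d.retained for d in pos) / len(pos)
    selectivity = 100.0 * sum(d.retained for d in neg) / len(neg)
    dr = DR_UNDEFINED if selectivity == 0 else sensitivity / selectivity
    return EvaluationSummary(
        n_pos_evaluable=len(pos),
        n_neg_evaluable=len(neg),
        sensitivity=sensitivity,
        selectivity=selectivity,
        dr=dr,
        threshold=threshold,
    )


def dr_from_percentages(sensitivity: float, selectivity: float) -> float | None:
    """DR from already-computed (possibly table-printed) percentages."""
    return DR_UNDEFINED if selectivity == 0 else sensitivity / selectivity


def threshold_sweep(
    config_template: FilterConfig,
    thresholds: Sequence,
    positives: Sequence[Minimotif],
    negatives: Sequence[Minimotif],
    resources: FilterResources,
    parameter: str = "distance_threshold",
) -> list[EvaluationSummary]:
    """Evaluate the filter at each threshold of one swept parameter.

    *parameter* is the :class:`FilterConfig` field to sweep
    (``distance_threshold`` or ``frequency_threshold``); thresholds must
    be strictly increasing.  Retention is monotone in either threshold,
    so non-decreasing sensitivity/selectivity columns are asserted — a
    violation indicates a filter bug, not a data property.
    """
    if list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be strictly increasing")
    summaries: list[EvaluationSummary] = []
    for value in thresholds:
        config = replace(config_template, **{parameter: value})
        dec_pos, _ = apply_filter(positives, config, resources)
        dec_neg, _ = apply_filter(negatives, config, resources)
        summaries.append(evaluate(dec_pos, dec_neg, threshold=value))
    for prev, cur in itertools.pairwise(summaries):
        if cur.sensitivity < prev.sensitivity - 1e-9 or cur.selectivity < prev.selectivity - 1e-9:
            raise EvaluationError(
                "internal consistency error: retention decreased between "
                f"thresholds {prev.threshold!r} and {cur.threshold!r}"
            )
    return summaries


def roc_auc_from_points(points: Iterable[tuple[float, float]]) -> RocCurve:
    """Build a ROC curve from raw (FPR, TPR) fractions.

    Anchors (0,0) and (1,1) are added, duplicates removed, points sorted
    by FPR (ties by TPR), and the AUC computed by the trapezoidal rule.
    """
    unique = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    fpr = np.array([p[0] for p in unique])
    tpr = np.array([p[1] for p in unique])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=tuple(unique), auc=auc)


def roc_from_sweep(
    summaries: Sequence[EvaluationSummary], parameter: str = "distance"
) -> RocCurve:
    """ROC over a sweep: each summary contributes (selectivity, sensitivity)
    as a (FPR, TPR) fraction."""
    if not summaries:
        raise EvaluationError("need at least one summary for a ROC curve")
    points = [(s.selectivity / 100.0, s.sensitivity / 100.0) for s in summaries]
    curve = roc_auc_from_points(points)
    return RocCurve(points=curve.points, auc=curve.auc, parameter=parameter)


def scores_from_decisions(
    decisions: Sequence[FilterDecision], worst: float | None = None
) -> list[float]:
    """Per-pair scores for significance testing of a function filter.

    Higher = more filter-favoured: the negated minimal pair distance.
    Pairs with no common ancestor get the worst rank (one unit below the
    largest observed distance, or *worst* when given).  Not-evaluable
    decisions are excluded, matching the evaluation denominators.
    """
    dists = [
        d.min_distance
        for d in decisions
        if d.evaluable and d.has_distance and d.min_distance is not None
    ]
    if worst is None:
        worst = -(max(dists, default=0) + 1.0)
    scores = []
    for d in decisions:
        if not d.evaluable:
            continue
        if d.min_distance is None:
            scores.append(worst)
        else:
            scores.append(-float(d.min_distance))
    return scores


def _auc_statistic(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    u = stats.mannwhitneyu(pos, neg, alternative="greater").statistic
    return float(u) / (len(pos) * len(neg))


def significance(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    method: str = "rank_test",
    n_permutations: int = 999,
    seed: int | None = None,
) -> SignificanceResult:
    """P-value that positives score no higher than negatives.

    ``rank_test``: one-sided Mann-Whitney/Wilcoxon rank-sum with tie
    correction.  ``permutation``: the group labels are permuted
    *n_permutations* times (seed mandatory for reproducibility); p is
    the smoothed fraction (c + 1)/(n + 1) of permutations whose AUC is
    at least the observed one.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both score lists must be non-empty")
    if method == "rank_test":
        res = stats.mannwhitneyu(pos, neg, alternative="greater")
        return SignificanceResult(
            p_value=float(res.pvalue), method=method, statistic=float(res.statistic)
        )
    if method == "permutation":
        if seed is None:
            raise ValueError("permutation method requires a seed")
        rng = np.random.default_rng(seed)
        observed = _auc_statistic(pos, neg)
        pooled = np.concatenate([pos, neg])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _auc_statistic(perm[: pos.size], perm[pos.size :]) >= observed - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        return SignificanceResult(
            p_value=p,
            method=method,
            statistic=observed,
            n_permutations=n_permutations,
            seed=seed,
        )
    raise ValueError(f"unknown significance method {method!r}")


def disjointness_check(
    positives: Iterable[tuple[str, str]], negatives: Iterable[tuple[str, str]]
) -> int:
    """Number of negative ordered (source, target) pairs present among
    the positives — must be 0 for a sound negative benchmark."""
    pos = set(positives)
    return sum(1 for pair in negatives if pair in pos)
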