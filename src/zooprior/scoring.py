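"""Weighted decision-tree scoring and ranking of diseases.

Each disease traverses a decision tree whose nodes are the criteria in
descending weight order (highest-ranked criterion first).  At each node
the disease's categorical answer is scored:

* binomial question: the designated full-score answer scores 1, the other
  scores 0 — the full criterion weight or nothing;
* multinomial question with ``m`` ordered categories: the answer at
  1-based ordinal position ``k`` scores ``k / m``.

The weighted question score is ``q = w * s`` for criterion weight ``w``;
disease totals are ``T = sum(q)`` and are normalized against the maximum
observed total (``N = T / T_max``), so the top disease scores 1.  Because
every disease visits every node, the tree evaluates to exactly this
weighted sum — the node order shapes only the trace presentation, never
the score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .ahp import CriterionWeights
from .config_io import AnswerTable, PrioritizationConfig, Question
from .errors import ValidationError

__all__ = [
    "AnswerScore",
    "TraceEntry",
    "ScoreTrace",
    "RankedDisease",
    "RankedDiseaseList",
    "answer_score",
    "weighted_question_score",
    "score_disease",
    "score_all",
    "rank_diseases",
    "sensitivity_scan",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class AnswerScore:
    """The raw score of one categorical answer.

    ``ordinal_position`` is the 1-based position ``k`` of the answer among
    the ``n_categories = m`` ordered categories; ``raw_score`` is 0/1 for
    binomial questions and ``k / m`` for multinomial ones.
    """

    question_id: str
    category_label: str
    ordinal_position: int
    n_categories: int
    raw_score: float


@dataclass(frozen=True)
class TraceEntry:
    """One decision-tree node visit: criterion, answer, weight, q = w*s."""

    criterion_id: str
    category_label: str
    weight: float
    raw_score: float
    weighted_score: float


@dataclass(frozen=True)
class ScoreTrace:
    """Per-question weighted scores for one disease, in tree-node order."""

    disease: str
    entries: tuple[TraceEntry, ...]
    total: float

    @property
    def max_possible(self) -> float:
        return sum(e.weight for e in self.entries)


@dataclass(frozen=True)
class RankedDisease:
    rank: int
    disease: str
    total: float
    normalized: float


@dataclass(frozen=True)
class RankedDiseaseList:
    """Final prioritized list, sorted by descending total score.

    Competition ranking: diseases with equal totals share a rank and the
    next rank is skipped; tied diseases keep the configured disease order.
    """

    entries: tuple[RankedDisease, ...]
    t_max: float
    normalization: str = "max_observed"


def answer_score(question: Question, label: str) -> AnswerScore:
    """Score one categorical answer to one question."""
    scale = question.scale
    if label not in scale.categories:
        raise ValidationError(
            f"question {question.criterion_id!r}: label {label!r} is not in "
            f"scale {list(scale.categories)}"
        )
    k = scale.categories.index(label) + 1
    m = len(scale.categories)
    if scale.kind == "binomial":
        s = 1.0 if label == scale.full_score_category else 0.0
    else:
        s = k / m
    return AnswerScore(
        question_id=question.criterion_id,
        category_label=label,
        ordinal_position=k,
        n_categories=m,
        raw_score=s,
    )


def weighted_question_score(score: AnswerScore, weight: float) -> float:
    """The criterion weight times the answer's raw score, q = w * s."""
    if weight < 0:
        raise ValidationError(f"criterion weight must be nonnegative, got {weight}")
    return weight * score.raw_score


def score_disease(
    disease: str,
    answers: AnswerTable,
    weights: CriterionWeights,
    config: PrioritizationConfig,
) -> ScoreTrace:
    """Run one disease through the weighted decision tree.

    Nodes are visited in descending criterion weight (the ranking order in
    ``weights``); the trace records the answer, raw score and weighted
    score at each node, and ``total`` is their sum.
    """
    if disease not in answers.rows:
        raise ValidationError(f"disease {disease!r} has no answer row")
    row = answers.rows[disease]
    entries = []
    missing = [cid for cid in weights.ranking if cid not in row]
    if missing:
        raise ValidationError(
            [
                f"disease {disease!r}: no answer for question {cid!r}"
                for cid in missing
            ]
        )
    for cid in weights.ranking:
        q = config.question_for(cid)
        sc = answer_score(q, row[cid])
        w = weights.weights[cid]
        entries.append(
            TraceEntry(
                criterion_id=cid,
                category_label=sc.category_label,
                weight=w,
                raw_score=sc.raw_score,
                weighted_score=weighted_question_score(sc, w),
            )
        )
    total = sum(e.weighted_score for e in entries)
    return ScoreTrace(disease=disease, entries=tuple(entries), total=total)


def score_all(
    answers: AnswerTable,
    weights: CriterionWeights,
    config: PrioritizationConfig,
) -> list[ScoreTrace]:
    """Score every configured disease, in configured order."""
    return [score_disease(d, answers, weights, config) for d in config.diseases]


def rank_diseases(
    traces, normalization: str = "max_observed"
) -> RankedDiseaseList:
    """Sort disease totals into the final prioritized list.

    ``normalization='max_observed'`` (default) divides by the top disease's
    total so the leader scores 1; ``'max_possible'`` divides by the sum of
    criterion weights instead.  If every total is zero, normalized scores
    are defined as 0 and a warning is emitted.
    """
    traces = list(traces)
    if not traces:
        raise ValidationError("at least one score trace is required")
    if normalization == "max_observed":
        denom = max(t.total for t in traces)
    elif normalization == "max_possible":
        denom = traces[0].max_possible
    else:
        raise ValidationError(
            f"unknown normalization {normalization!r}: "
            "use 'max_observed' or 'max_possible'"
        )
    if denom <= 0:
        warnings.warn(
            "all disease totals are zero; normalized scores set to 0",
            UserWarning,
        )
    # stable sort keeps configured disease order among ties
    ordered = sorted(traces, key=lambda t: -t.total)
    entries = []
    prev_total = None
    prev_rank = 0
    for pos, t in enumerate(ordered, start=1):
        if prev_total is not None and math.isclose(
            t.total, prev_total, abs_tol=_TIE_TOL
        ):
            rank = prev_rank  # competition ranking: ties share a rank
        else:
            rank = pos
        prev_total, prev_rank = t.total, rank
        entries.append(
            RankedDisease(
                rank=rank,
                disease=t.disease,
                total=t.total,
                normalized=(t.total / denom) if denom > 0 else 0.0,
            )
        )
    return RankedDiseaseList(
        entries=tuple(entries),
        t_max=max(t.total for t in traces),
        normalization=normalization,
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Ranked list with one criterion left out, and how many ranks moved."""

    criterion_id: str
    ranked: RankedDiseaseList
    rank_changes: int


def sensitivity_scan(
    answers: AnswerTable,
    weights: CriterionWeights,
    config: PrioritizationConfig,
) -> dict[str, SensitivityResult]:
    """Leave-one-criterion-out sensitivity of the final ranking.

    For each criterion, the remaining criteria keep their relative order
    and are re-weighted sequentially (n-1 ... 1); all diseases are
    re-scored and re-ranked, and the number of diseases whose rank differs
    from the baseline ranking is counted.  Deterministic.
    """
    if len(weights.ranking) < 2:
        raise ValidationError(
            "sensitivity scan requires at least 2 criteria"
        )
    baseline = rank_diseases(score_all(answers, weights, config))
    base_rank = {e.disease: e.rank for e in baseline.entries}
    out: dict[str, SensitivityResult] = {}
    for cid in weights.ranking:
        remaining = tuple(c for c in weights.ranking if c != cid)
        n = len(remaining)
        reduced = CriterionWeights(
            ranking=remaining,
            priorities={c: weights.priorities[c] for c in remaining},
            weights={c: float(n - r) for r, c in enumerate(remaining)},
            tie_notes=(),
        )
        ranked = rank_diseases(score_all(answers, reduced, config))
        changes = sum(
            1 for e in ranked.entries if e.rank != base_rank[e.disease]
        )
        out[cid] = SensitivityResult(
            criterion_id=cid, ranked=ranked, rank_changes=changes
        )
    return out
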