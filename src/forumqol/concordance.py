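"""Annotation vs. survey concordance: binarization, confusion counts, metrics.

The core procedure treats each annotated forum statement as a prediction of
the user's own questionnaire answer for the same question.  Both sides are
binarized — annotation polarity is already two-valued; survey answers map
"not at all" (1) to negative and "a little"/"quite a bit"/"very much"
(2-4) to positive.  The two 7-level global items (29, 30) have no printed
rule; the midpoint convention used here calls answers <= 4 positive
(impaired global health) and 5-7 negative, configurable via
``SEVEN_LEVEL_POSITIVE_MAX``.

A comparison where both sides are positive is a TP; annotation positive but
survey negative an FP; both negative a TN; annotation negative but survey
positive an FN.  Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean.  Counts can be pooled (micro-pooling) over fine or coarse
question groups, or overall.  Users with no labeled data for a question
simply do not contribute to that question's counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import catalog
from .corpus import BinaryLabel, Corpus, Polarity

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonLevel",
    "GroupBy",
    "Comparison",
    "ConfusionCounts",
    "Metrics",
    "ConcordanceResult",
    "SEVEN_LEVEL_POSITIVE_MAX",
    "binarize_answer",
    "filter_window",
    "user_prediction",
    "build_comparisons",
    "confusion",
    "metrics",
    "concordance_table",
    "user_accuracy_summary",
    "question_coverage",
    "mean_sd",
]

#: 7-level items (qids 29/30): answers <= this value count as positive
#: (impaired global health/QoL).  Midpoint of the 1-7 scale by default.
SEVEN_LEVEL_POSITIVE_MAX = 4


class ComparisonLevel(str, Enum):
    ANNOTATION = "annotation"  # one comparison per span annotation
    USER = "user"  # one per (user, question) via majority vote


class GroupBy(str, Enum):
    question = "question"
    fine = "fine"
    coarse = "coarse"
    overall = "overall"


@dataclass(frozen=True)
class Comparison:
    user_id: str
    qid: int
    predicted: BinaryLabel  # from the annotation(s)
    actual: BinaryLabel  # from the binarized survey answer
    level: ComparisonLevel
    n_source_annotations: int = 1
    exact_match: bool = False

    @property
    def outcome(self) -> str:
        if self.predicted is Polarity.POSITIVE:
            return "tp" if self.actual is Polarity.POSITIVE else "fp"
        return "fn" if self.actual is Polarity.POSITIVE else "tn"


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, outcome: str, n: int = 1) -> None:
        setattr(self, outcome, getattr(self, outcome) + n)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


@dataclass(frozen=True)
class ConcordanceResult:
    key: str
    level: ComparisonLevel
    counts: ConfusionCounts
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    total_annotations: int


def binarize_answer(qid: int, value: int) -> BinaryLabel:
    """Binarize one ordinal survey answer.

    4-level items: 1 ("not at all") -> NEGATIVE, 2-4 -> POSITIVE.
    7-level items: <= SEVEN_LEVEL_POSITIVE_MAX -> POSITIVE (impaired),
    above -> NEGATIVE.
    """
    question = catalog.get_question(qid)
    if not (1 <= value <= question.n_levels):
        raise ValueError(f"answer {value} for q{qid} outside 1..{question.n_levels}")
    if question.n_levels == 7:
        return Polarity.POSITIVE if value <= SEVEN_LEVEL_POSITIVE_MAX else Polarity.NEGATIVE
    return Polarity.NEGATIVE if value == 1 else Polarity.POSITIVE


def filter_window(
    corpus: Corpus, months: int, exclude_past_refs: bool = False
) -> Corpus:
    """View of the corpus restricted to each user's pre-survey window.

    Keeps documents with ``survey_date - months <= timestamp <= survey_date``
    (calendar months, per user); optionally also drops documents flagged as
    referring to past events.  An annotated user without a survey date is an
    error; unannotated documents of unsurveyed users are dropped silently.
    """
    if months <= 0:
        raise ValueError("months must be positive")
    annotated_users = {
        corpus.documents[a.doc_id].user_id
        for a in corpus.annotations
        if a.doc_id in corpus.documents
    }
    missing = sorted(annotated_users - set(corpus.surveys))
    if missing:
        raise ValueError(
            f"annotated user(s) without a survey date: {', '.join(missing)}"
        )

    keep = []
    for doc_id, doc in corpus.documents.items():
        survey = corpus.surveys.get(doc.user_id)
        if survey is None:
            continue
        start = (pd.Timestamp(survey.survey_date) - pd.DateOffset(months=months)).date()
        if not (start <= doc.timestamp <= survey.survey_date):
            continue
        if exclude_past_refs and corpus.flags_for(doc_id).refers_to_past:
            continue
        keep.append(doc_id)
    return corpus.subset(keep)


def user_prediction(
    labels: Sequence[BinaryLabel], tie_break: BinaryLabel = Polarity.POSITIVE
) -> Optional[BinaryLabel]:
    """Majority label over a user's annotations for one question.

    Ties go to ``tie_break`` (positive by default: the annotation schema is
    presence-biased).  An empty list yields ``None`` — the user contributes
    nothing for that question.
    """
    if not labels:
        return None
    n_pos = sum(1 for l in labels if l is Polarity.POSITIVE)
    n_neg = len(labels) - n_pos
    if n_pos > n_neg:
        return Polarity.POSITIVE
    if n_neg > n_pos:
        return Polarity.NEGATIVE
    return tie_break


def build_comparisons(
    corpus: Corpus,
    level: ComparisonLevel = ComparisonLevel.ANNOTATION,
    lenient: bool = False,
) -> list[Comparison]:
    """Pair every annotation (or user x question majority) with the
    binarized survey answer of the same user and question.

    ``lenient=True`` skips (with a warning) annotations whose user lacks a
    survey or whose question was not answered, instead of raising.
    """
    level = ComparisonLevel(level)
    comparisons: list[Comparison] = []
    skipped = 0

    def actual_for(user_id: str, qid: int) -> Optional[BinaryLabel]:
        nonlocal skipped
        survey = corpus.surveys.get(user_id)
        if survey is None or qid not in survey.answers:
            if not lenient:
                raise ValueError(
                    f"no survey answer for user {user_id!r} question {qid}"
                )
            skipped += 1
            return None
        return binarize_answer(qid, survey.answers[qid])

    if level is ComparisonLevel.ANNOTATION:
        for ann in corpus.annotations:
            doc = corpus.documents.get(ann.doc_id)
            if doc is None:
                continue
            actual = actual_for(doc.user_id, ann.qid)
            if actual is None:
                continue
            comparisons.append(
                Comparison(
                    user_id=doc.user_id,
                    qid=ann.qid,
                    predicted=ann.polarity,
                    actual=actual,
                    level=level,
                    n_source_annotations=1,
                    exact_match=ann.exact_match,
                )
            )
    else:
        by_user_q: dict[tuple[str, int], list[Polarity]] = {}
        for ann in corpus.annotations:
            doc = corpus.documents.get(ann.doc_id)
            if doc is None:
                continue
            by_user_q.setdefault((doc.user_id, ann.qid), []).append(ann.polarity)
        for (user_id, qid), labels in sorted(by_user_q.items()):
            predicted = user_prediction(labels)
            if predicted is None:
                continue
            actual = actual_for(user_id, qid)
            if actual is None:
                continue
            comparisons.append(
                Comparison(
                    user_id=user_id,
                    qid=qid,
                    predicted=predicted,
                    actual=actual,
                    level=level,
                    n_source_annotations=len(labels),
                )
            )
    if skipped:
        logger.warning("build_comparisons: skipped %d annotation(s) without survey answers", skipped)
    return comparisons


def _key_for(qid: int, key_by: GroupBy) -> str:
    if key_by is GroupBy.question:
        return f"q{qid}"
    if key_by is GroupBy.fine:
        return catalog.get_question(qid).fine_group
    if key_by is GroupBy.coarse:
        return catalog.get_question(qid).coarse_group.value
    return "overall"


def confusion(
    comparisons: Iterable[Comparison], key_by: GroupBy = GroupBy.question
) -> dict[str, ConfusionCounts]:
    """Pool TP/FP/TN/FN over all comparisons mapping to each key
    (micro-pooling across a group's member questions)."""
    key_by = GroupBy(key_by)
    table: dict[str, ConfusionCounts] = {}
    for cmp_ in comparisons:
        key = _key_for(cmp_.qid, key_by)
        table.setdefault(key, ConfusionCounts()).add(cmp_.outcome)
    return table


def metrics(counts: ConfusionCounts) -> Metrics:
    """Precision, recall, F1; each None when its denominator is zero.

    F1 is defined as 0 whenever tp = 0 but fp + fn > 0, and None only when
    tp = fp = fn = 0 (no positive instances on either side).
    """
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if counts.tp == 0:
        f1 = 0.0 if (counts.fp + counts.fn) > 0 else None
    else:
        f1 = 2 * counts.tp / (2 * counts.tp + counts.fp + counts.fn)
    return Metrics(precision=precision, recall=recall, f1=f1)


def concordance_table(
    comparisons: Sequence[Comparison], key_by: GroupBy = GroupBy.question
) -> list[ConcordanceResult]:
    """Confusion counts + metrics per key, with total contributing
    annotations, sorted by total (desc) then key."""
    key_by = GroupBy(key_by)
    counts = confusion(comparisons, key_by)
    totals: dict[str, int] = {}
    for cmp_ in comparisons:
        key = _key_for(cmp_.qid, key_by)
        totals[key] = totals.get(key, 0) + cmp_.n_source_annotations
    level = comparisons[0].level if comparisons else ComparisonLevel.ANNOTATION
    results = []
    for key, cc in counts.items():
        m = metrics(cc)
        results.append(
            ConcordanceResult(
                key=key,
                level=level,
                counts=cc,
                precision=m.precision,
                recall=m.recall,
                f1=m.f1,
                total_annotations=totals[key],
            )
        )
    results.sort(key=lambda r: (-r.total_annotations, r.key))
    return results


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Unweighted mean and sample SD (ddof=1); SD is 0.0 for a single value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sd of empty sequence")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def user_accuracy_summary(
    comparisons: Sequence[Comparison],
) -> tuple[dict[str, float], float, float]:
    """Per-user accuracy over the user's contributing questions, plus the
    cross-user mean and sample SD.

    Accuracy for a user is (TP+TN)/total over their USER-level comparisons.
    """
    per_user: dict[str, ConfusionCounts] = {}
    for cmp_ in comparisons:
        per_user.setdefault(cmp_.user_id, ConfusionCounts()).add(cmp_.outcome)
    accuracy = {
        u: (cc.tp + cc.tn) / cc.total for u, cc in sorted(per_user.items()) if cc.total
    }
    if not accuracy:
        return {}, float("nan"), float("nan")
    mean, sd = mean_sd(list(accuracy.values()))
    return accuracy, mean, sd


def question_coverage(corpus: Corpus) -> tuple[dict[str, float], float, float]:
    """Per-user fraction of the 53 questions with >=1 annotation, plus the
    mean and sample SD over users with any annotated document."""
    qids_by_user: dict[str, set[int]] = {}
    for ann in corpus.annotations:
        doc = corpus.documents.get(ann.doc_id)
        if doc is not None:
            qids_by_user.setdefault(doc.user_id, set()).add(ann.qid)
    coverage = {
        u: len(qids) / len(catalog.ALL_QIDS) for u, qids in sorted(qids_by_user.items())
    }
    if not coverage:
        return {}, float("nan"), float("nan")
    mean, sd = mean_sd(list(coverage.values()))
    return coverage, mean, sd
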