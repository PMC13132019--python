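"""Inter-annotator agreement per question via Fleiss kappa.

Span annotations are unitized to fixed rating items at two granularities:

* WORD — one item per whitespace-delimited token of every in-scope
  document; a rater "labels" the token iff one of their spans for the
  question overlaps the token's character range by at least one code point.
* DOC  — one item per document; labeled iff the rater placed at least one
  span for the question anywhere in it.

Each question is handled separately with two categories (labeled /
unlabeled), ignoring polarity and exact-match attributes.  Fleiss' kappa
assumes a fixed number of raters per item, so agreement is computed per
homogeneous stratum: the caller supplies an explicit annotator panel and
documents not covered by the full panel are excluded (with a logged count).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "UnitKind",
    "UnitRatingMatrix",
    "AgreementResult",
    "tokenize",
    "unitize",
    "fleiss_kappa",
    "agreement_table",
]

_TOKEN_RE = re.compile(r"\S+")


class UnitKind(str, Enum):
    WORD = "word"
    DOC = "doc"


@dataclass(frozen=True)
class UnitRatingMatrix:
    """Per-item (n_labeled, n_unlabeled) rating counts for one question."""

    unit_kind: UnitKind
    qid: int
    n_raters: int
    counts: np.ndarray  # shape (n_items, 2), rows sum to n_raters

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if self.n_raters < 2:
            raise ValueError("Fleiss kappa needs at least 2 raters")
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must have shape (n_items, 2)")
        if counts.shape[0] >= 1 and not np.all(counts.sum(axis=1) == self.n_raters):
            raise ValueError("every item's ratings must sum to n_raters")

    @property
    def n_items(self) -> int:
        return int(self.counts.shape[0])


@dataclass(frozen=True)
class AgreementResult:
    qid: int
    unit_kind: UnitKind
    kappa: float
    n_items: int
    n_raters: int
    n_labeled_docs: int  # documents where >=1 panel member assigned the label
    degenerate: bool = False  # all ratings in a single category


def tokenize(text: str) -> list[tuple[int, int]]:
    """Character ranges [start, end) of whitespace-delimited tokens."""
    return [m.span() for m in _TOKEN_RE.finditer(text)]


def _covered_doc_ids(corpus: Corpus, panel: frozenset[str]) -> list[str]:
    covered, skipped = [], 0
    for doc_id, doc in corpus.documents.items():
        if doc.annotators is None or panel <= set(doc.annotators):
            covered.append(doc_id)
        else:
            skipped += 1
    if skipped:
        logger.info(
            "unitize: excluded %d document(s) not covered by the full panel", skipped
        )
    return covered


def unitize(
    corpus: Corpus,
    qid: int,
    annotator_panel: Iterable[str],
    unit_kind: UnitKind = UnitKind.WORD,
) -> UnitRatingMatrix:
    """Build the per-item rating matrix for one question and panel."""
    panel = frozenset(annotator_panel)
    if len(panel) < 2:
        raise ValueError("annotator panel must contain at least 2 raters")
    unit_kind = UnitKind(unit_kind)
    n_raters = len(panel)

    spans: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ann in corpus.annotations:
        if ann.qid == qid and ann.annotator_id in panel:
            spans.setdefault(ann.doc_id, {}).setdefault(ann.annotator_id, []).append(
                (ann.start, ann.end)
            )

    rows: list[tuple[int, int]] = []
    for doc_id in _covered_doc_ids(corpus, panel):
        doc = corpus.documents[doc_id]
        by_rater = spans.get(doc_id, {})
        if unit_kind is UnitKind.DOC:
            n_labeled = sum(1 for r in panel if by_rater.get(r))
            rows.append((n_labeled, n_raters - n_labeled))
        else:
            for tok_start, tok_end in tokenize(doc.text):
                n_labeled = sum(
                    1
                    for r in panel
                    if any(s < tok_end and e > tok_start for s, e in by_rater.get(r, ()))
                )
                rows.append((n_labeled, n_raters - n_labeled))

    counts = np.array(rows, dtype=np.int64).reshape(-1, 2)
    return UnitRatingMatrix(unit_kind=unit_kind, qid=qid, n_raters=n_raters, counts=counts)


def fleiss_kappa(matrix: UnitRatingMatrix | np.ndarray, n_raters: Optional[int] = None) -> float:
    """Fleiss' kappa for a (n_items, n_categories) rating-count matrix.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar) with per-item agreement
    P_i = [sum_j n_ij (n_ij - 1)] / [n (n - 1)] and chance agreement
    Pe_bar = sum_j p_j^2, p_j the marginal category proportions.

    When every rating falls in a single category, 1 - Pe_bar is zero while
    observed agreement is perfect; this degenerate case returns 1.0.
    """
    if isinstance(matrix, UnitRatingMatrix):
        counts = matrix.counts
        n = matrix.n_raters
    else:
        counts = np.asarray(matrix, dtype=np.float64)
        n = int(counts[0].sum()) if n_raters is None else n_raters
    if n < 2:
        raise ValueError("Fleiss kappa needs at least 2 raters")
    counts = np.asarray(counts, dtype=np.float64)
    n_items = counts.shape[0]
    if n_items == 0:
        raise ValueError("rating matrix has no items")

    p_j = counts.sum(axis=0) / (n_items * n)
    pe_bar = float(np.sum(p_j**2))
    p_i = (np.sum(counts * (counts - 1.0), axis=1)) / (n * (n - 1.0))
    p_bar = float(np.mean(p_i))
    if 1.0 - pe_bar < 1e-15:
        return 1.0
    return (p_bar - pe_bar) / (1.0 - pe_bar)


def is_degenerate(matrix: UnitRatingMatrix) -> bool:
    """True when all ratings fall in one category (chance agreement = 1)."""
    if matrix.n_items == 0:
        return True
    totals = matrix.counts.sum(axis=0)
    return int(np.count_nonzero(totals)) <= 1


def agreement_table(
    corpus: Corpus,
    qids: Sequence[int],
    unit_kind: UnitKind,
    annotator_panel: Iterable[str],
) -> list[AgreementResult]:
    """One AgreementResult per question, reproducing per-question kappa
    listings with the count of documents carrying the label."""
    panel = frozenset(annotator_panel)
    results = []
    for qid in qids:
        matrix = unitize(corpus, qid, panel, unit_kind)
        if matrix.n_items == 0:
            logger.warning("agreement_table: no panel-covered documents for q%d", qid)
            continue
        labeled_docs = {
            a.doc_id
            for a in corpus.annotations
            if a.qid == qid and a.annotator_id in panel and a.doc_id in corpus.documents
        }
        covered = set(_covered_doc_ids(corpus, panel))
        results.append(
            AgreementResult(
                qid=qid,
                unit_kind=UnitKind(unit_kind),
                kappa=fleiss_kappa(matrix),
                n_items=matrix.n_items,
                n_raters=matrix.n_raters,
                n_labeled_docs=len(labeled_docs & covered),
                degenerate=is_degenerate(matrix),
            )
        )
    return results
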