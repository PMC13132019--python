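"""Data model and I/O for forum documents, span annotations and surveys.

On-disk layout (one directory):

* ``documents.jsonl``  — one object per line: doc_id, user_id, timestamp
  (ISO date), doc_type ("post"/"comment"), text, and optionally
  ``annotators`` (the panel assigned to code the document; absent/null when
  coverage is unknown).
* ``annotations.jsonl`` — doc_id, annotator_id, qid, start, end, polarity,
  exact_match.  Offsets are 0-based, half-open ``[start, end)`` in Unicode
  code points (standoff convention).
* ``flags.jsonl`` — doc_id, refers_to_past, subject_is_self (only
  non-default flag records need to be present).
* ``survey.csv`` — user_id, survey_date, q1..q53, plus optional demographic
  columns.

Annotation polarity marks whether the annotated text reports presence
("positive", the unmarked base-label case) or absence ("negative") of the
issue the question asks about.
"""

from __future__ import annotations

import csv
import json
import logging
from datetime import date
from pathlib import Path
from enum import Enum
from typing import Iterable, Optional, Union

from pydantic import BaseModel, Field, field_validator

from . import catalog

logger = logging.getLogger(__name__)

__all__ = [
    "Polarity",
    "BinaryLabel",
    "ForumDocument",
    "SpanAnnotation",
    "DocumentFlags",
    "SurveyRecord",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "write_brat",
    "exclude_other_subject",
]


class Polarity(str, Enum):
    POSITIVE = "positive"  # issue present / question answered "yes"
    NEGATIVE = "negative"  # issue absent / question answered "no"

    def flipped(self) -> "Polarity":
        return Polarity.NEGATIVE if self is Polarity.POSITIVE else Polarity.POSITIVE


#: Binarized survey answers use the same two-valued label as annotations.
BinaryLabel = Polarity


class ForumDocument(BaseModel):
    model_config = {"frozen": True}

    doc_id: str
    user_id: str
    timestamp: date
    doc_type: str = Field(pattern="^(post|comment)$")
    text: str = Field(min_length=1)
    #: panel assigned to annotate this document; None = unknown (assumed
    #: covered by any requested panel), () = not annotated.
    annotators: Optional[tuple[str, ...]] = None


class SpanAnnotation(BaseModel):
    model_config = {"frozen": True}

    doc_id: str
    annotator_id: str
    qid: int = Field(ge=1, le=53)
    start: int = Field(ge=0)
    end: int
    polarity: Polarity = Polarity.POSITIVE
    exact_match: bool = False

    @field_validator("end")
    @classmethod
    def _end_after_start(cls, v: int, info):
        start = info.data.get("start")
        if start is not None and v <= start:
            raise ValueError(f"span end {v} must exceed start {start}")
        return v


class DocumentFlags(BaseModel):
    model_config = {"frozen": True}

    doc_id: str
    refers_to_past: bool = False
    subject_is_self: bool = True


class SurveyRecord(BaseModel):
    model_config = {"frozen": True}

    user_id: str
    survey_date: date
    answers: dict[int, int]
    demographics: dict[str, object] = Field(default_factory=dict)

    @field_validator("answers")
    @classmethod
    def _answers_in_range(cls, v: dict[int, int]):
        for qid, value in v.items():
            n_levels = catalog.get_question(qid).n_levels
            if not (1 <= value <= n_levels):
                raise ValueError(
                    f"answer {value} for q{qid} outside 1..{n_levels}"
                )
        return v


class Corpus(BaseModel):
    """In-memory container tying documents, annotations, flags and surveys.

    Views produced by filters (time windows, subject exclusion) are plain
    new ``Corpus`` instances sharing the record objects.
    """

    documents: dict[str, ForumDocument] = Field(default_factory=dict)
    annotations: list[SpanAnnotation] = Field(default_factory=list)
    flags: dict[str, DocumentFlags] = Field(default_factory=dict)
    surveys: dict[str, SurveyRecord] = Field(default_factory=dict)

    def validate_links(self) -> None:
        """Check cross-record invariants; raise ValueError on the first hit."""
        for i, ann in enumerate(self.annotations):
            doc = self.documents.get(ann.doc_id)
            if doc is None:
                raise ValueError(
                    f"annotation #{i} references unknown doc_id {ann.doc_id!r}"
                )
            if ann.end > len(doc.text):
                raise ValueError(
                    f"annotation #{i} on {ann.doc_id!r}: end {ann.end} exceeds "
                    f"text length {len(doc.text)}"
                )
        for doc_id in self.flags:
            if doc_id not in self.documents:
                raise ValueError(f"flags reference unknown doc_id {doc_id!r}")

    def flags_for(self, doc_id: str) -> DocumentFlags:
        return self.flags.get(doc_id, DocumentFlags(doc_id=doc_id))

    def annotations_for(self, doc_id: str) -> list[SpanAnnotation]:
        return [a for a in self.annotations if a.doc_id == doc_id]

    def annotated_doc_ids(self) -> set[str]:
        return {a.doc_id for a in self.annotations}

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        keep = set(doc_ids)
        return Corpus(
            documents={d: doc for d, doc in self.documents.items() if d in keep},
            annotations=[a for a in self.annotations if a.doc_id in keep],
            flags={d: f for d, f in self.flags.items() if d in keep},
            surveys=dict(self.surveys),
        )

    def __eq__(self, other: object) -> bool:  # order-insensitive on annotations
        if not isinstance(other, Corpus):
            return NotImplemented
        key = lambda a: (a.doc_id, a.annotator_id, a.qid, a.start, a.end)
        return (
            self.documents == other.documents
            and sorted(self.annotations, key=key) == sorted(other.annotations, key=key)
            and self.flags == other.flags
            and self.surveys == other.surveys
        )


def _read_jsonl(path: Path) -> Iterable[tuple[int, dict]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path.name}:{lineno}: invalid JSON: {exc}") from None


def read_corpus(directory: Union[str, Path]) -> Corpus:
    """Read and validate a corpus directory; see module docstring for layout.

    Missing files are treated as empty collections (survey.csv and
    documents.jsonl excepted only when genuinely absent).
    """
    directory = Path(directory)
    corpus = Corpus()

    docs_path = directory / "documents.jsonl"
    if docs_path.exists():
        for lineno, obj in _read_jsonl(docs_path):
            try:
                if obj.get("annotators") is not None:
                    obj["annotators"] = tuple(obj["annotators"])
                doc = ForumDocument(**obj)
            except Exception as exc:
                raise ValueError(f"documents.jsonl:{lineno}: {exc}") from None
            if doc.doc_id in corpus.documents:
                raise ValueError(f"documents.jsonl:{lineno}: duplicate doc_id {doc.doc_id!r}")
            corpus.documents[doc.doc_id] = doc

    ann_path = directory / "annotations.jsonl"
    if ann_path.exists():
        for lineno, obj in _read_jsonl(ann_path):
            try:
                corpus.annotations.append(SpanAnnotation(**obj))
            except Exception as exc:
                raise ValueError(f"annotations.jsonl:{lineno}: {exc}") from None

    flags_path = directory / "flags.jsonl"
    if flags_path.exists():
        for lineno, obj in _read_jsonl(flags_path):
            try:
                rec = DocumentFlags(**obj)
            except Exception as exc:
                raise ValueError(f"flags.jsonl:{lineno}: {exc}") from None
            if rec.doc_id in corpus.flags:
                raise ValueError(f"flags.jsonl:{lineno}: duplicate flags for {rec.doc_id!r}")
            corpus.flags[rec.doc_id] = rec

    survey_path = directory / "survey.csv"
    if survey_path.exists():
        with survey_path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            qcols = [c for c in (reader.fieldnames or []) if c.startswith("q") and c[1:].isdigit()]
            demo_cols = [
                c
                for c in (reader.fieldnames or [])
                if c not in qcols and c not in ("user_id", "survey_date")
            ]
            for lineno, row in enumerate(reader, start=2):
                answers = {
                    int(c[1:]): int(row[c]) for c in qcols if row.get(c, "") != ""
                }
                demographics = {c: row[c] for c in demo_cols if row.get(c, "") != ""}
                try:
                    rec = SurveyRecord(
                        user_id=row["user_id"],
                        survey_date=date.fromisoformat(row["survey_date"]),
                        answers=answers,
                        demographics=demographics,
                    )
                except Exception as exc:
                    raise ValueError(f"survey.csv:{lineno}: {exc}") from None
                if rec.user_id in corpus.surveys:
                    raise ValueError(f"survey.csv:{lineno}: duplicate survey for {rec.user_id!r}")
                corpus.surveys[rec.user_id] = rec

    corpus.validate_links()
    return corpus


def write_corpus(corpus: Corpus, directory: Union[str, Path]) -> None:
    """Write a corpus directory such that ``read_corpus`` round-trips it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with (directory / "documents.jsonl").open("w", encoding="utf-8") as fh:
        for doc in corpus.documents.values():
            obj = {
                "doc_id": doc.doc_id,
                "user_id": doc.user_id,
                "timestamp": doc.timestamp.isoformat(),
                "doc_type": doc.doc_type,
                "text": doc.text,
            }
            if doc.annotators is not None:
                obj["annotators"] = list(doc.annotators)
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")

    with (directory / "annotations.jsonl").open("w", encoding="utf-8") as fh:
        for ann in corpus.annotations:
            fh.write(
                json.dumps(
                    {
                        "doc_id": ann.doc_id,
                        "annotator_id": ann.annotator_id,
                        "qid": ann.qid,
                        "start": ann.start,
                        "end": ann.end,
                        "polarity": ann.polarity.value,
                        "exact_match": ann.exact_match,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )

    with (directory / "flags.jsonl").open("w", encoding="utf-8") as fh:
        for rec in corpus.flags.values():
            fh.write(
                json.dumps(
                    {
                        "doc_id": rec.doc_id,
                        "refers_to_past": rec.refers_to_past,
                        "subject_is_self": rec.subject_is_self,
                    }
                )
                + "\n"
            )

    demo_cols: list[str] = []
    for rec in corpus.surveys.values():
        for c in rec.demographics:
            if c not in demo_cols:
                demo_cols.append(c)
    with (directory / "survey.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["user_id", "survey_date"] + [f"q{q}" for q in catalog.ALL_QIDS] + demo_cols
        )
        for rec in corpus.surveys.values():
            row = [rec.user_id, rec.survey_date.isoformat()]
            row += [rec.answers.get(q, "") for q in catalog.ALL_QIDS]
            row += [rec.demographics.get(c, "") for c in demo_cols]
            writer.writerow(row)


def write_brat(corpus: Corpus, directory: Union[str, Path]) -> None:
    """Export documents + annotations in BRAT standoff style for inspection.

    One ``<doc_id>.txt`` and ``<doc_id>.ann`` per document; entity type is
    ``Q<qid>``, with polarity/exact-match carried as attribute lines.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc_id, doc in corpus.documents.items():
        (directory / f"{doc_id}.txt").write_text(doc.text, encoding="utf-8")
        lines = []
        t = a = 0
        for ann in corpus.annotations_for(doc_id):
            t += 1
            lines.append(
                f"T{t}\tQ{ann.qid} {ann.start} {ann.end}\t{doc.text[ann.start:ann.end]}"
            )
            a += 1
            lines.append(f"A{a}\tPolarity T{t} {ann.polarity.value}")
            if ann.exact_match:
                a += 1
                lines.append(f"A{a}\tExactMatch T{t}")
            a += 1
            lines.append(f"A{a}\tAnnotator T{t} {ann.annotator_id}")
        (directory / f"{doc_id}.ann").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )


def exclude_other_subject(corpus: Corpus) -> Corpus:
    """Drop documents whose QoL content refers to someone other than the
    posting user (``subject_is_self=False``) from statistics-facing views."""
    keep = [
        d for d in corpus.documents if corpus.flags_for(d).subject_is_self
    ]
    removed = len(corpus.documents) - len(keep)
    if removed:
        logger.info("excluded %d other-subject document(s) from evaluation", removed)
    if removed == len(corpus.documents) and corpus.documents:
        logger.warning("all documents flagged other-subject; statistics view is empty")
    return corpus.subset(keep)
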