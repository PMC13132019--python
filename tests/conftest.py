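"""Shared fixtures: a tiny hand-built corpus exercising every record kind."""

from datetime import date

import pytest

from forumqol.corpus import (
    Corpus,
    DocumentFlags,
    ForumDocument,
    SpanAnnotation,
    SurveyRecord,
)


def make_survey(user_id: str, answers: dict[int, int], survey_date=date(2024, 6, 1)):
    base = {q: 1 for q in range(1, 54)}
    base.update(answers)
    return SurveyRecord(user_id=user_id, survey_date=survey_date, answers=base)


@pytest.fixture
def tiny_corpus() -> Corpus:
    """3 documents, 2 users, 4 annotations, 2 surveys, 1 other-subject flag."""
    docs = {
        "d1": ForumDocument(
            doc_id="d1",
            user_id="alice",
            timestamp=date(2024, 4, 15),
            doc_type="post",
            text="I had so much pain last week! It was exhausting.",
            annotators=("A1", "A2"),
        ),
        "d2": ForumDocument(
            doc_id="d2",
            user_id="bob",
            timestamp=date(2024, 5, 2),
            doc_type="comment",
            text="I do not have any pain. Stay strong ❤",
            annotators=("A1", "A2"),
        ),
        "d3": ForumDocument(
            doc_id="d3",
            user_id="alice",
            timestamp=date(2023, 1, 10),
            doc_type="comment",
            text="My sister was so worried back then.",
            annotators=("A1", "A2"),
        ),
    }
    annotations = [
        SpanAnnotation(doc_id="d1", annotator_id="A1", qid=9, start=0, end=29,
                       polarity="positive", exact_match=True),
        SpanAnnotation(doc_id="d1", annotator_id="A2", qid=9, start=13, end=17,
                       polarity="positive"),
        SpanAnnotation(doc_id="d2", annotator_id="A1", qid=9, start=0, end=23,
                       polarity="negative"),
        SpanAnnotation(doc_id="d3", annotator_id="A1", qid=22, start=0, end=34,
                       polarity="positive"),
    ]
    flags = {
        "d3": DocumentFlags(doc_id="d3", refers_to_past=True, subject_is_self=False),
    }
    surveys = {
        "alice": make_survey("alice", {9: 3, 22: 1}),
        "bob": make_survey("bob", {9: 1}),
    }
    corpus = Corpus(documents=docs, annotations=annotations, flags=flags, surveys=surveys)
    corpus.validate_links()
    return corpus
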