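"""Unitization and Fleiss kappa, checked against a brute-force oracle."""

from datetime import date

import numpy as np
import pytest

from forumqol.agreement import (
    UnitKind,
    UnitRatingMatrix,
    agreement_table,
    fleiss_kappa,
    tokenize,
    unitize,
)
from forumqol.corpus import Corpus, ForumDocument, SpanAnnotation


def fleiss_kappa_bruteforce(counts) -> float:
    """Independent, loop-based evaluation of Fleiss' 1971 formula."""
    counts = [list(map(int, row)) for row in counts]
    n_items = len(counts)
    n = sum(counts[0])
    totals = [0.0] * len(counts[0])
    p_bar = 0.0
    for row in counts:
        agree = 0
        for j, nij in enumerate(row):
            agree += nij * (nij - 1)
            totals[j] += nij
        p_bar += agree / (n * (n - 1))
    p_bar /= n_items
    pe = sum((t / (n_items * n)) ** 2 for t in totals)
    if abs(1 - pe) < 1e-15:
        return 1.0
    return (p_bar - pe) / (1 - pe)


def doc_corpus(texts_and_spans):
    """Corpus of single-user docs: [(text, {annotator: [(qid, s, e), ...]})]."""
    corpus = Corpus()
    for i, (text, by_rater) in enumerate(texts_and_spans):
        doc_id = f"d{i}"
        corpus.documents[doc_id] = ForumDocument(
            doc_id=doc_id, user_id="u", timestamp=date(2024, 1, 1),
            doc_type="post", text=text,
        )
        for rater, spans in by_rater.items():
            for qid, s, e in spans:
                corpus.annotations.append(
                    SpanAnnotation(doc_id=doc_id, annotator_id=rater, qid=qid,
                                   start=s, end=e)
                )
    return corpus


class TestUnitize:
    def test_identical_spans_rows_unanimous(self):
        corpus = doc_corpus(
            [("one two three four five six seven eight nine ten",
              {"A": [(9, 0, 7)], "B": [(9, 0, 7)]})]
        )
        m = unitize(corpus, 9, {"A", "B"}, UnitKind.WORD)
        assert m.n_items == 10
        assert all(tuple(r) in {(2, 0), (0, 2)} for r in m.counts)

    def test_partial_overlap_marks_token(self):
        # A spans chars [0,4) of "pain was bad", B spans [0,8)
        corpus = doc_corpus(
            [("pain was bad", {"A": [(9, 0, 4)], "B": [(9, 0, 8)]})]
        )
        m = unitize(corpus, 9, {"A", "B"}, UnitKind.WORD)
        assert [tuple(r) for r in m.counts] == [(2, 0), (1, 1), (0, 2)]

    def test_doc_level_all_unlabeled(self):
        corpus = doc_corpus([("no spans here", {})])
        m = unitize(corpus, 9, {"A", "B", "C"}, UnitKind.DOC)
        assert [tuple(r) for r in m.counts] == [(0, 3)]

    def test_panel_of_one_rejected(self):
        corpus = doc_corpus([("text", {})])
        with pytest.raises(ValueError):
            unitize(corpus, 9, {"A"}, UnitKind.WORD)

    def test_uncovered_documents_excluded(self):
        corpus = doc_corpus([("covered doc", {"A": [(9, 0, 7)]})])
        corpus.documents["d0"] = corpus.documents["d0"].model_copy(
            update={"annotators": ("A", "B")}
        )
        corpus.documents["d1"] = ForumDocument(
            doc_id="d1", user_id="u", timestamp=date(2024, 1, 1),
            doc_type="post", text="only rater A saw this", annotators=("A",),
        )
        m = unitize(corpus, 9, {"A", "B"}, UnitKind.WORD)
        assert m.n_items == 2  # d1's 5 tokens excluded

    def test_word_equals_doc_for_single_token_docs(self):
        corpus = doc_corpus(
            [
                ("yes", {"A": [(9, 0, 3)], "B": [(9, 0, 3)]}),
                ("no", {"A": [(9, 0, 2)]}),
                ("maybe", {}),
            ]
        )
        kw = fleiss_kappa(unitize(corpus, 9, {"A", "B"}, UnitKind.WORD))
        kd = fleiss_kappa(unitize(corpus, 9, {"A", "B"}, UnitKind.DOC))
        assert kw == pytest.approx(kd, abs=1e-12)

    def test_tokenize_keeps_punctuation_attached(self):
        assert tokenize("Pain, bad!  ❤") == [(0, 5), (6, 10), (12, 13)]


class TestFleissKappa:
    def test_hand_worked_third(self):
        """4 items, 3 raters, counts [(3,0),(2,1),(0,3),(1,2)] -> 1/3."""
        m = UnitRatingMatrix(
            unit_kind=UnitKind.WORD, qid=9, n_raters=3,
            counts=np.array([[3, 0], [2, 1], [0, 3], [1, 2]]),
        )
        assert fleiss_kappa(m) == pytest.approx(1 / 3, abs=1e-12)

    def test_perfect_agreement_mixed_categories(self):
        m = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_degenerate_single_category_returns_one(self):
        assert fleiss_kappa(np.array([[0, 3], [0, 3]])) == 1.0

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_raters = int(rng.integers(2, 5))
            n_items = int(rng.integers(1, 13))
            labeled = rng.integers(0, n_raters + 1, size=n_items)
            counts = np.stack([labeled, n_raters - labeled], axis=1)
            assert fleiss_kappa(counts, n_raters=n_raters) == pytest.approx(
                fleiss_kappa_bruteforce(counts), abs=1e-10
            )

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(7)
        for _ in range(20):
            labeled = rng.integers(0, 4, size=15)
            counts = np.stack([labeled, 3 - labeled], axis=1)
            if fleiss_kappa_bruteforce(counts) == 1.0 and (counts[:, 0] == counts[0, 0]).all():
                continue  # statsmodels returns nan on the degenerate case
            assert fleiss_kappa(counts, n_raters=3) == pytest.approx(
                sm_fleiss(counts), abs=1e-10
            )

    def test_column_swap_invariance(self):
        rng = np.random.default_rng(3)
        labeled = rng.integers(0, 4, size=30)
        counts = np.stack([labeled, 3 - labeled], axis=1)
        assert fleiss_kappa(counts, n_raters=3) == pytest.approx(
            fleiss_kappa(counts[:, ::-1], n_raters=3), abs=1e-12
        )

    def test_adding_unanimous_item_matches_oracle(self):
        counts = np.array([[2, 1], [1, 2], [3, 0]])
        extended = np.vstack([counts, [0, 3]])
        assert fleiss_kappa(extended, n_raters=3) == pytest.approx(
            fleiss_kappa_bruteforce(extended), abs=1e-12
        )

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[1, 0]]), n_raters=1)


class TestAgreementTable:
    def test_cloned_annotators_all_one(self, tiny_corpus):
        clone = [
            a.model_copy(update={"annotator_id": "A2"})
            for a in tiny_corpus.annotations
            if a.annotator_id == "A1"
        ]
        tiny_corpus.annotations = [
            a for a in tiny_corpus.annotations if a.annotator_id == "A1"
        ] + clone
        for unit in (UnitKind.WORD, UnitKind.DOC):
            for r in agreement_table(tiny_corpus, [9, 22], unit, ["A1", "A2"]):
                assert r.kappa == pytest.approx(1.0)

    def test_total_disagreement_nonpositive(self):
        corpus = doc_corpus(
            [
                ("alpha beta", {"A": [(9, 0, 5)]}),
                ("gamma delta", {"B": [(9, 0, 5)]}),
            ]
        )
        (result,) = agreement_table(corpus, [9], UnitKind.DOC, ["A", "B"])
        assert result.kappa <= 0

    def test_never_labeled_qid_degenerate(self):
        corpus = doc_corpus([("some words here", {"A": [(9, 0, 4)]})])
        (result,) = agreement_table(corpus, [17], UnitKind.WORD, ["A", "B"])
        assert result.kappa == 1.0
        assert result.degenerate
        assert result.n_labeled_docs == 0
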