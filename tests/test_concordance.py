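"""Binarization, temporal filtering, confusion counts and metrics."""

from datetime import date

import numpy as np
import pytest

from forumqol.concordance import (
    Comparison,
    ComparisonLevel,
    ConfusionCounts,
    GroupBy,
    binarize_answer,
    build_comparisons,
    concordance_table,
    confusion,
    filter_window,
    mean_sd,
    metrics,
    question_coverage,
    user_accuracy_summary,
    user_prediction,
)
from forumqol.corpus import Polarity

POS, NEG = Polarity.POSITIVE, Polarity.NEGATIVE


class TestBinarize:
    @pytest.mark.parametrize(
        "qid, value, expected",
        [
            (22, 2, POS),  # "a little" worried -> positive
            (22, 3, POS),
            (22, 4, POS),
            (9, 1, NEG),  # "not at all" pain -> negative
            (29, 7, NEG),  # best global health
            (29, 4, POS),  # midpoint rule: impaired side
            (30, 1, POS),
        ],
    )
    def test_rule(self, qid, value, expected):
        assert binarize_answer(qid, value) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_answer(9, 5)
        with pytest.raises(ValueError):
            binarize_answer(29, 0)


class TestFilterWindow:
    def test_window_boundaries(self, tiny_corpus):
        # survey 2024-06-01: d1 (2024-04-15) inside 6 months, d3 (2023-01-10) out
        view = filter_window(tiny_corpus, 6)
        assert set(view.documents) == {"d1", "d2"}
        view24 = filter_window(tiny_corpus, 24)
        assert set(view24.documents) == {"d1", "d2", "d3"}

    def test_past_reference_exclusion(self, tiny_corpus):
        assert "d3" in filter_window(tiny_corpus, 24, exclude_past_refs=False).documents
        assert "d3" not in filter_window(tiny_corpus, 24, exclude_past_refs=True).documents

    def test_missing_survey_for_annotated_user_errors(self, tiny_corpus):
        del tiny_corpus.surveys["bob"]
        with pytest.raises(ValueError, match="bob"):
            filter_window(tiny_corpus, 6)

    def test_shrinking_window_never_gains_documents(self, tiny_corpus):
        assert set(filter_window(tiny_corpus, 6).documents) <= set(
            filter_window(tiny_corpus, 24).documents
        )


class TestUserPrediction:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([POS, POS, NEG], POS),
            ([NEG, NEG, POS], NEG),
            ([POS, NEG], POS),  # tie -> positive (presence-biased schema)
            ([], None),
        ],
    )
    def test_majority_and_tie(self, labels, expected):
        assert user_prediction(labels) is expected

    def test_configurable_tie_break(self):
        assert user_prediction([POS, NEG], tie_break=NEG) is NEG


class TestBuildComparisons:
    def test_annotation_level_outcomes(self, tiny_corpus):
        # alice q9=3 (pos), q22=1 (neg); bob q9=1 (neg)
        cmp_ = build_comparisons(filter_window(tiny_corpus, 24), ComparisonLevel.ANNOTATION)
        outcomes = sorted(c.outcome for c in cmp_)
        # d1: two POSITIVE q9 spans vs survey positive -> 2 TP
        # d2: NEGATIVE q9 span vs bob negative -> TN
        # d3: POSITIVE q22 vs alice q22 negative -> FP
        assert outcomes == ["fp", "tn", "tp", "tp"]

    def test_user_level_majority(self, tiny_corpus):
        cmp_ = build_comparisons(filter_window(tiny_corpus, 24), ComparisonLevel.USER)
        by_key = {(c.user_id, c.qid): c for c in cmp_}
        assert by_key[("alice", 9)].outcome == "tp"
        assert by_key[("alice", 9)].n_source_annotations == 2
        assert by_key[("bob", 9)].outcome == "tn"
        assert by_key[("alice", 22)].outcome == "fp"

    def test_missing_survey_raises_unless_lenient(self, tiny_corpus):
        view = filter_window(tiny_corpus, 24)
        del view.surveys["bob"]
        with pytest.raises(ValueError, match="bob"):
            build_comparisons(view)
        lenient = build_comparisons(view, lenient=True)
        assert all(c.user_id == "alice" for c in lenient)


def random_comparisons(rng, n):
    return [
        Comparison(
            user_id=f"u{rng.integers(5)}",
            qid=int(rng.integers(1, 54)),
            predicted=POS if rng.random() < 0.5 else NEG,
            actual=POS if rng.random() < 0.5 else NEG,
            level=ComparisonLevel.ANNOTATION,
        )
        for _ in range(n)
    ]


class TestConfusionAndMetrics:
    def test_fine_group_pooling(self):
        cmps = [
            Comparison("u", 9, POS, POS, ComparisonLevel.ANNOTATION),
            Comparison("u", 19, NEG, POS, ComparisonLevel.ANNOTATION),
        ]
        fine = confusion(cmps, GroupBy.fine)
        assert fine == {"Pain": ConfusionCounts(tp=1, fn=1)}
        coarse = confusion(cmps, GroupBy.coarse)
        assert coarse == {"SYMPTOMATIC": ConfusionCounts(tp=1, fn=1)}
        assert confusion([], GroupBy.fine) == {}

    def test_totals_conserved_across_partitions(self):
        rng = np.random.default_rng(11)
        cmps = random_comparisons(rng, 400)
        overall = confusion(cmps, GroupBy.overall)["overall"]
        for key_by in (GroupBy.question, GroupBy.fine, GroupBy.coarse):
            pooled = sum(confusion(cmps, key_by).values(), ConfusionCounts())
            assert pooled == overall
        assert overall.total == 400

    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(tp=1, fp=0, tn=5, fn=0), (1.0, 1.0, 1.0)),
            (ConfusionCounts(tp=0, fp=2, tn=0, fn=1), (0.0, 0.0, 0.0)),
            (ConfusionCounts(tp=3, fp=1, tn=4, fn=2), (0.75, 0.6, 2 / 3)),
        ],
    )
    def test_metric_examples(self, counts, expected):
        m = metrics(counts)
        assert (m.precision, m.recall) == pytest.approx(expected[:2])
        assert m.f1 == pytest.approx(expected[2])

    def test_undefined_metrics(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert m.precision is None and m.recall is None and m.f1 is None
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=1))
        assert m.precision is None and m.recall == 0.0 and m.f1 == 0.0

    def test_metrics_match_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            cmps = random_comparisons(rng, int(rng.integers(1, 30)))
            cc = confusion(cmps, GroupBy.overall)["overall"]
            tp = sum(1 for c in cmps if c.predicted is POS and c.actual is POS)
            fp = sum(1 for c in cmps if c.predicted is POS and c.actual is NEG)
            fn = sum(1 for c in cmps if c.predicted is NEG and c.actual is POS)
            m = metrics(cc)
            assert (cc.tp, cc.fp, cc.fn) == (tp, fp, fn)
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))
            if m.precision and m.recall:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall)
                )

    def test_flipping_labels_swaps_counts(self):
        rng = np.random.default_rng(13)
        cmps = random_comparisons(rng, 200)
        a = confusion(cmps, GroupBy.overall)["overall"]
        # flipping every predicted label: TP<->FN, FP<->TN
        flip_pred = [
            Comparison(c.user_id, c.qid, c.predicted.flipped(), c.actual, c.level)
            for c in cmps
        ]
        b = confusion(flip_pred, GroupBy.overall)["overall"]
        assert (a.tp, a.fp, a.tn, a.fn) == (b.fn, b.tn, b.fp, b.tp)
        # flipping every actual label: TP<->FP, TN<->FN
        flip_act = [
            Comparison(c.user_id, c.qid, c.predicted, c.actual.flipped(), c.level)
            for c in cmps
        ]
        d = confusion(flip_act, GroupBy.overall)["overall"]
        assert (a.tp, a.fp, a.tn, a.fn) == (d.fp, d.tp, d.fn, d.tn)

    def test_concordance_table_sorted_by_total(self):
        cmps = [Comparison("u", 9, POS, POS, ComparisonLevel.ANNOTATION)] * 3 + [
            Comparison("u", 22, POS, POS, ComparisonLevel.ANNOTATION)
        ]
        table = concordance_table(cmps, GroupBy.question)
        assert [r.key for r in table] == ["q9", "q22"]
        assert table[0].total_annotations == 3


class TestUserSummaries:
    def test_user_accuracy(self):
        cmps = [
            Comparison("u1", 9, POS, POS, ComparisonLevel.USER),
            Comparison("u1", 22, NEG, NEG, ComparisonLevel.USER),
            Comparison("u1", 13, POS, NEG, ComparisonLevel.USER),
            Comparison("u2", 9, POS, POS, ComparisonLevel.USER),
            Comparison("u2", 22, NEG, POS, ComparisonLevel.USER),
        ]
        acc, mean, sd = user_accuracy_summary(cmps)
        assert acc["u1"] == pytest.approx(2 / 3)
        assert acc["u2"] == pytest.approx(0.5)
        assert mean == pytest.approx((2 / 3 + 0.5) / 2)

    def test_single_user_sd_zero(self):
        cmps = [Comparison("u1", 9, POS, POS, ComparisonLevel.USER)]
        _, mean, sd = user_accuracy_summary(cmps)
        assert (mean, sd) == (1.0, 0.0)

    def test_mean_sd_two_values(self):
        mean, sd = mean_sd([1.0, 0.5])
        assert mean == pytest.approx(0.75)
        assert sd == pytest.approx(np.std([1.0, 0.5], ddof=1))

    def test_question_coverage(self, tiny_corpus):
        cov, mean, _ = question_coverage(tiny_corpus)
        assert cov["alice"] == pytest.approx(2 / 53)  # q9 and q22
        assert cov["bob"] == pytest.approx(1 / 53)
        assert mean == pytest.approx((2 / 53 + 1 / 53) / 2)

    def test_user_without_annotations_excluded(self, tiny_corpus):
        tiny_corpus.annotations = [
            a for a in tiny_corpus.annotations if a.doc_id != "d2"
        ]
        cov, _, _ = question_coverage(tiny_corpus)
        assert "bob" not in cov
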