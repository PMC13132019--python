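"""Synthetic patient cohort generator.

The study data this pipeline is designed for — forum posts of patients
with breast cancer, expert span annotations, and each patient's EORTC
QLQ-C30/BR23 answers — are private.  This module generates corpora with
the statistical structure the analysis assumes, so every pipeline stage is
testable end to end:

* a latent binary QoL state per (user, question) drives *both* the survey
  answer and what the user writes in the forum;
* posts per user follow a long-tailed bin distribution (a few very active
  users, many occasional ones);
* per-question mention rates are heavily skewed, with a handful of
  questions (feeling ill/unwell, worry, pain, tension) dominating;
* a tunable ``consistency`` c is the probability that what a user writes
  matches their latent state, and ``survey_noise`` s the probability the
  survey answer contradicts it — giving the closed-form annotation-level
  accuracy c(1-s) + (1-c)s against which recovery is tested;
* 2-3 imperfect annotators (span recall < 1, spurious spans, polarity
  flips, boundary jitter) code the documents of the last ``period_months``,
  with the full 3-rater panel only on the most recent ``recent_months`` —
  mirroring a staged annotation campaign.

Text is template-based with exactly one sentence per mentioned issue, so
span offsets are well-defined and word-level unitization is meaningful;
realistic language is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import catalog
from .corpus import (
    Corpus,
    DocumentFlags,
    ForumDocument,
    Polarity,
    SpanAnnotation,
    SurveyRecord,
)

__all__ = [
    "AnnotatorSpec",
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "expected_accuracy",
    "summarize_cohort",
    "POSTS_PER_USER_BINS",
]

# Long-tail bins for total posts+comments per posting user:
# (low, high, weight); weights follow the observed study distribution
# 1:6, 2-10:28, 11-100:63, 101-1000:22, >1000:4 (top bin capped at 3000).
POSTS_PER_USER_BINS: tuple[tuple[int, int, float], ...] = (
    (1, 1, 6.0),
    (2, 10, 28.0),
    (11, 100, 63.0),
    (101, 1000, 22.0),
    (1001, 3000, 4.0),
)

# Target per-document marginal probability that a question is mentioned,
# matching the observed label skew: the fallback "feel ill or unwell" item
# (36) dominates, followed by worry/pain/tension; three intimate questions
# (sexual functioning/enjoyment, 44-46) are never discussed.
_TOP_MENTION_MARGINALS: dict[int, float] = {
    36: 0.110,
    22: 0.039,
    9: 0.037,
    21: 0.031,
    6: 0.028,
    18: 0.020,
    14: 0.019,
    43: 0.015,
    13: 0.012,
    24: 0.012,
}
_NEVER_MENTIONED: frozenset[int] = frozenset({44, 45, 46})


def default_mention_marginals() -> dict[int, float]:
    """Per-document marginal mention probability per question (skewed)."""
    marginals = dict(_TOP_MENTION_MARGINALS)
    rest = [
        q
        for q in catalog.ALL_QIDS
        if q not in marginals and q not in _NEVER_MENTIONED
    ]
    for k, q in enumerate(rest):
        marginals[q] = 0.004 * 0.9**k
    for q in _NEVER_MENTIONED:
        marginals[q] = 0.0
    return marginals


class AnnotatorSpec(BaseModel):
    model_config = {"frozen": True}

    annotator_id: str
    span_recall: float = Field(default=0.85, ge=0.0, le=1.0)
    false_span_rate: float = Field(default=0.03, ge=0.0)  # spurious spans per doc
    polarity_flip_prob: float = Field(default=0.02, ge=0.0, le=1.0)
    boundary_jitter_tokens: int = Field(default=1, ge=0)


def _default_annotators() -> list[AnnotatorSpec]:
    return [AnnotatorSpec(annotator_id=a) for a in ("A1", "A2", "A3")]


class SimConfig(BaseModel):
    """All parameters of the synthetic cohort (probabilities in [0, 1])."""

    n_users: int = Field(default=134, ge=1)
    period_months: int = Field(default=24, ge=1)  # annotated pre-survey window
    recent_months: int = Field(default=6, ge=0)  # full-panel + past-flag stratum
    history_months: int = Field(default=216, ge=1)  # forum history span
    p_zero_posts: float = Field(default=11 / 134, ge=0.0, le=1.0)
    posts_per_user_bins: tuple[tuple[int, int, float], ...] = POSTS_PER_USER_BINS
    p_post: float = Field(default=0.04, ge=0.0, le=1.0)  # vs. comment
    prevalence: dict[int, float] = Field(
        default_factory=lambda: {q: 0.35 for q in catalog.ALL_QIDS}
    )
    mention_marginal: dict[int, float] = Field(default_factory=default_mention_marginals)
    absent_mention_scale: float = Field(default=0.25, ge=0.0, le=1.0)
    consistency: float = Field(default=0.85, ge=0.0, le=1.0)
    survey_noise: float = Field(default=0.05, ge=0.0, le=1.0)
    annotators: list[AnnotatorSpec] = Field(default_factory=_default_annotators)
    recent_panel_size: int = Field(default=3, ge=0)
    older_panel_size: int = Field(default=2, ge=0)
    past_ref_prob: float = Field(default=0.10, ge=0.0, le=1.0)
    other_subject_prob: float = Field(default=14 / 2683, ge=0.0, le=1.0)
    survey_end: date = date(2024, 6, 30)
    survey_span_days: int = Field(default=45, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for name in ("prevalence", "mention_marginal"):
            table = getattr(self, name)
            for q, p in table.items():
                if q not in catalog.ALL_QIDS:
                    raise ValueError(f"{name}: invalid qid {q}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{q}]={p} outside [0, 1]")
        if self.recent_panel_size > len(self.annotators):
            raise ValueError("recent_panel_size exceeds number of annotators")
        if self.older_panel_size > len(self.annotators):
            raise ValueError("older_panel_size exceeds number of annotators")
        for lo, hi, w in self.posts_per_user_bins:
            if lo < 1 or hi < lo or w < 0:
                raise ValueError(f"invalid posts-per-user bin ({lo}, {hi}, {w})")
        return self

    def mention_prob(self, qid: int, present: bool) -> float:
        """Per-document mention probability conditional on the latent state,
        chosen so the marginal over the latent distribution hits
        ``mention_marginal[qid]``."""
        t = self.mention_marginal.get(qid, 0.0)
        p = self.prevalence.get(qid, 0.0)
        denom = p + (1.0 - p) * self.absent_mention_scale
        if denom <= 0.0:
            return 0.0
        m = min(1.0, t / denom)
        return m if present else m * self.absent_mention_scale


@dataclass
class GroundTruth:
    """Latent per-user states and the oracle annotator's exact spans."""

    latent_state: dict[str, dict[int, Polarity]] = field(default_factory=dict)
    true_spans: list[SpanAnnotation] = field(default_factory=list)


# --- template text -------------------------------------------------------

_TOPIC: dict[int, str] = {
    1: "strenuous activities like carrying heavy shopping bags",
    2: "long walks",
    3: "short walks outside the house",
    4: "having to stay in bed during the day",
    5: "eating, dressing and washing without help",
    6: "my work and daily activities",
    7: "my hobbies and leisure activities",
    8: "shortness of breath",
    9: "pain",
    10: "needing to rest all the time",
    11: "sleeping at night",
    12: "feeling weak",
    13: "my appetite",
    14: "nausea",
    15: "vomiting",
    16: "constipation",
    17: "diarrhea",
    18: "tiredness",
    19: "pain getting in the way of my daily activities",
    20: "concentrating on reading or television",
    21: "feeling tense",
    22: "worrying",
    23: "feeling irritable",
    24: "feeling depressed",
    25: "remembering things",
    26: "my family life because of the treatment",
    27: "my social activities because of the treatment",
    28: "financial difficulties caused by the treatment",
    29: "my overall health this week",
    30: "my overall quality of life this week",
    31: "a dry mouth",
    32: "food and drink tasting different than usual",
    33: "painful or watery eyes",
    34: "losing my hair",
    35: "being upset about losing my hair",
    36: "feeling ill or unwell",
    37: "hot flushes",
    38: "headaches",
    39: "feeling physically less attractive",
    40: "feeling less feminine",
    41: "looking at myself naked",
    42: "being dissatisfied with my body",
    43: "worrying about my health in the future",
    44: "interest in sex",
    45: "being sexually active",
    46: "enjoying sex",
    47: "pain in my arm and shoulder",
    48: "a swollen arm and hand",
    49: "raising my arm or moving it sideways",
    50: "pain in the area of my affected breast",
    51: "swelling in the area of my affected breast",
    52: "oversensitivity in the area of my affected breast",
    53: "skin problems in the area of my affected breast",
}

_POS_TEMPLATES = (
    "I have been having real trouble with {topic} lately.",
    "This week {topic} has been a big problem for me again.",
)
_NEG_TEMPLATES = (
    "I have had no trouble with {topic} at all lately.",
    "Thankfully {topic} has not been a problem for me this week.",
)

_FILLERS = (
    "Thanks everyone for the kind words.",
    "My oncologist scheduled another scan for next month.",
    "Sending hugs to all of you.",
    "Has anyone here tried the new support group?",
    "The weather has been lovely around here.",
    "I started a new book over the weekend.",
    "My daughter came to visit over the holidays.",
    "Wishing everyone a calm week ahead.",
    "I finally got around to cleaning up the garden.",
    "We celebrated a small anniversary at home.",
)


def _mention_sentence(rng: np.random.Generator, qid: int, polarity: Polarity) -> str:
    pool = _POS_TEMPLATES if polarity is Polarity.POSITIVE else _NEG_TEMPLATES
    return pool[int(rng.integers(len(pool)))].format(topic=_TOPIC[qid])


def _survey_answer(
    rng: np.random.Generator, qid: int, present: bool, noise: float
) -> int:
    """Draw an ordinal answer consistent with the latent state, flipped to
    the other side of the binarization threshold with probability ``noise``."""
    side_present = present if rng.random() >= noise else not present
    n_levels = catalog.get_question(qid).n_levels
    if n_levels == 7:
        return int(rng.integers(1, 5)) if side_present else int(rng.integers(5, 8))
    return int(rng.integers(2, 5)) if side_present else 1


def _jitter_span(
    rng: np.random.Generator,
    tokens: list[tuple[int, int]],
    start: int,
    end: int,
    jitter: int,
) -> tuple[int, int]:
    """Move span boundaries by up to ``jitter`` whole tokens."""
    if jitter <= 0 or not tokens:
        return start, end
    idx_start = next(
        (i for i, (s, e) in enumerate(tokens) if e > start), 0
    )
    idx_end = next(
        (i for i in range(len(tokens) - 1, -1, -1) if tokens[i][0] < end),
        len(tokens) - 1,
    )
    j_start = idx_start + int(rng.integers(-jitter, jitter + 1))
    j_end = idx_end + int(rng.integers(-jitter, jitter + 1))
    j_start = max(0, min(j_start, len(tokens) - 1))
    j_end = max(j_start, min(j_end, len(tokens) - 1))
    return tokens[j_start][0], tokens[j_end][1]


def _draw_post_count(rng: np.random.Generator, config: SimConfig) -> int:
    if rng.random() < config.p_zero_posts:
        return 0
    weights = np.array([w for _, _, w in config.posts_per_user_bins], dtype=float)
    weights /= weights.sum()
    lo, hi, _ = config.posts_per_user_bins[int(rng.choice(len(weights), p=weights))]
    # log-uniform within the bin reproduces the long tail inside wide bins
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi + 1)))))


def generate_cohort(config: SimConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a full corpus (documents, annotations, flags, surveys) plus
    the generating ground truth.  Deterministic given ``config.seed``."""
    from .agreement import tokenize  # local import to avoid cycle at import time

    rng = np.random.default_rng(config.seed)
    corpus = Corpus()
    truth = GroundTruth()

    qids = np.array(catalog.ALL_QIDS)
    prev_vec = np.array([config.prevalence.get(int(q), 0.0) for q in qids])
    history_days = int(config.history_months * 30.44)
    annotator_specs = list(config.annotators)

    for u in range(config.n_users):
        user_id = f"u{u + 1:04d}"
        survey_date = config.survey_end - timedelta(
            days=int(rng.integers(0, config.survey_span_days + 1))
        )
        latent = rng.random(len(qids)) < prev_vec
        truth.latent_state[user_id] = {
            int(q): (Polarity.POSITIVE if present else Polarity.NEGATIVE)
            for q, present in zip(qids, latent)
        }
        answers = {
            int(q): _survey_answer(rng, int(q), bool(p), config.survey_noise)
            for q, p in zip(qids, latent)
        }
        corpus.surveys[user_id] = SurveyRecord(
            user_id=user_id, survey_date=survey_date, answers=answers
        )

        # per-user conditional mention probabilities per document
        p_mention = np.array(
            [
                config.mention_prob(int(q), bool(present))
                for q, present in zip(qids, latent)
            ]
        )
        n_docs = _draw_post_count(rng, config)
        if n_docs == 0:
            continue
        annotated_start = (
            pd.Timestamp(survey_date) - pd.DateOffset(months=config.period_months)
        ).date()
        recent_start = (
            pd.Timestamp(survey_date) - pd.DateOffset(months=config.recent_months)
        ).date()
        mention_draws = rng.random((n_docs, len(qids))) < p_mention

        for d in range(n_docs):
            doc_id = f"{user_id}-d{d + 1:05d}"
            timestamp = survey_date - timedelta(days=int(rng.integers(0, history_days)))
            doc_type = "post" if rng.random() < config.p_post else "comment"

            mentioned = [int(q) for q in qids[mention_draws[d]]]
            mentions: list[tuple[int, Polarity, str]] = []
            for q in mentioned:
                pol = truth.latent_state[user_id][q]
                if rng.random() >= config.consistency:
                    pol = pol.flipped()
                mentions.append((q, pol, _mention_sentence(rng, q, pol)))

            # geometric filler count gives ~400-character documents with a
            # long length tail, matching typical forum-post lengths
            n_fill = min(40, int(rng.geometric(0.11)))
            fillers = [str(f) for f in rng.choice(_FILLERS, size=n_fill)]
            parts: list[tuple[Optional[int], Optional[Polarity], str]] = [
                (None, None, s) for s in fillers
            ] + [(q, pol, s) for q, pol, s in mentions]
            order = rng.permutation(len(parts))
            text_parts, mention_spans = [], []
            offset = 0
            for i in order:
                q, pol, sentence = parts[i]
                if offset:
                    offset += 1  # joining space
                if q is not None:
                    mention_spans.append((q, pol, offset, offset + len(sentence)))
                text_parts.append(sentence)
                offset += len(sentence)
            text = " ".join(text_parts)

            in_window = annotated_start <= timestamp <= survey_date
            is_recent = recent_start <= timestamp <= survey_date
            if in_window:
                panel_size = (
                    config.recent_panel_size if is_recent else config.older_panel_size
                )
                panel = tuple(spec.annotator_id for spec in annotator_specs[:panel_size])
            else:
                panel = ()

            corpus.documents[doc_id] = ForumDocument(
                doc_id=doc_id,
                user_id=user_id,
                timestamp=timestamp,
                doc_type=doc_type,
                text=text,
                annotators=panel,
            )

            for q, pol, s, e in mention_spans:
                truth.true_spans.append(
                    SpanAnnotation(
                        doc_id=doc_id,
                        annotator_id="oracle",
                        qid=q,
                        start=s,
                        end=e,
                        polarity=pol,
                    )
                )

            if in_window and panel:
                tokens = tokenize(text)
                for spec in annotator_specs[: len(panel)]:
                    for q, pol, s, e in mention_spans:
                        if rng.random() >= spec.span_recall:
                            continue
                        ann_pol = (
                            pol.flipped()
                            if rng.random() < spec.polarity_flip_prob
                            else pol
                        )
                        js, je = _jitter_span(
                            rng, tokens, s, e, spec.boundary_jitter_tokens
                        )
                        corpus.annotations.append(
                            SpanAnnotation(
                                doc_id=doc_id,
                                annotator_id=spec.annotator_id,
                                qid=q,
                                start=js,
                                end=je,
                                polarity=ann_pol,
                                exact_match=bool(rng.random() < 0.6),
                            )
                        )
                    for _ in range(int(rng.poisson(spec.false_span_rate))):
                        ts = int(rng.integers(0, len(tokens)))
                        te = min(len(tokens), ts + 1 + int(rng.integers(0, 5)))
                        corpus.annotations.append(
                            SpanAnnotation(
                                doc_id=doc_id,
                                annotator_id=spec.annotator_id,
                                qid=int(rng.integers(1, 54)),
                                start=tokens[ts][0],
                                end=tokens[te - 1][1],
                                polarity=Polarity.POSITIVE
                                if rng.random() < 0.5
                                else Polarity.NEGATIVE,
                                exact_match=False,
                            )
                        )

            refers_to_past = bool(is_recent and rng.random() < config.past_ref_prob)
            subject_is_self = not (rng.random() < config.other_subject_prob)
            if refers_to_past or not subject_is_self:
                corpus.flags[doc_id] = DocumentFlags(
                    doc_id=doc_id,
                    refers_to_past=refers_to_past,
                    subject_is_self=subject_is_self,
                )

    corpus.validate_links()
    return corpus, truth


def expected_accuracy(config: SimConfig) -> float:
    """Closed-form annotation-level accuracy for noise-free annotators.

    The annotation polarity matches the latent state with probability c
    (``consistency``); the binarized survey answer matches it with
    probability 1 - s (``survey_noise``).  They agree with probability
    c(1-s) + (1-c)s.  Annotator polarity flips or spurious spans break the
    closed form, so configs using them are rejected.
    """
    for spec in config.annotators:
        if spec.polarity_flip_prob > 0:
            raise ValueError(
                "expected_accuracy requires polarity_flip_prob = 0 for all annotators"
            )
        if spec.false_span_rate > 0:
            raise ValueError(
                "expected_accuracy requires false_span_rate = 0 for all annotators"
            )
    c, s = config.consistency, config.survey_noise
    return c * (1.0 - s) + (1.0 - c) * s


_BIN_LABELS = ("1", "2-10", "11-100", "101-1000", ">1000")


def summarize_cohort(corpus: Corpus) -> dict:
    """Descriptive report: posts-per-user long-tail bins, labeled-document
    fraction, post length mean/SD, and per-question label frequencies."""
    per_user: dict[str, int] = {}
    lengths = []
    for doc in corpus.documents.values():
        per_user[doc.user_id] = per_user.get(doc.user_id, 0) + 1
        lengths.append(len(doc.text))

    bins = {label: 0 for label in _BIN_LABELS}
    for n in per_user.values():
        if n == 1:
            bins["1"] += 1
        elif n <= 10:
            bins["2-10"] += 1
        elif n <= 100:
            bins["11-100"] += 1
        elif n <= 1000:
            bins["101-1000"] += 1
        else:
            bins[">1000"] += 1

    labeled_docs = corpus.annotated_doc_ids() & set(corpus.documents)
    n_docs = len(corpus.documents)
    label_doc_counts = {q: 0 for q in catalog.ALL_QIDS}
    seen: set[tuple[str, int]] = set()
    for ann in corpus.annotations:
        if ann.doc_id in corpus.documents and (ann.doc_id, ann.qid) not in seen:
            seen.add((ann.doc_id, ann.qid))
            label_doc_counts[ann.qid] += 1

    arr = np.asarray(lengths, dtype=float)
    return {
        "n_users_posting": len(per_user),
        "n_documents": n_docs,
        "posts_per_user_bins": bins,
        "labeled_fraction": (len(labeled_docs) / n_docs) if n_docs else 0.0,
        "post_length_mean": float(arr.mean()) if n_docs else float("nan"),
        "post_length_sd": float(arr.std(ddof=1)) if n_docs > 1 else 0.0,
        "label_doc_counts": label_doc_counts,
    }
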