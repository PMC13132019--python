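# Methods

This note documents the statistical procedures `forumqol` implements, the
assumptions behind the synthetic cohort generator, and the numerical and
design choices made where more than one reasonable convention exists.

## The analysis

The pipeline quantifies how well QoL information annotated in a user's
online forum posts predicts that user's answers to the EORTC QLQ-C30 and
QLQ-BR23 questionnaires.  Its stages, in order:

1. **Subject exclusion.**  Documents whose QoL content refers to someone
   other than the posting user (`subject_is_self = false`) are annotated
   but removed from every statistics-facing view; the count is logged.
2. **Temporal windowing.**  Only documents with
   `survey_date − m months ≤ timestamp ≤ survey_date` (per user, calendar
   months via pandas `DateOffset`) enter an *m*-month analysis; the window
   is anchored on each user's survey date.  Optionally, documents flagged
   as referring to past events are also dropped — the questionnaires ask
   about the last week, so an old anecdote inside the window can still
   misalign with the survey's recall period.
3. **Agreement.**  Per question, span annotations are unitized to rating
   items (see below) and Fleiss' κ (1971) is computed over the two
   categories *labeled* / *unlabeled*, ignoring polarity and exact-match
   attributes.
4. **Concordance.**  Each annotation's polarity (positive = issue present)
   is compared with the binarized survey answer of the same user and
   question, yielding TP/FP/TN/FN, precision, recall and F1 — per
   question, micro-pooled over fine or coarse question groups, or overall.
5. **Per-user summaries.**  Per-user answer accuracy `(TP+TN)/total` over
   the user's contributing questions, and per-user question coverage (the
   fraction of the 53 items with at least one annotation), each with an
   unweighted mean and sample SD (ddof = 1; SD of a single value is
   reported as 0).

## Binarization

4-level items: answer 1 ("not at all") → negative; 2–4 ("a little",
"quite a bit", "very much") → positive.  The two 7-level global items
(29, 30) need an extra convention: answers ≤ 4 are treated as positive
(impaired global health/QoL), 5–7 as negative.  The midpoint is a
documented choice (`concordance.SEVEN_LEVEL_POSITIVE_MAX`); these items
are rarely annotated, so any monotone threshold would serve.

## Unitization and Fleiss κ

* **Word units**: one item per whitespace-delimited token (punctuation
  stays attached); a rater labels the token iff one of their spans for the
  question overlaps the token's character range by at least one code
  point.  Partial-overlap credit matches span-based annotation practice;
  exact token-boundary agreement would punish one-character offset
  differences that carry no meaning.
* **Post units**: one item per document, labeled iff the rater placed any
  span for the question in it.
* **Panels.**  Fleiss' formula assumes a constant number of raters per
  item, but annotation campaigns are often staged (here: three annotators
  on the most recent six months, two on the older material).  κ is
  therefore computed per homogeneous stratum: the caller names an explicit
  panel, and documents not covered by the full panel are excluded with a
  logged count.  Coverage is carried on each document (`annotators`
  field); when unknown it is assumed complete.
* **Degenerate case.**  When every rating falls in one category,
  `1 − P̄e = 0` while observed agreement is perfect; κ is reported as 1.0
  with a `degenerate` flag rather than NaN, so tables stay numeric without
  losing the information.  Negative κ values are reported as computed,
  never clamped.

## Grouping and metric conventions

* Fine groups are the 23 EORTC scale-based clusters; coarse groups are
  functional (items 1–7, 20–27, 39–46), symptomatic (8–19, 28, 31–38,
  47–53) and global (29, 30).  Group pooling is micro-pooling: confusion
  counts are summed over member questions before metrics are computed, so
  totals are conserved across any partition.
* Precision, recall and F1 are undefined (reported blank, excluded from
  averages) when their denominators vanish; F1 is 0 when TP = 0 but
  FP + FN > 0.
* Two comparison levels are first-class.  ANNOTATION level counts every
  span annotation as one instance (what the per-question result tables
  total).  USER level first aggregates each user's annotation polarities
  per question by majority vote, ties going to positive — the annotation
  schema is presence-biased, the unmarked base label denoting presence —
  then contributes one instance per (user, question).  A user with no
  labeled data for a question contributes nothing for it.

## EORTC scale scoring

Raw score `RS` = mean of answered items; with item range `r = n_levels−1`,
functional scales score `(1 − (RS−1)/r)·100` and symptom/global scales
`((RS−1)/r)·100`.  A score is missing when fewer than `ceil(k/2)` of a
`k`-item scale's items are answered.  One deliberate simplification: the
BR23 sexual-functioning and sexual-enjoyment scales are scored with the
uniform functional (reversed) formula, keeping every functional score
antitone in its items; the official manual scores those two scales in the
non-reversed direction.  This affects only the 0–100 scale scores, never
the binarized concordance analysis, which uses raw answers.

## The synthetic cohort generator

Real data of this kind — patients' forum histories linked to their own
questionnaire answers — are inherently private, so the generator produces
cohorts with the statistical structure the analysis assumes:

* **Latent states.**  Each (user, question) pair has a latent binary state
  drawn with per-question prevalence (default 0.35), static over the
  simulated period.  The state drives *both* data sources, which is
  exactly the premise the concordance analysis tests.
* **Surveys.**  The answer lands on the latent side of the binarization
  threshold with probability `1 − survey_noise` (default 0.95): present →
  uniform over {2, 3, 4} (4-level) or {1..4} (7-level); absent → 1 or
  uniform {5..7}.
* **Posting behavior.**  134 users by default, 11/134 never posting;
  posts-per-user drawn from long-tail bins (1 : 6, 2–10 : 28, 11–100 : 63,
  101–1000 : 22, >1000 : 4 users, log-uniform within bins, top bin capped
  at 3000), timestamps uniform over 216 months of history.  Only the 24
  months before each user's survey are annotated — three annotators for
  the final 6 months, two for the rest — leaving roughly 2,000–2,500
  annotated documents per cohort.
* **Text and mentions.**  Documents are filler sentences (geometric count,
  giving a mean length near 400 characters with a long tail) plus at most
  one template sentence per mentioned question, so spans are exact and
  word unitization meaningful.  Realistic language is a non-goal.  A
  present issue is mentioned per document with probability chosen so the
  *marginal* per-document mention rate matches a skewed target: ~11% for
  the dominant fallback item ("Did you feel ill or unwell?"), 1–4% for the
  next nine, a decaying tail elsewhere, and zero for the three intimate
  sexuality items — reproducing the top-heavy label distribution and a
  labeled-document fraction around one quarter to one third.  Absent
  issues are mentioned (negatively) at `absent_mention_scale` (default
  0.25) times the present-issue rate.
* **Consistency.**  A mention's polarity matches the latent state with
  probability `c` (default 0.85).  For noise-free annotators the
  annotation-level accuracy has the closed form `c(1−s) + (1−c)s`
  (`expected_accuracy`), the oracle used in recovery tests; configurations
  with annotator polarity flips or spurious spans are rejected there
  because they break the closed form.
* **Annotators.**  Each panel member reproduces a mention's span with
  probability `span_recall` (0.85), flips its polarity with probability
  0.02, jitters boundaries by up to one token, and adds spurious spans at
  0.03 per document.  Past-reference flags are drawn (p = 0.10) only for
  the recent 6-month stratum, mirroring when that labeling happens;
  other-subject flags at ~0.5%.

What passing tests on these cohorts shows — and what it does not: the
pipeline's arithmetic is correct, its filters are exact, and the
concordance statistics recover a known generating consistency.  It does
not show that real forum language can be annotated at any particular
agreement level, nor what concordance real patients exhibit: the generator
has no vague wording, no interpretation ambiguity (so κ is driven only by
span recall and jitter), no temporal drift of the latent state, and no
correlation between posting frequency and health state.

## Problem sizes and reproducibility

All randomness flows from one seeded `numpy` generator; equal
configurations produce byte-identical corpora and report bundles.  The
test suite runs cohorts of 30–150 users; parameter-recovery checks use 150
users with flat mention rates (≈ 10,000+ annotation-level comparisons) for
tight Monte-Carlo error, and the report-determinism check uses the default
study-scale configuration.  `scripts/acceptance.py` runs the default
configuration and reports labeled fractions, mean κ, mean F1 per grouping,
user accuracy and question coverage, every value recomputed at run time
from the seed given on the command line.
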