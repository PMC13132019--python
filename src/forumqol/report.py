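"""End-to-end orchestration and paper-style report tables.

``run_pipeline`` executes the full analysis on a corpus (read from disk or
simulated): other-subject exclusion, temporal windowing, per-question
agreement, annotation-survey concordance at question / fine-group /
coarse-group granularity, and descriptive statistics.  It writes one CSV
per report table plus a JSON manifest, and is byte-reproducible for a
fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__, catalog
from .agreement import UnitKind, agreement_table
from .concordance import (
    ComparisonLevel,
    GroupBy,
    build_comparisons,
    concordance_table,
    filter_window,
    mean_sd,
    question_coverage,
    user_accuracy_summary,
)
from .corpus import Corpus, exclude_other_subject, read_corpus
from .synthetic import SimConfig, generate_cohort, summarize_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "label_frequency_table", "labeled_fraction"]


class RunConfig(BaseModel):
    """Configuration of a full pipeline run.

    Exactly one of ``input_dir`` (a corpus directory) or ``sim`` (a
    synthetic-cohort configuration) must be provided.
    """

    input_dir: Optional[Path] = None
    sim: Optional[SimConfig] = None
    months_short: int = Field(default=6, ge=1)
    months_long: int = Field(default=24, ge=1)
    exclude_past_refs: bool = True
    level: ComparisonLevel = ComparisonLevel.ANNOTATION
    panel: Optional[list[str]] = None  # None: infer the largest observed panel
    out_dir: Path = Path("reports")
    seed: Optional[int] = None  # overrides sim.seed when set

    def load_corpus(self) -> Corpus:
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("provide exactly one of input_dir or sim")
        if self.input_dir is not None:
            return read_corpus(self.input_dir)
        sim = self.sim
        if self.seed is not None:
            sim = sim.model_copy(update={"seed": self.seed})
        corpus, _ = generate_cohort(sim)
        return corpus


def labeled_fraction(corpus: Corpus) -> float:
    """Fraction of documents in the view carrying at least one QoL label."""
    n_docs = len(corpus.documents)
    if n_docs == 0:
        return 0.0
    return len(corpus.annotated_doc_ids() & set(corpus.documents)) / n_docs


def label_frequency_table(
    corpus: Corpus, top_n: Optional[int] = None
) -> pd.DataFrame:
    """Per-question label frequencies over a corpus view.

    Columns: qid, question, n_docs (documents with >=1 annotation for the
    question), pct_docs (relative to all documents in the view), n_users
    (users with >=1 such document), pct_users (relative to all users
    posting in the view).  Rows ordered by (n_docs desc, qid asc).
    """
    n_docs_total = len(corpus.documents)
    posting_users = {doc.user_id for doc in corpus.documents.values()}
    docs_by_q: dict[int, set[str]] = {}
    users_by_q: dict[int, set[str]] = {}
    for ann in corpus.annotations:
        doc = corpus.documents.get(ann.doc_id)
        if doc is None:
            continue
        docs_by_q.setdefault(ann.qid, set()).add(ann.doc_id)
        users_by_q.setdefault(ann.qid, set()).add(doc.user_id)

    rows = []
    for qid in sorted(docs_by_q):
        nd, nu = len(docs_by_q[qid]), len(users_by_q[qid])
        rows.append(
            {
                "qid": qid,
                "question": catalog.get_question(qid).text,
                "n_docs": nd,
                "pct_docs": round(100.0 * nd / n_docs_total, 1) if n_docs_total else 0.0,
                "n_users": nu,
                "pct_users": round(100.0 * nu / len(posting_users), 1)
                if posting_users
                else 0.0,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["qid", "question", "n_docs", "pct_docs", "n_users", "pct_users"]
    )
    frame = frame.sort_values(
        ["n_docs", "qid"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        frame = frame.head(top_n)
    return frame


def _infer_panel(corpus: Corpus) -> list[str]:
    best: tuple[str, ...] = ()
    for doc in corpus.documents.values():
        if doc.annotators and len(doc.annotators) > len(best):
            best = doc.annotators
    if len(best) < 2:
        raise ValueError("cannot infer an annotator panel of size >= 2")
    return list(best)


def _fmt(x: Optional[float], digits: int = 4) -> str:
    return "" if x is None else f"{x:.{digits}f}"


def _concordance_frame(results_by_window: dict[str, list]) -> pd.DataFrame:
    """Merge per-window concordance tables into a Table-6/7-style frame."""
    keys: list[str] = []
    for results in results_by_window.values():
        for r in results:
            if r.key not in keys:
                keys.append(r.key)
    rows = []
    for key in keys:
        row: dict[str, object] = {"key": key}
        for window, results in results_by_window.items():
            match = next((r for r in results if r.key == key), None)
            if match is None:
                row.update(
                    {
                        f"f1_{window}": "",
                        f"precision_{window}": "",
                        f"recall_{window}": "",
                        f"tp_{window}": 0,
                        f"fp_{window}": 0,
                        f"tn_{window}": 0,
                        f"fn_{window}": 0,
                        f"total_annotations_{window}": 0,
                    }
                )
            else:
                row.update(
                    {
                        f"f1_{window}": _fmt(match.f1),
                        f"precision_{window}": _fmt(match.precision),
                        f"recall_{window}": _fmt(match.recall),
                        f"tp_{window}": match.counts.tp,
                        f"fp_{window}": match.counts.fp,
                        f"tn_{window}": match.counts.tn,
                        f"fn_{window}": match.counts.fn,
                        f"total_annotations_{window}": match.total_annotations,
                    }
                )
        rows.append(row)
    frame = pd.DataFrame(rows)
    last_total = [c for c in frame.columns if c.startswith("total_annotations_")]
    if last_total:
        frame = frame.sort_values(
            [last_total[0], "key"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return frame


def _f1_summary(results) -> dict[str, float | int]:
    defined = [r.f1 for r in results if r.f1 is not None]
    if not defined:
        return {"n_keys": len(results), "n_defined": 0}
    mean, sd = mean_sd(defined)
    return {
        "n_keys": len(results),
        "n_defined": len(defined),
        "mean_f1": round(mean, 4),
        "sd_f1": round(sd, 4),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to
    ``config.out_dir``.  Returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    full = _stage("load_corpus", config.load_corpus)
    evaluable = _stage("exclude_other_subject", exclude_other_subject, full)
    n_excluded = len(full.documents) - len(evaluable.documents)

    short, long_ = config.months_short, config.months_long
    view_long_raw = _stage("filter_window", filter_window, evaluable, long_, False)
    view_short_raw = _stage("filter_window", filter_window, evaluable, short, False)
    view_long = _stage(
        "filter_window", filter_window, evaluable, long_, config.exclude_past_refs
    )
    view_short = _stage(
        "filter_window", filter_window, evaluable, short, config.exclude_past_refs
    )

    # Table 2 style: posts-per-user long tail over the whole corpus
    summary = _stage("summarize_cohort", summarize_cohort, evaluable)
    pd.DataFrame(
        [
            {"posts_per_user": k, "n_users": v}
            for k, v in summary["posts_per_user_bins"].items()
        ]
    ).to_csv(out / "posts_per_user.csv", index=False)

    # Table 4 style: label frequencies over the long annotated window
    label_frequency_table(view_long_raw).to_csv(out / "label_frequency.csv", index=False)

    # Table 5 style: per-question agreement on the recent full-panel stratum
    panel = config.panel or _stage("infer_panel", _infer_panel, view_short_raw)
    agree_rows = []
    word = _stage(
        "agreement", agreement_table, view_short_raw, catalog.ALL_QIDS, UnitKind.WORD, panel
    )
    doc = _stage(
        "agreement", agreement_table, view_short_raw, catalog.ALL_QIDS, UnitKind.DOC, panel
    )
    doc_by_qid = {r.qid: r for r in doc}
    for r in word:
        agree_rows.append(
            {
                "qid": r.qid,
                "question": catalog.get_question(r.qid).text,
                "kappa_word": f"{r.kappa:.4f}",
                "kappa_doc": f"{doc_by_qid[r.qid].kappa:.4f}",
                "labeled_posts": r.n_labeled_docs,
                "degenerate": r.degenerate,
            }
        )
    pd.DataFrame(agree_rows).to_csv(out / "agreement.csv", index=False)

    # Table 6 style: per-question concordance, windows not past-filtered
    level = config.level
    cmp_short_raw = _stage("comparisons", build_comparisons, view_short_raw, level)
    cmp_long_raw = _stage("comparisons", build_comparisons, view_long_raw, level)
    by_question = {
        f"{short}mo": concordance_table(cmp_short_raw, GroupBy.question),
        f"{long_}mo": concordance_table(cmp_long_raw, GroupBy.question),
    }
    _concordance_frame(by_question).to_csv(out / "concordance_questions.csv", index=False)

    # Table 7 style: grouped concordance, past-filtered windows
    cmp_short = _stage("comparisons", build_comparisons, view_short, level)
    cmp_long = _stage("comparisons", build_comparisons, view_long, level)
    frames = []
    for granularity in (GroupBy.fine, GroupBy.coarse):
        frame = _concordance_frame(
            {
                f"{short}mo": concordance_table(cmp_short, granularity),
                f"{long_}mo": concordance_table(cmp_long, granularity),
            }
        )
        frame.insert(0, "grouping", granularity.value)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "concordance_groups.csv", index=False
    )

    # per-user summaries on the short past-filtered window
    user_cmp = build_comparisons(view_short, ComparisonLevel.USER)
    _, acc_mean, acc_sd = user_accuracy_summary(user_cmp)
    _, cov_mean, cov_sd = question_coverage(view_short)

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "counts": {
            "documents": len(full.documents),
            "documents_evaluable": len(evaluable.documents),
            "excluded_other_subject": n_excluded,
            "annotations": len(evaluable.annotations),
            "surveys": len(evaluable.surveys),
            f"documents_{short}mo": len(view_short_raw.documents),
            f"documents_{long_}mo": len(view_long_raw.documents),
            f"comparisons_{short}mo": len(cmp_short_raw),
            f"comparisons_{long_}mo": len(cmp_long_raw),
        },
        "labeled_fraction": {
            f"{short}mo": round(labeled_fraction(view_short_raw), 4),
            f"{long_}mo": round(labeled_fraction(view_long_raw), 4),
        },
        "agreement_panel": list(panel),
        "mean_kappa_word": round(
            mean_sd([r.kappa for r in word])[0], 4
        )
        if word
        else None,
        "f1_summary": {
            "question": _f1_summary(by_question[f"{short}mo"]),
            "fine": _f1_summary(concordance_table(cmp_short, GroupBy.fine)),
            "coarse": _f1_summary(concordance_table(cmp_short, GroupBy.coarse)),
        },
        "user_accuracy": {"mean": round(acc_mean, 4), "sd": round(acc_sd, 4)}
        if user_cmp
        else None,
        "question_coverage": {"mean": round(cov_mean, 4), "sd": round(cov_sd, 4)}
        if view_short.annotations
        else None,
        "post_length": {
            "mean": round(summary["post_length_mean"], 1),
            "sd": round(summary["post_length_sd"], 1),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("report bundle written to %s", out)
    return manifest
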