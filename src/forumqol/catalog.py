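"""Static knowledge about the 53 EORTC QLQ-C30 / QLQ-BR23 items.

The QLQ-C30 is the EORTC's 30-item core quality-of-life instrument for
patients with cancer; the QLQ-BR23 adds 23 breast-cancer-specific items.
Items are numbered 1-53 here (C30 = 1-30, BR23 = 31-53).  Items 1-28 and
31-53 use 4-level ordinal responses ("not at all" ... "very much"); the two
global health/QoL items 29 and 30 use 7-level responses.

This module exposes the item catalog (texts, response levels, fine and
coarse groupings) and 0-100 scale scoring following the EORTC scoring
manual conventions: for a scale with items of common range ``r = n_levels-1``
and raw score ``RS`` (mean of answered items),

* functional scales:        ``S = (1 - (RS - 1)/r) * 100``
* symptom and global scale: ``S = ((RS - 1)/r) * 100``

so higher functional scores mean better functioning and higher symptom
scores mean a heavier symptom burden.  A scale score is missing when fewer
than half of its items (rounded up) were answered.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

__all__ = [
    "Instrument",
    "CoarseGroup",
    "ScaleKind",
    "Question",
    "ScaleDefinition",
    "ALL_QIDS",
    "get_question",
    "all_questions",
    "fine_groups",
    "coarse_groups",
    "group_members",
    "get_scale",
    "all_scales",
    "scale_score",
    "score_survey",
]

ALL_QIDS = tuple(range(1, 54))


class Instrument(str, Enum):
    C30 = "C30"
    BR23 = "BR23"


class CoarseGroup(str, Enum):
    FUNCTIONAL = "FUNCTIONAL"
    SYMPTOMATIC = "SYMPTOMATIC"
    GLOBAL = "GLOBAL"


class ScaleKind(str, Enum):
    functional = "functional"
    symptom = "symptom"
    global_ = "global"


@dataclass(frozen=True)
class Question:
    qid: int
    text: str
    instrument: Instrument
    n_levels: int
    fine_group: str
    coarse_group: CoarseGroup


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    kind: ScaleKind
    item_qids: frozenset[int]
    value_range: int  # n_levels - 1, shared by all items of the scale


# Fine groups whose scale direction is functional (higher = better); all
# remaining fine groups are symptom scales except "Global health".
_FUNCTIONAL_SCALES = {
    "Physical functioning",
    "Role functioning",
    "Emotional functioning",
    "Cognitive functioning",
    "Social functioning",
    "Body image",
    "Future perspective",
    "Sexual functioning",
    "Sexual enjoyment",
}


@lru_cache(maxsize=1)
def _load_catalog() -> dict[int, Question]:
    catalog: dict[int, Question] = {}
    with resources.files("forumqol.data").joinpath("questions.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        for row in csv.DictReader(fh):
            q = Question(
                qid=int(row["qid"]),
                text=row["text"],
                instrument=Instrument(row["instrument"]),
                n_levels=int(row["n_levels"]),
                fine_group=row["fine_group"],
                coarse_group=CoarseGroup(row["coarse_group"]),
            )
            catalog[q.qid] = q
    if sorted(catalog) != list(ALL_QIDS):
        raise RuntimeError("question catalog does not cover qids 1..53")
    return catalog


def get_question(qid: int) -> Question:
    """Return the catalog entry for a question id (1-53)."""
    try:
        return _load_catalog()[int(qid)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"qid must be an integer in 1..53, got {qid!r}") from None


def all_questions() -> list[Question]:
    return [get_question(q) for q in ALL_QIDS]


@lru_cache(maxsize=1)
def fine_groups() -> dict[str, frozenset[int]]:
    """Mapping fine-group name -> member qids (a partition of 1..53)."""
    groups: dict[str, set[int]] = {}
    for q in all_questions():
        groups.setdefault(q.fine_group, set()).add(q.qid)
    return {name: frozenset(qids) for name, qids in groups.items()}


@lru_cache(maxsize=1)
def coarse_groups() -> dict[str, frozenset[int]]:
    """Mapping FUNCTIONAL/SYMPTOMATIC/GLOBAL -> member qids."""
    groups: dict[str, set[int]] = {}
    for q in all_questions():
        groups.setdefault(q.coarse_group.value, set()).add(q.qid)
    return {name: frozenset(qids) for name, qids in groups.items()}


def group_members(group_name: str, granularity: str = "fine") -> frozenset[int]:
    """Return the qid set of a fine or coarse group.

    Raises ``ValueError`` listing the valid names when the group is unknown.
    """
    if granularity == "fine":
        table = fine_groups()
    elif granularity == "coarse":
        table = coarse_groups()
    else:
        raise ValueError(f"granularity must be 'fine' or 'coarse', got {granularity!r}")
    try:
        return table[group_name]
    except KeyError:
        valid = ", ".join(sorted(table))
        raise ValueError(
            f"unknown {granularity} group {group_name!r}; valid names: {valid}"
        ) from None


def _scale_kind(fine_group: str) -> ScaleKind:
    if fine_group == "Global health":
        return ScaleKind.global_
    if fine_group in _FUNCTIONAL_SCALES:
        return ScaleKind.functional
    return ScaleKind.symptom


@lru_cache(maxsize=1)
def all_scales() -> dict[str, ScaleDefinition]:
    """Scoring scales, one per fine group (single-item measures included)."""
    scales = {}
    for name, qids in fine_groups().items():
        levels = {get_question(q).n_levels for q in qids}
        if len(levels) != 1:
            raise RuntimeError(f"scale {name!r} mixes response levels")
        scales[name] = ScaleDefinition(
            name=name,
            kind=_scale_kind(name),
            item_qids=qids,
            value_range=levels.pop() - 1,
        )
    return scales


def get_scale(name: str) -> ScaleDefinition:
    try:
        return all_scales()[name]
    except KeyError:
        valid = ", ".join(sorted(all_scales()))
        raise ValueError(f"unknown scale {name!r}; valid names: {valid}") from None


def scale_score(
    answers: Mapping[int, Optional[int]], scale: ScaleDefinition
) -> Optional[float]:
    """Score one scale to 0-100, or ``None`` when too many items are missing.

    ``answers`` maps qid -> ordinal answer (1..n_levels) or None/absent for
    missing.  At least half of the scale's items (rounded up) must be
    answered; answers outside the item's level range raise ``ValueError``.
    """
    present: list[int] = []
    for qid in scale.item_qids:
        value = answers.get(qid)
        if value is None:
            continue
        n_levels = scale.value_range + 1
        if not (1 <= value <= n_levels):
            raise ValueError(
                f"answer {value} for qid {qid} outside 1..{n_levels}"
            )
        present.append(value)
    if len(present) < math.ceil(len(scale.item_qids) / 2):
        return None
    raw = sum(present) / len(present)
    frac = (raw - 1.0) / scale.value_range
    if scale.kind is ScaleKind.functional:
        return (1.0 - frac) * 100.0
    return frac * 100.0


def score_survey(answers: Mapping[int, Optional[int]]) -> dict[str, Optional[float]]:
    """Score every scale for one respondent's answer set."""
    return {name: scale_score(answers, sc) for name, sc in sorted(all_scales().items())}
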