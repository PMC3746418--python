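"""The post-ranking filter cascade that turns a score ranking into a target list.

Walking the ranked ingroup leaves from best to worst, each leaf receives the
first applicable category:

1. its genome project is already registered elsewhere
   (``completed_elsewhere`` / ``in_progress_elsewhere`` / ``targeted_elsewhere``);
2. it belongs to a deliberately excluded group (``excluded_group``);
3. it is not held in the culture collection doing the sequencing
   (``not_in_collection``);
4. it is held but too difficult to cultivate (``technical_rejection``);
5. otherwise it is ``selected`` until the target quota is filled, then
   ``replacement`` until the replacement pool is filled, then ``postponed``.

The categories partition the ranked leaves, so the category counts always
sum to the ingroup leaf count; the selected set is exactly the
highest-ranked run of eligible leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import TableFormatError
from .matching import MatchStatus
from .scoring import ScoreTable, round_half_up
from .stats import RankedLeaf

__all__ = [
    "Category",
    "AvailabilityEntry",
    "SelectionReport",
    "select_targets",
    "category_report",
    "read_availability_tsv",
]

logger = logging.getLogger(__name__)


class Category(str, Enum):
    SELECTED = "selected"
    REPLACEMENT = "replacement"
    COMPLETED_ELSEWHERE = "completed_elsewhere"
    IN_PROGRESS_ELSEWHERE = "in_progress_elsewhere"
    TARGETED_ELSEWHERE = "targeted_elsewhere"
    NOT_IN_COLLECTION = "not_in_collection"
    EXCLUDED_GROUP = "excluded_group"
    TECHNICAL_REJECTION = "technical_rejection"
    POSTPONED = "postponed"


@dataclass(frozen=True)
class AvailabilityEntry:
    leaf: str
    in_collection: bool = True
    fastidious: bool = False
    excluded_group: bool = False


# registry statuses (either match statuses or raw project statuses) that
# mean "this genome is already covered elsewhere", and their category
_REGISTRY_CATEGORY: dict[str, Category] = {
    MatchStatus.FOUND_COMPLETE.value: Category.COMPLETED_ELSEWHERE,
    "completed": Category.COMPLETED_ELSEWHERE,
    "complete": Category.COMPLETED_ELSEWHERE,
    "in_progress": Category.IN_PROGRESS_ELSEWHERE,
    "in progress": Category.IN_PROGRESS_ELSEWHERE,
    MatchStatus.FOUND_INCOMPLETE.value: Category.TARGETED_ELSEWHERE,
    "targeted": Category.TARGETED_ELSEWHERE,
}


@dataclass(frozen=True)
class SelectionReport:
    selected: tuple[str, ...]
    replacements: tuple[str, ...]
    categories: dict[str, Category]
    counts: dict[Category, int] = field(default_factory=dict)

    def __post_init__(self):
        counts = {c: 0 for c in Category}
        for cat in self.categories.values():
            counts[cat] += 1
        object.__setattr__(self, "counts", counts)


def select_targets(
    ranking: Sequence[RankedLeaf | str],
    matches: Mapping[str, object],
    availability: Iterable[AvailabilityEntry],
    n_targets: int,
    n_replacements: int = 0,
    default_in_collection: bool = False,
) -> SelectionReport:
    """Partition a ranking into selection categories.

    ``ranking`` is the ordered ingroup ranking (best first), as produced by
    :func:`rpdselect.stats.rank_leaves` (bare labels are accepted too).
    ``matches`` maps a leaf label to its registry status — either a
    :class:`~rpdselect.matching.MatchStatus` (candidate statuses pass the
    filter) or a raw registry project status string ("completed",
    "in_progress", "targeted").  Leaves absent from ``matches`` have no
    registered project.  Leaves absent from ``availability`` default to not
    being in the collection (a strain that cannot be obtained cannot be
    sequenced); pass ``default_in_collection=True`` to flip that.
    """
    if not ranking:
        raise ValueError("ranking must be non-empty")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if n_replacements < 0:
        raise ValueError("n_replacements must be >= 0")

    avail = {a.leaf: a for a in availability}
    labels = [r.leaf if isinstance(r, RankedLeaf) else str(r) for r in ranking]
    if len(set(labels)) != len(labels):
        raise ValueError("ranking contains duplicate leaves")

    categories: dict[str, Category] = {}
    selected: list[str] = []
    replacements: list[str] = []
    for label in labels:
        status = matches.get(label)
        if status is not None:
            key = status.value if isinstance(status, MatchStatus) else str(status)
            registry_cat = _REGISTRY_CATEGORY.get(key)
            if registry_cat is not None:
                categories[label] = registry_cat
                continue
        entry = avail.get(
            label, AvailabilityEntry(leaf=label, in_collection=default_in_collection)
        )
        if entry.excluded_group:
            categories[label] = Category.EXCLUDED_GROUP
        elif not entry.in_collection:
            categories[label] = Category.NOT_IN_COLLECTION
        elif entry.fastidious:
            categories[label] = Category.TECHNICAL_REJECTION
        elif len(selected) < n_targets:
            categories[label] = Category.SELECTED
            selected.append(label)
        elif len(replacements) < n_replacements:
            categories[label] = Category.REPLACEMENT
            replacements.append(label)
        else:
            categories[label] = Category.POSTPONED
    if len(selected) < n_targets:
        logger.warning(
            "only %d eligible strains for %d requested targets", len(selected), n_targets
        )
    return SelectionReport(
        selected=tuple(selected),
        replacements=tuple(replacements),
        categories=categories,
    )


def category_report(
    report: SelectionReport,
    ranking: Sequence[RankedLeaf],
    table: Optional[ScoreTable] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-leaf category table (rank, leaf, scores, category) plus a counts summary.

    Scores are reported at 3 decimals, the usual presentation precision.
    """
    rows = []
    for r in ranking:
        score = table[r.leaf] if table is not None else None
        rows.append(
            {
                "rank": r.rank,
                "leaf": r.leaf,
                "brpd": round_half_up(score.brpd) if score else round_half_up(r.score),
                "urpd": (
                    round_half_up(score.urpd)
                    if score is not None and score.urpd is not None
                    else None
                ),
                "category": report.categories[r.leaf].value,
            }
        )
    per_leaf = pd.DataFrame(rows)
    counts = pd.DataFrame(
        {
            "category": [c.value for c in Category],
            "count": [report.counts[c] for c in Category],
        }
    )
    return per_leaf, counts


def read_availability_tsv(path) -> list[AvailabilityEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["leaf", "in_collection", "fastidious", "excluded_group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"availability table is missing column(s): {', '.join(missing)}"
        )
    return [
        AvailabilityEntry(
            leaf=row.leaf,
            in_collection=bool(int(row.in_collection)),
            fastidious=bool(int(row.fastidious)),
            excluded_group=bool(int(row.excluded_group)),
        )
        for row in df.itertuples(index=False)
    ]
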