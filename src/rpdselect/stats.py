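"""Ranking, saturation curves, correlations and cross-release stability.

These are the summary analyses a phylogeny-driven selection run needs on
top of the raw per-leaf scores: a deterministic ranking, the cumulative
saturation curve (how many top-ranked leaves capture a given fraction of
the tree's total diversity), tie-corrected Kendall correlations between
score variants, residuals of leaf height on path length, and a stability
comparison of two score tables restricted to their shared leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import RpdSelectError
from .scoring import ScoreTable

__all__ = [
    "RankedLeaf",
    "SaturationCurve",
    "StabilityReport",
    "rank_leaves",
    "saturation",
    "k_for_fraction",
    "kendall_tau",
    "height_residuals",
    "compare_releases",
]


@dataclass(frozen=True)
class RankedLeaf:
    leaf: str
    score: float
    rank: int


def _variant_scores(table: ScoreTable, by: str) -> list[tuple[str, float]]:
    if by not in ("brpd", "urpd"):
        raise ValueError(f"unknown score variant {by!r}; expected 'brpd' or 'urpd'")
    pairs = []
    for s in table.ingroup:
        value = s.brpd if by == "brpd" else s.urpd
        if value is None:
            raise RpdSelectError(
                f"variant {by!r} requested but leaf {s.leaf!r} has no such score"
            )
        pairs.append((s.leaf, value))
    return pairs


def rank_leaves(table: ScoreTable, by: str = "brpd") -> list[RankedLeaf]:
    """Ingroup leaves in decreasing score order.

    Ties are broken by ascending leaf label and receive consecutive ranks in
    that order, so the ranking (and any top-k set derived from it) is
    deterministic. Ranks are 1-based. Outgroup-flagged leaves are excluded.
    """
    pairs = _variant_scores(table, by)
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return [RankedLeaf(leaf=l, score=v, rank=i + 1) for i, (l, v) in enumerate(pairs)]


@dataclass(frozen=True)
class SaturationCurve:
    """Cumulative share of total diversity captured by the top-k leaves."""

    sorted_scores: tuple[float, ...]
    cumulative_percent: tuple[float, ...]
    total: float

    def __len__(self) -> int:
        return len(self.sorted_scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": np.arange(1, len(self.sorted_scores) + 1),
                "score": self.sorted_scores,
                "cumulative_percent": self.cumulative_percent,
            }
        )


def saturation(table: ScoreTable, by: str = "brpd") -> SaturationCurve:
    """Decreasingly sorted scores with their cumulative percentage of the total.

    The divisor is the sum of the sorted (ingroup) scores themselves, so the
    curve always ends at 100%.
    """
    ranked = rank_leaves(table, by)
    if not ranked:
        raise RpdSelectError("cannot compute a saturation curve on an empty ingroup")
    scores = np.array([r.score for r in ranked], dtype=float)
    total = float(scores.sum())
    if total <= 0:
        raise RpdSelectError("all scores are zero; cumulative percentages are undefined")
    cum = 100.0 * np.cumsum(scores) / total
    return SaturationCurve(
        sorted_scores=tuple(scores.tolist()),
        cumulative_percent=tuple(cum.tolist()),
        total=total,
    )


def k_for_fraction(curve: SaturationCurve, fraction: float) -> int:
    """Smallest k whose cumulative score sum reaches ``fraction`` of the total."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    target = 100.0 * fraction
    for i, c in enumerate(curve.cumulative_percent):
        if c >= target - 1e-12:
            return i + 1
    return len(curve.cumulative_percent)


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected) between two paired score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall correlation is undefined for a constant vector")
    tau = sps.kendalltau(x, y, variant="b").statistic
    return float(tau)


def height_residuals(table: ScoreTable) -> dict[str, float]:
    """OLS residuals of leaf height regressed on root-path branch count.

    Height and the number of branches to the root are strongly coupled; the
    residuals isolate the branch-length signal from the path-length signal.
    The fit includes an intercept, so the residuals sum to zero.
    """
    ingroup = table.ingroup
    if len(ingroup) < 3:
        raise RpdSelectError("need at least 3 leaves to fit the height regression")
    n_branches = np.array([s.n_branches for s in ingroup], dtype=float)
    heights = np.array([s.height for s in ingroup], dtype=float)
    if np.all(n_branches == n_branches[0]):
        raise RpdSelectError("branch counts are constant; regression is degenerate")
    design = np.column_stack([np.ones_like(n_branches), n_branches])
    coef, *_ = np.linalg.lstsq(design, heights, rcond=None)
    resid = heights - design @ coef
    return {s.leaf: float(r) for s, r in zip(ingroup, resid)}


@dataclass(frozen=True)
class StabilityReport:
    """Agreement of two score tables on their shared leaves."""

    common_labels: int
    kendall_brpd: float
    kendall_urpd: float | None
    topk_lost: int
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "common_labels": [self.common_labels],
                "kendall_brpd": [self.kendall_brpd],
                "kendall_urpd": [self.kendall_urpd],
                "k": [self.k],
                "topk_lost": [self.topk_lost],
            }
        )


def compare_releases(table_a: ScoreTable, table_b: ScoreTable, k: int) -> StabilityReport:
    """Score stability across two trees (e.g. successive reference releases).

    Both tables are restricted to their shared ingroup leaves; Kendall tau-b
    is computed per variant on the paired scores, and ``topk_lost`` counts
    the members of ``table_a``'s top-k that do not appear in ``table_b``'s
    top-k (ranked over the shared leaves with deterministic tie-breaking).
    """
    a = {s.leaf: s for s in table_a.ingroup}
    b = {s.leaf: s for s in table_b.ingroup}
    common = sorted(set(a) & set(b))
    if len(common) < 2:
        raise RpdSelectError(f"only {len(common)} shared leaf label(s); need at least 2")
    if not 0 < k <= len(common):
        raise ValueError(f"k={k} out of range for {len(common)} shared labels")

    brpd_a = [a[l].brpd for l in common]
    brpd_b = [b[l].brpd for l in common]
    tau_b = kendall_tau(brpd_a, brpd_b)
    have_u = all(a[l].urpd is not None for l in common) and all(
        b[l].urpd is not None for l in common
    )
    tau_u = (
        kendall_tau([a[l].urpd for l in common], [b[l].urpd for l in common])
        if have_u
        else None
    )

    def topk(which: dict) -> set[str]:
        order = sorted(common, key=lambda l: (-which[l].brpd, l))
        return set(order[:k])

    lost = len(topk(a) - topk(b))
    return StabilityReport(
        common_labels=len(common),
        kendall_brpd=tau_b,
        kendall_urpd=tau_u,
        topk_lost=lost,
        k=k,
    )
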