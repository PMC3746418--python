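"""Per-leaf Relative Phylogenetic Diversity (RPD) scoring.

A leaf's score is an apportionment of the branch lengths on its path to the
root.  Writing ``b_i`` for the length of the *i*-th branch counted from the
leaf upward, ``s_i`` for the number of leaves of the subtree below that
branch, and ``N`` for the number of branches on the path:

* balanced score  ``bRPD = sum_i b_i / s_i`` — each internal branch is
  shared out among the leaves below it in proportion, so summed over all
  leaves bRPD returns exactly the total branch length of the tree;
* unbalanced score ``uRPD = sum_i b_i / 2**(i-1)`` — each pair of sister
  clades is weighted equally regardless of size; on a strictly bifurcating
  tree this likewise sums to the total branch length.

Both scores reward long pendant branches and topological isolation: a leaf
separated from the root by few, sparsely populated subtrees keeps more of
each shared branch.  uRPD is only defined on strictly dichotomous paths; a
generalized variant dividing by the running product of child counts is
available for trees with polytomies.

Scores are stored at full precision; reporting rounds half-up to 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional

import pandas as pd

from .errors import RpdSelectError, UnknownLeafError, UnsupportedTopologyError
from .tree import RootedTree, root_path

__all__ = [
    "LeafScore",
    "ScoreTable",
    "brpd",
    "urpd",
    "leaf_height",
    "score_all",
    "round_half_up",
]

UrpdMode = Literal["strict", "generalized", "omit"]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, as printed score tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LeafScore:
    """Scores and auxiliary path statistics for one leaf.

    ``n_branches`` is the number of branches between leaf and root (the
    quantity reported as "# nodes" in printed score tables: a leaf attached
    directly to the root has 1).
    """

    leaf: str
    brpd: float
    urpd: Optional[float]
    height: float
    n_branches: int
    is_outgroup: bool = False


@dataclass(frozen=True)
class ScoreTable:
    scores: tuple[LeafScore, ...]
    tree_total_length: float

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def __getitem__(self, leaf: str) -> LeafScore:
        for s in self.scores:
            if s.leaf == leaf:
                return s
        raise UnknownLeafError(f"no score for leaf {leaf!r}")

    @property
    def ingroup(self) -> tuple[LeafScore, ...]:
        return tuple(s for s in self.scores if not s.is_outgroup)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "leaf": [s.leaf for s in self.scores],
                "brpd": [s.brpd for s in self.scores],
                "urpd": [s.urpd for s in self.scores],
                "height": [s.height for s in self.scores],
                "n_branches": [s.n_branches for s in self.scores],
                "is_outgroup": [int(s.is_outgroup) for s in self.scores],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        scores = tuple(
            LeafScore(
                leaf=str(r.leaf),
                brpd=float(r.brpd),
                urpd=None if pd.isna(r.urpd) else float(r.urpd),
                height=float(r.height),
                n_branches=int(r.n_branches),
                is_outgroup=bool(int(r.is_outgroup)),
            )
            for r in df.itertuples()
        )
        total = sum(s.brpd for s in scores)
        return cls(scores=scores, tree_total_length=total)


# ---------------------------------------------------------------------------
# Single-leaf entry points (convenient but O(depth) each; bulk scoring below)
# ---------------------------------------------------------------------------


def brpd(tree: RootedTree, leaf: str) -> float:
    """Balanced RPD of one leaf: sum of b_i / s_i over the root path."""
    return sum(b.length / b.subtree_leaf_count for b in root_path(tree, leaf).branches)


def urpd(tree: RootedTree, leaf: str, mode: UrpdMode = "strict") -> float:
    """Unbalanced RPD of one leaf: sum of b_i / 2**(i-1) along the root path.

    With ``mode="generalized"`` the denominator is the running product of
    child counts of the nodes passed, which reduces to powers of two on
    strictly bifurcating paths.
    """
    path = root_path(tree, leaf)
    total = 0.0
    denom = 1.0
    for branch in path.branches:
        if branch.sibling_split_count > 2 and mode != "generalized":
            raise UnsupportedTopologyError(
                f"polytomy ({branch.sibling_split_count} children) on the root path of "
                f"{leaf!r}; uRPD is defined for strictly bifurcating trees "
                "(use generalized mode to divide by child counts instead)"
            )
        denom *= branch.sibling_split_count
        total += branch.length / denom
    return total


def leaf_height(tree: RootedTree, leaf: str) -> float:
    """Sum of branch lengths between the leaf and the root."""
    return root_path(tree, leaf).height


# ---------------------------------------------------------------------------
# Bulk scoring
# ---------------------------------------------------------------------------


def score_all(
    tree: RootedTree,
    outgroup: Iterable[str] = (),
    urpd_mode: UrpdMode = "strict",
) -> ScoreTable:
    """Score every leaf of the tree in a single pass.

    Outgroup leaves remain part of the topology — subtree sizes and hence all
    scores are computed on the full tree — but are flagged so downstream
    ranking and selection ignore them.  The ordering of ingroup scores does
    not depend on the outgroup scores.

    ``urpd_mode``: "strict" raises on any polytomy (the unbalanced score is
    only defined on dichotomous trees); "generalized" divides by the running
    product of child counts; "omit" records no unbalanced score.

    Raises if the outgroup exhausts the leaf set.
    """
    outgroup = set(outgroup)
    unknown = outgroup - set(tree.leaf_index)
    if unknown:
        raise UnknownLeafError(f"outgroup labels not in tree: {sorted(unknown)}")
    if outgroup and outgroup >= set(tree.leaf_index):
        raise RpdSelectError("outgroup must not contain every leaf")

    # Pre-order accumulation, O(number of nodes) overall.  For the
    # unbalanced score the carried quantity g(v) is the sum, over branches
    # already traversed, of each length divided by the product of
    # out-degrees of the internal nodes from that branch's lower end down
    # to v; then uRPD(leaf) = pendant_length + g(parent).  The root's own
    # out-degree never enters, so a multifurcating root is harmless.
    scores: list[LeafScore] = []
    want_u = urpd_mode != "omit"
    # stack entries: (node, brpd_acc, g_acc, height_acc, depth)
    stack: list[tuple] = [(tree.root, 0.0, 0.0, 0.0, 0)]
    while stack:
        node, b_acc, g_acc, h_acc, depth = stack.pop()
        if node.is_leaf:
            if depth == 0:
                continue  # degenerate one-node tree: nothing below the root
            scores.append(
                LeafScore(
                    leaf=node.label,
                    brpd=b_acc,
                    urpd=(node.parent_branch_length + g_acc) if want_u else None,
                    height=h_acc,
                    n_branches=depth,
                    is_outgroup=node.label in outgroup,
                )
            )
            continue
        for child in node.children:
            bl = child.parent_branch_length
            child_g = g_acc
            if want_u and not child.is_leaf:
                deg = len(child.children)
                if deg != 2 and urpd_mode == "strict":
                    raise UnsupportedTopologyError(
                        f"polytomy ({deg} children) below the root; uRPD is defined "
                        "for strictly bifurcating trees (use generalized mode or "
                        "omit uRPD)"
                    )
                child_g = (g_acc + bl) / deg
            stack.append(
                (
                    child,
                    b_acc + bl / child.subtree_leaf_count,
                    child_g,
                    h_acc + bl,
                    depth + 1,
                )
            )
    total = tree.total_branch_length()
    scores.sort(key=lambda s: s.leaf)
    return ScoreTable(scores=tuple(scores), tree_total_length=total)
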