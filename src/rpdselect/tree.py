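"""Rooted-tree model and Newick reading/writing.

The scoring formulas need, for every leaf, the ordered list of branches on
the path to the root together with the number of leaves hanging below each
branch.  This module provides exactly that: a light rooted-tree structure
with cached subtree leaf counts, built from standard Newick via dendropy,
plus pruning with unary-node collapse.

Conventions:

* Branch lengths are mandatory on every non-root branch and must be >= 0
  (zero-length branches occur in ML trees; negative lengths are artifacts
  and are rejected).
* A length attached to the root itself (or to the single node of a
  one-leaf tree) lies above the root and outside every leaf-to-root path;
  it is preserved for round-tripping but ignored by all scoring.
* Internal node labels (often bootstrap supports) are parsed and preserved
  but never interpreted.
* Root paths are always ordered leaf-to-root.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

from .errors import NewickParseError, TreeValidationError, UnknownLeafError

__all__ = [
    "TreeNode",
    "RootedTree",
    "RootPath",
    "RootPathBranch",
    "parse_newick",
    "write_newick",
    "root_path",
    "prune_leaves",
]


@dataclass
class TreeNode:
    """One node of a rooted tree.

    ``parent_branch_length`` is ``None`` only for the root.
    ``subtree_leaf_count`` is cached at construction time.
    """

    label: str = ""
    parent_branch_length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    subtree_leaf_count: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} bl={self.parent_branch_length}>"


@dataclass(frozen=True)
class RootPathBranch:
    """One branch on a leaf-to-root path.

    ``subtree_leaf_count`` is the number of leaves of the subtree hanging
    below the branch.  ``sibling_split_count`` is the number of children of
    the node at the lower (leafward) end of the branch; it is 1 for the
    pendant branch, and for any other branch it is the out-degree of the
    node where the previous branch of the path attaches.  The running
    product of these counts is the denominator sequence of generalized
    unbalanced scoring (powers of two on strictly bifurcating paths).
    """

    length: float
    subtree_leaf_count: int
    sibling_split_count: int


@dataclass(frozen=True)
class RootPath:
    leaf: str
    branches: tuple[RootPathBranch, ...]

    def __len__(self) -> int:
        return len(self.branches)

    @property
    def height(self) -> float:
        return sum(b.length for b in self.branches)


class RootedTree:
    """Rooted topology with branch lengths and uniquely labeled leaves."""

    def __init__(self, root: TreeNode, root_edge_length: Optional[float] = None):
        self.root = root
        self.root_edge_length = root_edge_length
        self.leaf_index: dict[str, TreeNode] = {}
        self._validate_and_index()

    # -- construction / validation ------------------------------------

    def _validate_and_index(self) -> None:
        self.leaf_index.clear()
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeValidationError("leaf with empty label")
                if node.label in self.leaf_index:
                    raise TreeValidationError(f"duplicate leaf label: {node.label!r}")
                self.leaf_index[node.label] = node
                node.subtree_leaf_count = 1
            else:
                if node is not self.root and len(node.children) < 2:
                    raise TreeValidationError(
                        f"internal node {node.label!r} has {len(node.children)} child(ren); "
                        "unary nodes must be collapsed"
                    )
                node.subtree_leaf_count = sum(c.subtree_leaf_count for c in node.children)
            if node is not self.root:
                bl = node.parent_branch_length
                if bl is None:
                    raise TreeValidationError(
                        f"branch above {node.label or '<internal>'!r} has no length; "
                        "scoring requires branch lengths on every branch"
                    )
                if bl < 0:
                    raise TreeValidationError(
                        f"negative branch length {bl} above {node.label or '<internal>'!r}"
                    )
        if self.root.parent is not None:
            raise TreeValidationError("root must not have a parent")
        if not self.root.is_leaf and len(self.root.children) < 2 and self.root.subtree_leaf_count > 1:
            raise TreeValidationError("root must have >= 2 children")

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    # -- queries -------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.postorder() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return self.root.subtree_leaf_count

    def total_branch_length(self) -> float:
        """Sum of all branch lengths; the root edge, being above the root, is excluded."""
        return sum(
            n.parent_branch_length for n in self.postorder() if n is not self.root
        )

    def __contains__(self, label: str) -> bool:
        return label in self.leaf_index

    def copy(self) -> "RootedTree":
        def clone(node: TreeNode, parent: Optional[TreeNode]) -> TreeNode:
            new = TreeNode(
                label=node.label,
                parent_branch_length=node.parent_branch_length,
                parent=parent,
            )
            new.children = [clone(c, new) for c in node.children]
            return new

        return RootedTree(clone(self.root, None), self.root_edge_length)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed parsing)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    def convert(dnode, parent: Optional[TreeNode]) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label or ""
        else:
            label = dnode.label or ""
        node = TreeNode(
            label=label,
            parent_branch_length=None if parent is None else dnode.edge.length,
            parent=parent,
        )
        node.children = [convert(c, node) for c in dnode.child_nodes()]
        return node

    root_edge = dtree.seed_node.edge.length
    return RootedTree(convert(dtree.seed_node, None), root_edge_length=root_edge)


def parse_newick(text: str) -> RootedTree:
    """Parse a single-tree Newick string into a :class:`RootedTree`.

    Quoted labels are unquoted, square-bracket comments are discarded, and
    internal-node labels are preserved.  Missing branch lengths, duplicate
    leaf labels and negative lengths raise :class:`TreeValidationError`;
    syntax errors raise :class:`NewickParseError` carrying the parser's
    position report.
    """
    if not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.\-|/]+$")


def _format_label(label: str) -> str:
    if not label:
        return ""
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def write_newick(tree: RootedTree) -> str:
    """Serialize to Newick; round-trips topology, labels and lengths exactly."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = _format_label(node.label)
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")" + _format_label(
                node.label
            )
        if node.parent is not None:
            body += f":{_format_length(node.parent_branch_length)}"
        return body

    out = render(tree.root)
    if tree.root_edge_length is not None:
        out += f":{_format_length(tree.root_edge_length)}"
    return out + ";"


# ---------------------------------------------------------------------------
# Root paths and pruning
# ---------------------------------------------------------------------------


def root_path(tree: RootedTree, leaf: str) -> RootPath:
    """Ordered leaf-to-root branch list with subtree sizes and split counts."""
    try:
        node = tree.leaf_index[leaf]
    except KeyError:
        raise UnknownLeafError(f"leaf {leaf!r} not in tree") from None
    branches: list[RootPathBranch] = []
    current = node
    first = True
    while current.parent is not None:
        split = 1 if first else len(current.children)
        branches.append(
            RootPathBranch(
                length=current.parent_branch_length,
                subtree_leaf_count=current.subtree_leaf_count,
                sibling_split_count=split,
            )
        )
        current = current.parent
        first = False
    return RootPath(leaf=leaf, branches=tuple(branches))


def prune_leaves(tree: RootedTree, labels: set[str]) -> RootedTree:
    """Return a new tree without the named leaves.

    Unary internal nodes created by the removal are collapsed, concatenating
    branch lengths.  If the root itself becomes unary its single child is
    promoted to root and that child's branch length moves onto the (ignored)
    root edge, so no leaf-to-root path gains length that is above the new
    root.
    """
    unknown = set(labels) - set(tree.leaf_index)
    if unknown:
        raise UnknownLeafError(f"labels not in tree: {sorted(unknown)}")
    if tree.n_leaves - len(set(labels)) < 2:
        raise TreeValidationError("pruning would leave fewer than 2 leaves")
    if not labels:
        return tree.copy()

    def build(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.label in labels:
                return None
            return TreeNode(label=node.label, parent_branch_length=node.parent_branch_length)
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # collapse the unary node: child inherits the concatenated length
            child = kept[0]
            if node.parent_branch_length is not None:
                child.parent_branch_length = (
                    child.parent_branch_length + node.parent_branch_length
                )
            return child
        new = TreeNode(label=node.label, parent_branch_length=node.parent_branch_length)
        new.children = kept
        for c in kept:
            c.parent = new
        return new

    new_root = build(tree.root)
    assert new_root is not None
    root_edge = tree.root_edge_length
    if new_root.parent_branch_length is not None:
        # the old root collapsed away; the surviving subtree's stem lies
        # above the new root and is kept only as the ignored root edge
        root_edge = new_root.parent_branch_length
        new_root.parent_branch_length = None
    return RootedTree(new_root, root_edge_length=root_edge)
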