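"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's tree model and accumulation passes:
scores are computed by enumerating every (leaf, ancestor-branch) pair on a
dendropy tree, Kendall's tau by explicit pair counting, and OLS by the
closed-form simple-regression solution.
"""

from __future__ import annotations

import math

import dendropy


def _dendropy_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def brute_force_scores(newick: str) -> dict[str, dict[str, float]]:
    """Per-leaf bRPD/uRPD/height/branch count by leaf-by-leaf path enumeration."""
    tree = _dendropy_tree(newick)
    out: dict[str, dict[str, float]] = {}
    for leaf in tree.leaf_node_iter():
        brpd = urpd = height = 0.0
        i = 0
        node = leaf
        while node.parent_node is not None:
            i += 1
            length = node.edge.length
            n_below = len(node.leaf_nodes())
            brpd += length / n_below
            urpd += length / 2 ** (i - 1)
            height += length
            node = node.parent_node
        out[leaf.taxon.label] = {
            "brpd": brpd,
            "urpd": urpd,
            "height": height,
            "n_branches": i,
        }
    return out


def kendall_tau_b(x, y) -> float:
    """O(n^2) pair-counting Kendall tau-b with tie correction."""
    n = len(x)
    assert n == len(y)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


def ols_residuals(x, y) -> list[float]:
    """Residuals of y on x from the closed-form simple regression with intercept."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    return [yi - (intercept + slope * xi) for xi, yi in zip(x, y)]
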