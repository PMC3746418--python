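"""Self-contained inputs: the six-leaf worked-example tree, seeded Yule
trees, and full synthetic selection scenarios.

Nothing here touches the network or disk (except the explicit writer): the
worked example is a constant, and everything else is generated from a seed
so that every pipeline stage can be exercised reproducibly.

The synthetic scenario emulates the shape of a real selection run — a
bifurcating species tree, a project registry covering part of the species
with noisily spelled strain names, a taxonomy with synonyms and type-strain
deposits, and an availability table — not real sequence-derived branch
lengths or real nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matching import (
    MatchStatus,
    ProjectRecord,
    ProjectStatus,
    TaxonomyEntry,
    match_registry,
)
from .selection import AvailabilityEntry
from .tree import RootedTree, TreeNode, write_newick

__all__ = [
    "FIGURE1_NEWICK",
    "figure1_tree",
    "yule_tree",
    "SyntheticScenario",
    "synthetic_scenario",
    "write_scenario",
]

# Six-leaf example: F hangs directly off the root; A sits in the densest
# subtree and D on a sparse sister clade at the same height, so the pair
# (A, D) separates topological isolation from plain height.
FIGURE1_NEWICK = "((((A:2,B:1):1,C:2):2,(D:2,E:1):3):2,F:6);"


def figure1_tree() -> RootedTree:
    """The six-leaf worked-example tree (total branch length 22)."""
    from .tree import parse_newick

    return parse_newick(FIGURE1_NEWICK)


# ---------------------------------------------------------------------------
# Yule (pure-birth) trees
# ---------------------------------------------------------------------------


def yule_tree(seed: int, n_leaves: int, rate: float = 1.0) -> RootedTree:
    """Strictly bifurcating pure-birth tree with ``n_leaves`` leaves.

    Each extant lineage splits at exponential rate ``rate``; branch lengths
    are the waiting times. Deterministic given ``seed``. Leaves are labeled
    ``L0001``... in order of appearance.
    """
    if n_leaves < 2:
        raise ValueError("a Yule tree needs at least 2 leaves")
    if rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode(parent=root)
        root.children.append(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / (rate * len(active)))
        idx = rng.integers(len(active))
        node, born = active.pop(int(idx))
        node.parent_branch_length = t - born
        for _ in range(2):
            child = TreeNode(parent=node)
            node.children.append(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (rate * len(active)))
    for i, (node, born) in enumerate(active):
        node.parent_branch_length = t - born
    # deterministic labels in tree (creation) order
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            counter += 1
            node.label = f"L{counter:04d}"
        stack.extend(reversed(node.children))
    return RootedTree(root)


# ---------------------------------------------------------------------------
# Synthetic selection scenarios
# ---------------------------------------------------------------------------

_SYLLABLES = [
    "ba", "ce", "di", "fo", "ga", "hu", "ki", "lo", "mi", "na",
    "pe", "ru", "sa", "te", "vi", "xo", "ze", "chi", "thra", "spo",
]


def _word(rng: np.random.Generator, n_syll: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))


def _perturb_strain(rng: np.random.Generator, name: str) -> str:
    """Respell a strain name without leaving its equivalence class.

    Only class-preserving edits are applied: case flips, insertion or
    deletion of separator characters (spaces, hyphens, dots), and appending
    a single type-strain "T".
    """
    chars = list(name)
    # random case flips
    chars = [
        (c.upper() if rng.random() < 0.5 else c.lower()) if c.isalpha() else c
        for c in chars
    ]
    # drop existing separators at random
    chars = [c for c in chars if c.isalnum() or c == "_" or rng.random() < 0.5]
    out = "".join(chars)
    # insert a separator somewhere in the middle
    if len(out) > 2 and rng.random() < 0.5:
        pos = int(rng.integers(1, len(out)))
        sep = str(rng.choice([" ", "-", "."]))
        out = out[:pos] + sep + out[pos:]
    if rng.random() < 0.5:
        out = out + ("T" if rng.random() < 0.5 else " T")
    return out


@dataclass(frozen=True)
class SyntheticScenario:
    """A reproducible tree + registry + taxonomy + availability bundle."""

    seed: int
    tree: RootedTree
    registry: list[ProjectRecord]
    taxonomy: list[TaxonomyEntry]
    availability: list[AvailabilityEntry]

    def leaf_status_map(self) -> dict[str, MatchStatus]:
        """Registry match status per leaf, for feeding into target selection.

        Records are matched against the taxonomy; each matched species maps
        back to its leaf. Leaves without any record are absent from the map.
        """
        by_species = {}
        results = match_registry(self.registry, self.taxonomy)
        records = {r.record_id: r for r in self.registry}
        for res in results:
            if res.matched_species is not None:
                # keep the "most covered" status if several records hit one species
                prev = by_species.get(res.matched_species)
                order = {
                    MatchStatus.FOUND_COMPLETE: 2,
                    MatchStatus.FOUND_INCOMPLETE: 1,
                    MatchStatus.STRAINS_NOT_FOUND: 0,
                }
                if prev is None or order[res.status] > order[prev]:
                    by_species[res.matched_species] = res.status
        del records
        return {
            leaf: status
            for leaf, status in by_species.items()
            if leaf in self.tree.leaf_index
        }


def synthetic_scenario(
    seed: int,
    n_leaves: int = 50,
    frac_registered: float = 0.3,
    frac_unavailable: float = 0.2,
    frac_fastidious: float = 0.05,
    frac_excluded: float = 0.02,
) -> SyntheticScenario:
    """Generate a full, internally consistent selection scenario.

    ``frac_registered`` of the species carry a registry record whose strain
    name is a class-preserving respelling of a true type-strain deposit (so
    a correct matcher recovers every one); ``frac_unavailable`` of the
    species are flagged as not held in the collection. All randomness comes
    from a single stream derived from ``seed``.
    """
    for name, frac in (
        ("frac_registered", frac_registered),
        ("frac_unavailable", frac_unavailable),
        ("frac_fastidious", frac_fastidious),
        ("frac_excluded", frac_excluded),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1F]))
    tree = yule_tree(int(rng.integers(2**31)), n_leaves)

    # species binomials as leaf labels
    names: list[str] = []
    seen = set()
    while len(names) < n_leaves:
        genus = _word(rng, 3).capitalize()
        epithet = _word(rng, 3)
        binomial = f"{genus} {epithet}"
        if binomial not in seen:
            seen.add(binomial)
            names.append(binomial)
    for old, new in zip(sorted(tree.leaf_index), names):
        tree.leaf_index[old].label = new
    tree.leaf_index = {n.label: n for n in tree.leaf_index.values()}

    taxonomy: list[TaxonomyEntry] = []
    deposits_by_species: dict[str, list[str]] = {}
    strain_no = iter(range(10000, 10000 + 2 * n_leaves))
    for binomial in names:
        deposits = [f"DSM {next(strain_no)}", f"ATCC {next(strain_no)}"]
        deposits_by_species[binomial] = deposits
        synonyms = {binomial}
        if rng.random() < 0.3:
            synonyms.add(f"{_word(rng, 3).capitalize()} {binomial.split()[1]}")
        taxonomy.append(
            TaxonomyEntry(
                accepted_species=binomial,
                synonyms=frozenset(synonyms),
                type_strain_deposits=frozenset(deposits),
            )
        )

    n_registered = int(round(frac_registered * n_leaves))
    registered = list(rng.choice(names, size=n_registered, replace=False))
    registry: list[ProjectRecord] = []
    for i, binomial in enumerate(registered):
        deposit = str(rng.choice(deposits_by_species[binomial]))
        spelled = _perturb_strain(rng, deposit)
        entry = taxonomy[names.index(binomial)]
        name_used = str(rng.choice(sorted(entry.synonyms)))
        status = ProjectStatus.COMPLETE if rng.random() < 0.5 else ProjectStatus.INCOMPLETE
        registry.append(
            ProjectRecord(
                record_id=f"GP{i:05d}",
                organism_name=f"{name_used} {spelled}",
                species_field=name_used if rng.random() < 0.7 else "",
                ncbi_project_name=f"{name_used} genome sequencing",
                strain_field=spelled,
                culture_collection=_perturb_strain(rng, deposit)
                if rng.random() < 0.5
                else "",
                project_status=status,
            )
        )

    n_unavail = int(round(frac_unavailable * n_leaves))
    unavailable = set(rng.choice(names, size=n_unavail, replace=False))
    availability = [
        AvailabilityEntry(
            leaf=binomial,
            in_collection=binomial not in unavailable,
            fastidious=bool(rng.random() < frac_fastidious),
            excluded_group=bool(rng.random() < frac_excluded),
        )
        for binomial in names
    ]
    return SyntheticScenario(
        seed=seed,
        tree=tree,
        registry=registry,
        taxonomy=taxonomy,
        availability=availability,
    )


def write_scenario(scenario: SyntheticScenario, outdir) -> dict[str, Path]:
    """Write the scenario as newick + registry/taxonomy/availability TSVs."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "registry": outdir / "registry.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "availability": outdir / "availability.tsv",
    }
    paths["tree"].write_text(write_newick(scenario.tree) + "\n")
    pd.DataFrame(
        {
            "record_id": [r.record_id for r in scenario.registry],
            "organism_name": [r.organism_name for r in scenario.registry],
            "species": [r.species_field for r in scenario.registry],
            "ncbi_project_name": [r.ncbi_project_name for r in scenario.registry],
            "strain": [r.strain_field for r in scenario.registry],
            "culture_collection": [r.culture_collection for r in scenario.registry],
            "status": [r.project_status.value for r in scenario.registry],
        }
    ).to_csv(paths["registry"], sep="\t", index=False)
    pd.DataFrame(
        {
            "accepted_species": [t.accepted_species for t in scenario.taxonomy],
            "synonyms": [";".join(sorted(t.synonyms)) for t in scenario.taxonomy],
            "type_strain_deposits": [
                ";".join(sorted(t.type_strain_deposits)) for t in scenario.taxonomy
            ],
        }
    ).to_csv(paths["taxonomy"], sep="\t", index=False)
    pd.DataFrame(
        {
            "leaf": [a.leaf for a in scenario.availability],
            "in_collection": [int(a.in_collection) for a in scenario.availability],
            "fastidious": [int(a.fastidious) for a in scenario.availability],
            "excluded_group": [int(a.excluded_group) for a in scenario.availability],
        }
    ).to_csv(paths["availability"], sep="\t", index=False)
    return paths
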