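# rpdselect

Phylogeny-driven target selection for genome-sequencing (and similar)
projects. Given a rooted phylogenetic tree with branch lengths — e.g. a
16S rRNA maximum-likelihood tree of bacterial and archaeal type strains —
`rpdselect` scores every leaf by its **Relative Phylogenetic Diversity
(RPD)**, ranks the leaves, and combines the ranking with a genome-project
registry and a culture-collection availability table to produce a
prioritized list of sequencing targets. It is aimed at people planning
large-scale sequencing, metabolite-screening or phenotyping campaigns who
want to cover as much evolutionary diversity as possible with a fixed
budget of organisms.

## The scoring

Let `N_j` be the number of branches between leaf *j* and the root, `b_ij`
the length of the *i*-th of these branches counted from the leaf upward,
and `s_ij` the number of leaves of the subtree hanging below that branch.
The two score variants are

```
bRPD(j) = Σ_{i=1..N_j}  b_ij / s_ij            (balanced)
uRPD(j) = Σ_{i=1..N_j}  b_ij / 2^(i-1)         (unbalanced)
```

bRPD shares each internal branch among the leaves below it in proportion,
so **Σ_j bRPD(j) equals the total branch length of the tree** — the score
of a subtree is just the sum of its leaves' scores, which makes saturation
analyses ("how many organisms capture 50% of the diversity?") trivial.
uRPD instead weights each pair of sister clades equally regardless of
size; on strictly bifurcating trees it conserves the total as well. Both
variants reward long pendant branches and topological isolation, and both
depend only on the tree — not on which leaves have already been targeted —
so the ranking never needs recomputing when project registries change.

## Worked example

`python examples/score_example_tree.py` scores the six-leaf demonstration
tree `((((A:2,B:1):1,C:2):2,(D:2,E:1):3):2,F:6);` and prints:

```
leaf    height    bRPD    uRPD  #branches
A        7.000   3.567   3.250          4
B        6.000   2.567   2.250          4
C        6.000   3.067   3.500          3
D        7.000   3.900   4.000          3
E        6.000   2.900   3.000          3
F        6.000   6.000   6.000          1
```

Reading the table: F hangs directly off the root on a branch shared with
nobody, so it keeps its full pendant length (6.0). A and D are equally far
from the root (height 7.0), but D sits behind fewer splits in a sparser
subtree, so it outscores A (3.900 vs 3.567). The bRPD column sums to 22.0,
the tree's total branch length. For leaf A the balanced sum expands to
`2/1 + 1/2 + 2/3 + 2/5 = 3.567` and the unbalanced one to
`2/1 + 1/2 + 2/4 + 2/8 = 3.25`.

The other example scripts demonstrate ranking and saturation
(`saturation_and_ranking.py`), cross-release stability
(`stability_comparison.py`) and the full match-and-select pipeline on a
synthetic scenario (`full_selection_pipeline.py`).

## Command line

The same functionality is exposed as a thin CLI:

```
rpdselect score    --tree tree.nwk --out scores.tsv
rpdselect rank     --tree tree.nwk --out-ranking r.tsv --out-curve c.tsv
rpdselect compare  --tree-a old.nwk --tree-b new.nwk --out stability.tsv
rpdselect match    --registry gold.tsv --taxonomy lpsn.tsv --out matches.tsv
rpdselect select   --tree tree.nwk --registry gold.tsv --taxonomy lpsn.tsv \
                   --availability holdings.tsv --n-targets 1000 \
                   --n-replacements 685 --out-matches m.tsv \
                   --out-report report.tsv --out-counts counts.tsv
rpdselect fixtures --seed 1 --n-leaves 50 --outdir scenario/
```

Use `--outgroup LABEL` to keep rooting taxa in the tree (they still shape
the subtree sizes) while excluding them from ranking and selection.

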