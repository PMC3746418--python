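# Methods

## The scoring model

`rpdselect` assigns each leaf *j* of a rooted tree with branch lengths a
Relative Phylogenetic Diversity score. With `N_j` branches between leaf
and root, `b_ij` the length of the *i*-th branch counted from the leaf
upward and `s_ij` the number of leaves below that branch:

* **bRPD(j) = Σ b_ij / s_ij** — every branch is divided evenly among the
  leaves that descend from it. Summing over all leaves counts each branch
  exactly once, so the bRPD total equals the tree's total branch length
  and the score of any subtree is the sum of its leaves' scores.
* **uRPD(j) = Σ b_ij / 2^(i−1)** — the weight halves at each split on the
  way up, so sister clades are weighted equally regardless of how many
  leaves they contain. Averaged over the leaves of a branch the divisor
  equals the leaf count, so on strictly bifurcating trees the uRPD total
  conserves the total branch length too.

Both variants depend only on the tree: no leaf is marked or removed when
a genome project starts elsewhere, so the ranking is stable across
registry updates and the same scores can serve several projects. Branch
lengths are taken as a proxy for expected character change, which assumes
some correlation between the tree's underlying marker (e.g. 16S rRNA) and
the characters one actually cares about, but no molecular clock.

### Interpretation of the auxiliary columns

`height` is the leaf-to-root branch-length sum; `n_branches` is `N_j`
(a leaf attached directly to the root has 1 — the column counts branches
on the path, which is what the formulas index over). `height_residuals`
regresses height on `n_branches` with an intercept (residuals then sum to
zero) to isolate the branch-length signal from the path-length signal.

## Tree handling

Newick parsing and the underlying tokenizer are delegated to dendropy;
the parsed tree is converted to a small rooted-tree model that enforces
what scoring needs: unique non-empty leaf labels, a branch length on
every non-root branch, no negative lengths. Zero-length branches are
legal (ML trees contain them; they contribute 0). A length on the root
itself lies above the root node and outside every leaf-to-root path; it
is preserved for round-tripping but ignored by all scoring. Internal-node
labels (typically bootstrap supports) are parsed and carried along but
never interpreted. Square-bracket comments are discarded; quoted labels
are unquoted on input and re-quoted on output when needed.

`prune_leaves` removes leaves and collapses the resulting unary nodes by
concatenating branch lengths. If the root itself becomes unary, its
single child is promoted to root and the former stem length moves onto
the ignored root edge — no surviving leaf's path gains length that sits
above the new root.

## Polytomies

bRPD is defined on arbitrary rooted trees. uRPD's power-of-two divisors
presuppose dichotomy, so the default (`strict`) mode raises on any
polytomy below the root. A documented `generalized` mode divides by the
running product of child counts instead, which reduces to 2^(i−1) on
bifurcating paths and still conserves the total branch length; `omit`
skips uRPD entirely. A multifurcating **root** needs no policy at all:
the divisor of the rootmost branch is the product of out-degrees of nodes
strictly below it, so the root's own out-degree never enters either
formula. This is the package's own resolution of a case the method
description leaves open.

## Outgroups

Rooting taxa stay in the tree when scoring — subtree sizes, and hence all
scores, are computed on the full topology — but are flagged and excluded
from ranking, saturation and selection. Because every leaf's score is
computed on the same fixed tree, the relative order of ingroup scores
does not depend on the outgroup scores.

## Ranking, saturation, stability

Ranking sorts by decreasing score with ties broken by ascending leaf
label; ranks are 1-based and consecutive, so top-k sets are reproducible.
The saturation curve is the cumulative percentage of the summed ingroup
scores after sorting decreasingly; `k_for_fraction` returns the smallest
k reaching a given fraction (a ≤1e−12 slack absorbs float rounding at
exact boundaries). Kendall correlations use the tie-corrected tau-b
(scipy), since realistic score vectors contain ties; analyses that used
an unspecified tau variant may therefore differ in the third decimal.
`compare_releases` restricts two score tables to their shared leaves,
computes tau per variant, and counts how many of table A's top-k leave
table B's top-k.

## Registry matching

Species names extracted from the organism, species and project-name
fields (each full field value plus its leading "Genus species" binomial,
since organism names commonly embed strain suffixes) are matched by exact
string equality against the synonym lists — misspellings are rare enough
in practice that fuzzy matching buys little and risks false merges.
Strain names from all five name fields are compared under a relaxed
equivalence: (i) case-insensitive; (ii) a single trailing "T" (type-
strain marker) is ignored; (iii) characters other than letters, digits
and underscores are ignored. The rules are applied in the order
punctuation-strip → lowercase → trailing-t strip, so "DSM 1T", "DSM 1 T"
and "dsm1t" are all equivalent to "DSM 1"; underscores are deliberately
retained characters, so "SOSP1-21" and "SOSP1_21" differ. Equality
consults both the stripped and unstripped keys. One edge case: stripping
a single trailing "t" is not idempotent on adversarial names ending in
"tt"; real collection identifiers end in digits or a single T, where the
canonical form is a fixed point (the tests assert this on that corpus).

Every record gets exactly one status: `species_not_found`,
`strains_not_found` (both mark the strain as a remaining sequencing
candidate), or `found_incomplete` / `found_complete` by project status.
A record matching several species resolves to the first taxonomy entry
in file order, with a logged warning.

## Selection cascade

Walking the ranking from best to worst, each leaf receives the first
applicable category: registry status (`completed_elsewhere`,
`in_progress_elsewhere`, `targeted_elsewhere`) → `excluded_group` →
`not_in_collection` → `technical_rejection` (fastidious) → `selected`
until the quota fills → `replacement` until that pool fills →
`postponed`. Registry status precedes availability, and group exclusion
precedes the availability flags; both orderings are this package's fixed,
documented choice. The match-status map may also carry raw registry
status strings ("completed", "in_progress", "targeted");
`found_incomplete` maps to `targeted_elsewhere`, since a two-valued
project status cannot distinguish in-progress from merely targeted
projects and the latter is the broader class. Leaves missing from the
availability table default to *not in collection* (what cannot be
obtained cannot be sequenced); `default_in_collection=True` flips this.
A target quota exceeding the eligible pool selects everything eligible
and logs a warning rather than failing. The categories partition the
ranked leaves, so the counts always sum to the ingroup leaf count.

## Synthetic data

The Yule generator grows a strictly bifurcating pure-birth tree: each
extant lineage splits at rate 1.0 per unit time by default, waiting times
are exponential, and branch lengths are the elapsed durations. It
reproduces the qualitative features that matter here — asymmetric
topologies and variable root-to-tip spans, hence right-skewed score
distributions — but not rate heterogeneity across lineages, calibrated
depths, or estimation error in branch lengths.

`synthetic_scenario` bundles a Yule tree whose leaves are invented
binomials with a taxonomy (two type-strain deposits per species, ~30%
with an extra synonym), a registry covering `frac_registered` of the
species (default 0.3) whose strain names are respelled using only
equivalence-preserving edits — case flips, separator insertion/removal,
an appended "T" — and an availability table with `frac_unavailable`
(default 0.2) of species out of collection, 5% fastidious and 2% in an
excluded group. All randomness flows from one named stream per scenario,
so a seed fully determines every artifact. Because the respellings are
constructed from the rule-preserving operations, 100% match recovery is
the correct expectation, and the matcher is tested against it; real
registries additionally contain genuinely missing deposits, free-text
noise and occasional misspellings that this generator does not emulate —
passing these tests shows the rules are implemented as specified, not
that recall on real registry dumps is 100%.

## Numerical choices and problem sizes

Scores are stored at full double precision; presentation rounds half-up
to 3 decimals. TSVs are written with 6 decimals so reruns are
byte-identical. Conservation is asserted at 1e−9 relative tolerance, and
agreement with the brute-force (leaf × ancestor-branch) enumeration
oracle at 1e−12 absolute. Scoring is a single post-order pass for subtree
sizes plus a single pre-order pass for the accumulated sums — O(nodes)
overall, comfortably fast for reference trees with ~10⁴ leaves. The test
suite exercises conservation on 100 seeded trees of up to 500 leaves,
oracle agreement on 50 seeded trees of up to 12 leaves, and skewness on
100 trees of 200 leaves; these sizes were chosen as the smallest that
make the statistical assertions stable.

## Limitations

* The method consumes a tree; it does not infer one, and artifacts of the
  underlying phylogeny (mis-annotated sequences, alignment problems)
  propagate directly into the ranking.
* uRPD is undefined on polytomies except through the documented
  generalized mode.
* Registry matching is exact-by-design; systematically misspelled
  species names will surface as `species_not_found` candidates.
* The selection cascade's precedence order is fixed; projects wanting,
  e.g., availability filtering before registry filtering must reorder by
  composing the library calls themselves.
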