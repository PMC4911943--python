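# Methods

## Model

A taxonomy is a rooted forest of concepts; a concept's circumscription is
treated as a nonempty set. Between two nonempty sets exactly one of the five
RCC-5 base relations holds (`==`, `>`, `<`, `><`, `!`); an articulation may
assert any nonempty disjunction of them between one concept of the later
taxonomy (T2, always written on the left) and one of the earlier (T1).
Three constraints are global: nonemptiness of every concept, sibling
disjointness, and coverage — a parent equals the union of its children.
Coverage is a per-concept flag (`nocoverage` in the input dialect) so a
concept can be given an intensional reading whose circumscription exceeds
its children; sibling disjointness cannot be switched off in this
implementation because it is built into the region construction below.

## Encoding and reasoner

The reasoner represents interpretations over *candidate Euler regions*: a
region is a signature (deepest containing concept in T2 or none, deepest in
T1 or none), where "deepest" ranges over *eligible* concepts — leaves, plus
internal concepts with coverage off. With e2 and e1 eligible concepts there
are (e2+1)(e1+1) − 1 regions (outside/outside is excluded). A model is a
set of occupied regions; a concept's extension is the union of occupied
regions at or below it. Sibling disjointness and within-taxonomy inclusion
hold by construction; multi-root forests need no special casing because two
roots never share a region. Nonemptiness becomes one must-hit constraint
per concept, and each base relation becomes a pattern over the three zones
of a pair (x, y) — x∩y, x\y, y\x:

* `==`: both difference zones forced empty;
* `>` / `<`: one difference zone forced empty, the other plus the
  intersection must be hit;
* `><`: all three zones must be hit;
* `!`: the intersection forced empty.

After fixing one disjunct per articulation (a *branch*; the product over
disjunction sizes, with early pruning), the constraints split into a
forced-empty region set E and a family of must-hit sets. Satisfiability is
then a linear check — every must-hit set must survive E — because the
maximal occupancy (all non-forced-empty regions) is a canonical witness.
Everything is plain-integer bitmask arithmetic.

**Possible worlds** are distinct induced relation maps over the cross
pairs, not distinct occupancies (many occupancies induce one world). They
are enumerated by breadth-first search over zone restrictions: the maximal
occupancy of the current region set F gives one world; any different world
must empty at least one currently nonempty pair zone Z, so children F\Z are
explored, deduplicated by F and by induced map. Validity is anti-monotone
under restriction, which makes the pruning exhaustive. Regions pinned by a
singleton must-hit can never be vacated; when every free region is pinned
the branch has exactly one model and the zone scan is skipped — this is the
fast path that makes full-scale instances (hundreds of concepts, ~10^5
regions) run in seconds. The search is fully deterministic; the `seed`
argument exists for interface stability only.

**MIR.** If enumeration exhausts under the world cap (default 256), each
cell is the union of that pair's relation over all worlds. Otherwise a
per-pair fallback runs 5·|C2|·|C1| satisfiability queries — relation t is
realizable at (x, y) iff all must-hit sets and t's witness zones survive
E ∪ (t's forced-empty zones) — so the MIR is exact even when enumeration is
truncated. Both strategies agree wherever both run (tested). Within-taxonomy
relations are not part of the MIR (the cell count is the cross-pair product
|C2|·|C1|); they are derivable — ancestor `>` descendant, `==` only along
monotypic coverage-on chains, `!` otherwise — and exposed by
`within_taxonomy_relation`.

**Diagnosis** of inconsistent inputs is deletion-based minimization over
articulations with the taxonomy structure held fixed: the result is
unsatisfiable while every proper subset is satisfiable. Minimal cores are
not unique; any minimal one is returned.

**Oracle.** An independent brute-force module enumerates all 2^k − 1
occupancy subsets (numpy, hard cap k ≤ 20 regions), applies the same
pattern semantics, and deduplicates by induced map. Reasoner/oracle
agreement on randomized small instances is the repository's central
correctness property. The worked-example fixture (39 regions) is
intentionally above oracle range; it is checked against its published
counts instead.

## Composition table

The shipped 25-entry RCC-5 composition table was produced by brute-force
enumeration of subset triples over a 6-element universe, the smallest size
at which the table is stable (size 6 equals size 7; both are re-derived in
the tests). Notably (>,<) composes to {== > < ><} — exclusion is impossible
because both outer sets contain the middle one — while (<,>) composes to
all five relations.

## Synthetic generators

`make_sized_pair(n2, n1, n_arts, seed)` builds T1 as a root(+genus-layer)
tree with exactly n1 concepts, clones it into T2, and grafts acquisition
leaves (attached round-robin to random genera) until T2 has exactly n2
concepts. Articulations follow the species-first recipe: every shared leaf
`==` its counterpart, every acquisition `!` the T1 root, then one root
statement plus further logically implied statements (genus counterparts,
leaf-under-root inclusions) as padding until exactly n_arts inputs exist.
Padding is sampled from already-implied cells, so it can never change the
world set; the instance always has exactly one world and n2 × n1 MIR cells.
The tree shape (number of genera) follows from the articulation budget:
leaves = min(n1 − 1, n_arts − acquisitions − 1).

`generate_evolved_pair(params)` derives T2 from T1 through the observed
change taxonomy: k-way splits (children `<` the old leaf; by convention the
first child keeps the old name, mirroring how narrowed concepts retain the
epithet), acquisitions (`!` the T1 root), two-leaf lumps (the later concept
`>` each merged leaf, keeping the first leaf's name), and renames (`==`,
new name). Defaults are deliberately modest (6 leaves, flat tree) — the
point of the generator is known ground truth, not realism at scale. The
root statement is `>` when acquisitions exist; `{== <}` when only splits
exist (whether the split children exhaust the old concepts is left open,
reproducing the published two-world slack); `==` otherwise. The expected
world count is exact: every undetermined region doubles the worlds, and the
undetermined regions are (i) per split target X, content of X outside every
later concept — open unless the root statement is `==` or `>`; (ii) per
lump L under a `>` root statement, content of L outside the earlier root;
and (iii) per (lump, split) pair, content of L inside X's residue, which no
species-level statement bounds. Hence 2^(n_lump·(1+n_split)) worlds with
acquisitions, 2^(n_split·(1+n_lump)) with splits only, and 1 otherwise.

What the generator does *not* emulate: nomenclatural acts (synonymy lists,
authorities), more than two time steps, rank-level rearrangements between
fixed endpoints, or expert disagreement (articulations are always correct
by construction). Passing tests therefore demonstrate the reasoning and
bookkeeping, not robustness to erroneous expert input.

## Metrics

Relation tallies count singleton MIR cells per relation, with disjunctive
cells reported separately as ambiguous; tallies plus ambiguous always sum
to |C2|·|C1|. The information-expression ratio is MIR cells per input
articulation. Relative congruence is 100 × (congruent cells) / (concepts in
the concept-poorer taxonomy) and may exceed 100 when redundant monotypic
chains each contribute a congruent cell. Name:meaning categories compare
same-rank pairs only (rank labels trimmed, case-insensitive, and tabulated
only for ranks present in both taxonomies): `==:=`, `==:≠`, `>:=`, `<:=`,
`><:=`, where "=" is exact string identity of the full name token — a
re-combined epithet counts as a different name. Pairs that are neither
congruent nor same-named are not counted; exclusion under an identical name
would be a homonym and is asserted absent. The reliability ratio divides
`==:=` (reliable) by the other four categories (unreliable), normalizing
the smaller side to 1. All ratios and percentages print with one decimal,
rounding half away from zero to match the published table style.
Category classification uses singleton cells, or a caller-chosen world when
ambiguous cells exist.

## Merge graphs

Concepts are grouped by congruence (EQ cells plus monotypic coverage
chains); classes containing concepts of both taxonomies, or more than one
concept, render as gray rounded boxes, remaining T2/T1 singletons as green
boxes / yellow octagons. Containment edges (from `>`/`<` cells and
parenthood) are transitively reduced with networkx; `><` cells become
dashed blue overlap edges. The combined-concept view replaces each overlap
(A, B) with Euler subregion nodes A*B (child of both), A\B and B\A, checked
nonempty against the chosen world's witness occupancy (for a genuine
overlap all three are occupied). Output is deterministic DOT text; layout
and rendering are left to GraphViz or any DOT consumer. When several worlds
exist the CLI renders world index 0 by default (`--world` selects another);
subregion emptiness is decided in that world only.

## Numerical and degenerate-input choices

Ties and orderings are fixed everywhere (taxonomy declaration order, the
relation order `== > < >< !`, lexicographic CSV and DOT ordering), so
byte-identical reruns require no seed. Single-concept taxonomies are legal
(coverage is vacuous); empty articulation sets are legal (every cell is
then the full disjunction realizable under the structural constraints).
The world cap defaults to 256; the enumeration also carries an internal
node budget (64 × cap) guarding pathological under-constrained inputs, and
reports `exhausted=False` whenever it stops early — MIR exactness never
depends on it. The oracle refuses instances above 20 regions rather than
degrade. Problem sizes used in the shipped tests (full-scale 483 × 317
instance, 200 randomized oracle comparisons, a 32-scenario generator grid)
were chosen so the whole suite completes in about a minute on one CPU.

## Known limitations

* Exclusion cannot be relaxed per-sibling (no "incertae sedis" overlap
  among siblings) because disjointness is structural.
* Articulations relate exactly two taxonomies; multi-way alignment means
  repeated pairwise runs.
* The per-pair MIR fallback is quadratic in concept counts times five
  queries; it is intended for moderate ambiguous instances, not for
  under-constrained inputs at full scale.
* Diagnosis returns one minimal core, not all of them, and does not suggest
  repairs.
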