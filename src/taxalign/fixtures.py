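"""Synthetic alignment problems with known ground truth.

Emulates the change taxonomy observed between successive editions of a
classification standard:

* *reassessment splits* — a later treatment carves k narrower species
  concepts out of one earlier concept; each child is articulated as
  properly included (<) in the old concept, and whether the children's
  union exhausts the old concept is deliberately left open;
* *acquisitions* — species based on newly collected material, articulated
  as exclusive (!) of the earlier root, which expands the later parent
  concepts;
* *lumps* — one later concept properly includes (>) several earlier ones;
* *renames* — congruent circumscription under a new name.

Also ships the hard-coded mouse-lemur fixture (Microcebus/Mirza, 2005
vs. 1993 treatments; reconstructed from the published worked example) and a
sized-instance builder exercising the MIR product law at arbitrary scale.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import AlignmentProblem, Articulation, Concept, Taxonomy
from .rcc5 import BaseRelation, RelationSet

__all__ = [
    "ScenarioParams",
    "GroundTruth",
    "fixture_fig1",
    "fixture_fig1_ranks",
    "make_sized_pair",
    "generate_evolved_pair",
]

_EQ = RelationSet.of(BaseRelation.EQ)
_GT = RelationSet.of(BaseRelation.GT)
_LT = RelationSet.of(BaseRelation.LT)
_DJ = RelationSet.of(BaseRelation.DJ)


def fixture_fig1() -> AlignmentProblem:
    """The published mouse-lemur worked example.

    T1 is the 1993 treatment: genus *Microcebus* with three species
    (murinus, rufus, coquereli).  T2 is the 2005 treatment: *Microcebus*
    with eight species plus the monotypic genus *Mirza* — 11 concepts
    against 4.  Nine input articulations: the three reassessment species
    each properly included in 1993 murinus, the four acquisition species
    exclusive of the 1993 genus, and two congruences (rufus, coquereli).

    Note: the published figure legend prints only the node/edge counts;
    this 11/4-concept reconstruction is validated by the printed 44-MIR
    and two-world outcomes and by the synonymy narrative of the source
    treatments.
    """
    t2 = Taxonomy("2005", "Microcebus_Mirza_sec_2005")
    mic2 = t2.add_concept("Microcebus")
    species_2005 = [
        "Microcebus_berthae",
        "Microcebus_griseorufus",
        "Microcebus_murinus",
        "Microcebus_myoxinus",
        "Microcebus_ravelobensis",
        "Microcebus_rufus",
        "Microcebus_sambiranensis",
        "Microcebus_tavaratra",
    ]
    for name in species_2005:
        t2.add_edge(mic2, t2.add_concept(name))
    mirza = t2.add_concept("Mirza")
    t2.add_edge(mirza, t2.add_concept("Mirza_coquereli"))

    t1 = Taxonomy("1993", "Microcebus_sec_1993")
    mic1 = t1.add_concept("Microcebus")
    for name in ("Microcebus_murinus", "Microcebus_rufus", "Microcebus_coquereli"):
        t1.add_edge(mic1, t1.add_concept(name))

    arts = [
        Articulation(t2["Microcebus_griseorufus"], _LT, t1["Microcebus_murinus"], "fig1"),
        Articulation(t2["Microcebus_murinus"], _LT, t1["Microcebus_murinus"], "fig1"),
        Articulation(t2["Microcebus_myoxinus"], _LT, t1["Microcebus_murinus"], "fig1"),
        Articulation(t2["Microcebus_berthae"], _DJ, t1["Microcebus"], "fig1"),
        Articulation(t2["Microcebus_ravelobensis"], _DJ, t1["Microcebus"], "fig1"),
        Articulation(t2["Microcebus_sambiranensis"], _DJ, t1["Microcebus"], "fig1"),
        Articulation(t2["Microcebus_tavaratra"], _DJ, t1["Microcebus"], "fig1"),
        Articulation(t2["Microcebus_rufus"], _EQ, t1["Microcebus_rufus"], "fig1"),
        Articulation(t2["Mirza_coquereli"], _EQ, t1["Microcebus_coquereli"], "fig1"),
    ]
    return AlignmentProblem(t2, t1, arts)


def fixture_fig1_ranks() -> list[tuple[str, str, str]]:
    """Rank sidecar rows for the mouse-lemur fixture."""
    problem = fixture_fig1()
    rows = []
    for tax in (problem.t2, problem.t1):
        for c in tax.concepts:
            rank = "genus" if tax.parent(c) is None else "species"
            rows.append((tax.id, c.name, rank))
    return rows


def _build_tree(tax: Taxonomy, n_leaves: int, n_genera: int, leaf_names: list[str]) -> None:
    """Root plus an optional genus layer; leaves distributed round-robin."""
    root = tax.add_concept("Root")
    if n_genera == 0:
        for name in leaf_names:
            tax.add_edge(root, tax.add_concept(name))
        return
    genera = [tax.add_concept(f"Genus_{g:03d}") for g in range(n_genera)]
    for g in genera:
        tax.add_edge(root, g)
    for i, name in enumerate(leaf_names):
        tax.add_edge(genera[i % n_genera], tax.add_concept(name))


def make_sized_pair(
    n2_concepts: int, n1_concepts: int, n_articulations: int, seed: int = 0
) -> AlignmentProblem:
    """A consistent pair of given concept counts with a unique world.

    T1 is a root(+genera) tree with exactly ``n1_concepts`` concepts; T2
    clones it and grafts acquisition leaves until it holds exactly
    ``n2_concepts``.  Articulations follow the species-first recipe: every
    shared leaf is congruent, every acquisition leaf excludes the T1 root,
    and one highest-level statement relates the roots.  If that minimal set
    is smaller than ``n_articulations``, the remainder is padded with
    logically implied statements (which can never change the world set).
    """
    if n2_concepts < n1_concepts or n1_concepts < 2:
        raise ValueError("need n2_concepts >= n1_concepts >= 2")
    n_new = n2_concepts - n1_concepts
    # leaf congruences and acquisition exclusions are mandatory; the root
    # statement is implied by them under coverage, so it yields to a tight
    # articulation budget (it is the first padding statement otherwise)
    n_leaves = min(n1_concepts - 1, max(1, n_articulations - n_new - 1))
    n_genera = n1_concepts - 1 - n_leaves
    if n_leaves + n_new > n_articulations or n_genera > n_leaves:
        raise ValueError(
            f"infeasible sizes: {n_articulations} articulations cannot cover "
            f"{n2_concepts}x{n1_concepts} concepts with the species-first recipe"
        )
    rng = random.Random(seed)
    leaf_names = [f"Species_{i:04d}" for i in range(n_leaves)]

    t1 = Taxonomy("t1", "earlier_edition")
    _build_tree(t1, n_leaves, n_genera, leaf_names)
    t2 = Taxonomy("t2", "later_edition")
    _build_tree(t2, n_leaves, n_genera, leaf_names)

    attach_to = (
        [t2[f"Genus_{g:03d}"] for g in range(n_genera)] if n_genera else [t2["Root"]]
    )
    for i in range(n_new):
        leaf = t2.add_concept(f"Novum_{i:04d}")
        t2.add_edge(rng.choice(attach_to), leaf)

    arts = [
        Articulation(t2[name], _EQ, t1[name], "sized") for name in leaf_names
    ]
    arts += [
        Articulation(t2[f"Novum_{i:04d}"], _DJ, t1["Root"], "sized") for i in range(n_new)
    ]

    n_pad = n_articulations - len(arts)
    pads = [Articulation(t2["Root"], _GT if n_new else _EQ, t1["Root"], "root")]
    for g in range(n_genera):
        g2, g1 = t2[f"Genus_{g:03d}"], t1[f"Genus_{g:03d}"]
        grew = any(k.name.startswith("Novum") for k in t2.children(g2))
        pads.append(Articulation(g2, _GT if grew else _EQ, g1, "pad"))
    pads += [Articulation(t2[name], _LT, t1["Root"], "pad") for name in leaf_names]
    if n_pad > len(pads):
        raise ValueError("not enough implied statements available for padding")
    arts += pads[:n_pad]
    return AlignmentProblem(t2, t1, arts)


@dataclass
class ScenarioParams:
    """Knobs of the evolved-pair generator.

    ``leaf_count_t1`` species in the earlier treatment, grouped into genera
    of ``internal_arity`` (0/1 keeps a flat tree); ``n_split`` leaves are
    split ``split_ways``-ways, ``n_new`` acquisitions are added, ``n_lump``
    pairs of leaves are merged, ``n_rename`` leaves change name only.
    Splits, lumps and renames apply to distinct leaves.
    """

    leaf_count_t1: int = 6
    internal_arity: int = 0
    n_split: int = 0
    n_new: int = 0
    n_lump: int = 0
    n_rename: int = 0
    seed: int = 0
    split_ways: int = 3


@dataclass
class GroundTruth:
    """What the generator knows about its own output."""

    articulations: list[Articulation]
    root_articulation: Articulation
    expected_worlds: int
    expected_cells: dict[tuple[Concept, Concept], RelationSet] = field(default_factory=dict)


def generate_evolved_pair(params: ScenarioParams) -> tuple[AlignmentProblem, GroundTruth]:
    """Derive a later taxonomy from an earlier one with known articulations.

    The emitted statements follow the species-first recipe: one statement
    per species-level change plus a single root statement.  With
    acquisitions the root statement is ``>`` (new material expands the later
    root), which also settles every split parent's upper bound; without
    acquisitions but with splits it is the disjunction ``{== <}``, leaving
    open whether the split children exhaust their old concepts — each split
    then doubles the number of possible worlds, the published two-world
    slack.  Lumped concepts keep the same open upper bound when the root
    statement is ``>``.
    """
    p = params
    if min(p.leaf_count_t1, p.split_ways) < 2 or min(
        p.n_split, p.n_new, p.n_lump, p.n_rename
    ) < 0:
        raise ValueError("invalid scenario parameters")
    n_targets = p.n_split + 2 * p.n_lump + p.n_rename
    if n_targets > p.leaf_count_t1:
        raise ValueError(
            f"{n_targets} distinct target leaves needed but only "
            f"{p.leaf_count_t1} leaves in the earlier taxonomy"
        )
    rng = random.Random(p.seed)
    leaf_names = [f"Species_{i:04d}" for i in range(p.leaf_count_t1)]
    n_genera = 0 if p.internal_arity < 2 else -(-p.leaf_count_t1 // p.internal_arity)

    t1 = Taxonomy("t1", "earlier_edition")
    _build_tree(t1, p.leaf_count_t1, n_genera, leaf_names)

    targets = rng.sample(leaf_names, n_targets)
    split_of = targets[: p.n_split]
    lump_of = [
        (targets[p.n_split + 2 * i], targets[p.n_split + 2 * i + 1])
        for i in range(p.n_lump)
    ]
    rename_of = targets[p.n_split + 2 * p.n_lump:]
    lumped = {n for pair in lump_of for n in pair}

    t2 = Taxonomy("t2", "later_edition")
    root2 = t2.add_concept("Root")
    genus2_of: dict[str, Concept] = {}
    if n_genera:
        for g in range(n_genera):
            genus2_of[f"Genus_{g:03d}"] = gc = t2.add_concept(f"Genus_{g:03d}")
            t2.add_edge(root2, gc)

    def t2_parent(leaf_name: str) -> Concept:
        if not n_genera:
            return root2
        return genus2_of[t1.parent(t1[leaf_name]).name]

    arts: list[Articulation] = []
    expected: dict[tuple[Concept, Concept], RelationSet] = {}

    for name in leaf_names:
        old = t1[name]
        if name in split_of:
            for j in range(p.split_ways):
                # convention: the first narrowed concept keeps the old name
                child_name = name if j == 0 else f"{name}_sp{j}"
                child = t2.add_concept(child_name)
                t2.add_edge(t2_parent(name), child)
                arts.append(Articulation(child, _LT, old, "split"))
        elif name in lumped:
            continue  # handled below, one concept per lump pair
        elif name in rename_of:
            child = t2.add_concept(f"{name}_renamed")
            t2.add_edge(t2_parent(name), child)
            arts.append(Articulation(child, _EQ, old, "rename"))
        else:
            child = t2.add_concept(name)
            t2.add_edge(t2_parent(name), child)
            arts.append(Articulation(child, _EQ, old, "unchanged"))
    for a_name, b_name in lump_of:
        child = t2.add_concept(a_name)  # the lump keeps the first valid name
        t2.add_edge(t2_parent(a_name), child)
        arts.append(Articulation(child, _GT, t1[a_name], "lump"))
        arts.append(Articulation(child, _GT, t1[b_name], "lump"))
    for i in range(p.n_new):
        child = t2.add_concept(f"Novum_{i:04d}")
        t2.add_edge(root2, child)
        arts.append(Articulation(child, _DJ, t1["Root"], "acquisition"))

    # Exact world count: each undetermined Euler region doubles the worlds,
    # and every one of them toggles a distinct cross-pair cell.  The open
    # regions are: per split target X, "content of X outside every later
    # concept" (closed by a == or > root statement); per lump L when the
    # root statement is >, "content of L outside the earlier root"; and per
    # (lump L, split target X) pair, "content of L inside X's residue",
    # which no species-level statement bounds.
    if p.n_new > 0:
        root_rel = _GT
        expected_worlds = 2 ** (p.n_lump * (1 + p.n_split))
    elif p.n_split > 0:
        root_rel = RelationSet.of(BaseRelation.EQ, BaseRelation.LT)
        expected_worlds = 2 ** (p.n_split * (1 + p.n_lump))
    else:
        root_rel = _EQ
        expected_worlds = 1
    root_art = Articulation(t2["Root"], root_rel, t1["Root"], "root")
    arts.append(root_art)

    for a in arts:
        if a is root_art and len(root_rel) > 1 and p.n_split > 0:
            expected[(a.left, a.right)] = root_rel
        elif a is not root_art and a.label == "lump" and p.n_new > 0:
            expected[(a.left, a.right)] = a.relation  # GT, forced
        else:
            expected[(a.left, a.right)] = a.relation if len(a.relation) == 1 else a.relation

    problem = AlignmentProblem(t2, t1, arts)
    truth = GroundTruth(
        articulations=arts,
        root_articulation=root_art,
        expected_worlds=expected_worlds,
        expected_cells=expected,
    )
    return problem, truth
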