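"""Core alignment logic over candidate Euler regions.

The encoding follows the *polynomial* region semantics: a candidate region
is a signature (deepest containing concept in T2 or none, deepest in T1 or
none); an interpretation is the set of occupied regions, and a concept's
extension is the union of occupied regions whose deepest node lies at or
below it.  Sibling disjointness and within-taxonomy inclusion hold by
construction of the signatures; nonemptiness becomes a "must hit at least
one region" constraint per concept, and each RCC-5 articulation becomes a
pattern over three per-pair witnesses (a region inside x∩y, inside x\\y,
inside y\\x):

====  =================================================
==    x\\y and y\\x empty
>     y\\x empty, x∩y and x\\y occupied
<     x\\y empty, x∩y and y\\x occupied
><    x∩y, x\\y and y\\x all occupied
!     x∩y empty
====  =================================================

After fixing one base relation per (possibly disjunctive) articulation, the
constraints split into forced-empty region sets and must-hit region sets,
so satisfiability reduces to checking that every must-hit set survives the
forced-empty union — the maximal occupancy is then a witness model.
Possible worlds (distinct induced relation maps over the cross-taxonomy
pairs, not distinct occupancies) are enumerated by breadth-first search
over zone restrictions: any world other than the maximal one must empty at
least one currently nonempty per-pair zone, and validity is anti-monotone
under restriction, so the search is exhaustive.

Everything is plain-integer bitmask arithmetic; no external solver is used.
The brute-force :mod:`taxalign.oracle` independently checks this module on
small instances.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .model import AlignmentProblem, Articulation, Concept, Taxonomy
from .rcc5 import BaseRelation, RelationSet

__all__ = [
    "CandidateRegion",
    "World",
    "MIRTable",
    "InconsistencyError",
    "candidate_regions",
    "check_consistency",
    "enumerate_worlds",
    "compute_mir",
    "diagnose",
    "within_taxonomy_relation",
]


class InconsistencyError(RuntimeError):
    """The input constraints admit no possible world; run diagnose()."""


@dataclass(frozen=True)
class CandidateRegion:
    """Euler-region signature: deepest containing concept per taxonomy."""

    deepest_t2: Concept | None
    deepest_t1: Concept | None

    def __post_init__(self):
        if self.deepest_t2 is None and self.deepest_t1 is None:
            raise ValueError("a candidate region needs a deepest concept in at least one taxonomy")

    def __repr__(self) -> str:
        a = self.deepest_t2.label if self.deepest_t2 else "-"
        b = self.deepest_t1.label if self.deepest_t1 else "-"
        return f"Region({a}|{b})"


@dataclass
class World:
    """One consistent alignment: a base relation for every cross pair,
    plus one occupancy that realizes it."""

    relations: dict[tuple[Concept, Concept], BaseRelation]
    witness: frozenset[CandidateRegion]


@dataclass
class MIRTable:
    """Maximally Informative Relations: per cross pair, the set of base
    relations realized in at least one possible world."""

    cells: dict[tuple[Concept, Concept], RelationSet]
    provenance: dict[tuple[Concept, Concept], str]
    n_t2: int
    n_t1: int
    n_worlds: int
    exhausted: bool = True

    def __len__(self) -> int:
        return len(self.cells)

    def singleton_cells(self) -> dict[tuple[Concept, Concept], BaseRelation]:
        return {p: next(iter(rs)) for p, rs in self.cells.items() if len(rs) == 1}

    def ambiguous_cells(self) -> dict[tuple[Concept, Concept], RelationSet]:
        return {p: rs for p, rs in self.cells.items() if len(rs) > 1}


_REL_CODE = {r: i for i, r in enumerate(BaseRelation)}


# ---------------------------------------------------------------------------
# encoding


class _Encoding:
    """Bitmask machinery shared by all reasoning entry points.

    Regions are indexed ``a2 * (e1 + 1) + a1`` where index 0 on either axis
    means "outside that taxonomy" and index i+1 means eligible concept i.
    Bit 0 (outside both) can never be occupied.
    """

    def __init__(self, problem: AlignmentProblem):
        if not problem.options.sibling_disjointness:
            raise ValueError(
                "sibling_disjointness=False is not supported: disjointness is "
                "built into the Euler-region signatures"
            )
        self.problem = problem
        t2, t1 = problem.t2, problem.t1
        self.elig2 = t2.eligible_concepts()
        self.elig1 = t1.eligible_concepts()
        self.e2, self.e1 = len(self.elig2), len(self.elig1)
        self.block = self.e1 + 1                      # regions per T2 slot
        self.n_bits = (self.e2 + 1) * self.block
        self.ALL = ((1 << self.n_bits) - 1) & ~1      # bit 0 is the dead region

        full_block = (1 << self.block) - 1
        rep = sum(1 << (b * self.block) for b in range(self.e2 + 1))

        elig_index2 = {c: i for i, c in enumerate(self.elig2)}
        elig_index1 = {c: i for i, c in enumerate(self.elig1)}
        # ancestor concept lists per eligible slot (for compact remapping)
        self.anc2 = [[c for c in t2.ancestors_or_self(e)] for e in self.elig2]
        self.anc1 = [[c for c in t1.ancestors_or_self(e)] for e in self.elig1]

        self.mask2: dict[Concept, int] = {}
        for c in t2.concepts:
            m = 0
            for d in t2.descendants_or_self(c):
                i = elig_index2.get(d)
                if i is not None:
                    m |= full_block << ((i + 1) * self.block)
            self.mask2[c] = m
        self.mask1: dict[Concept, int] = {}
        for c in t1.concepts:
            col = 0
            for d in t1.descendants_or_self(c):
                j = elig_index1.get(d)
                if j is not None:
                    col |= 1 << (j + 1)
            self.mask1[c] = col * rep

        # nonemptiness: every concept's extension must be hit
        self.global_hits: list[int] = [self.mask2[c] for c in t2.concepts]
        self.global_hits += [self.mask1[c] for c in t1.concepts]

    # -- articulation patterns -----------------------------------------
    def zones(self, x: Concept, y: Concept) -> tuple[int, int, int]:
        """(x∩y, x\\y, y\\x) region masks for a cross pair."""
        m2, m1 = self.mask2[x], self.mask1[y]
        return m2 & m1, m2 & ~m1 & self.ALL, m1 & ~m2 & self.ALL

    def pattern(self, rel: BaseRelation, x: Concept, y: Concept) -> tuple[int, list[int]]:
        """(forced-empty mask, must-hit masks) realizing ``x rel y``.

        Nonemptiness of x and y themselves is a global constraint and not
        repeated here.
        """
        mi, ml, mr = self.zones(x, y)
        if rel is BaseRelation.EQ:
            return ml | mr, [mi]
        if rel is BaseRelation.GT:
            return mr, [mi, ml]
        if rel is BaseRelation.LT:
            return ml, [mi, mr]
        if rel is BaseRelation.OV:
            return 0, [mi, ml, mr]
        return mi, []  # DJ

    def branches(self, articulations: list[Articulation] | None = None):
        """Yield (empty_mask, must_hits) for every consistent choice of one
        base relation per articulation, in deterministic disjunct order."""
        arts = self.problem.articulations if articulations is None else articulations
        choices = []
        for a in arts:
            choices.append([self.pattern(r, a.left, a.right) for r in a.relation.ordered])

        def rec(i: int, empty: int, hits: list[int]):
            if i == len(choices):
                f = self.ALL & ~empty
                if all(h & f for h in self.global_hits) and all(h & f for h in hits):
                    yield empty, self.global_hits + hits
                return
            for e, h in choices[i]:
                e2 = empty | e
                # cheap necessary condition; the full check runs at the leaf
                if all(m & self.ALL & ~e2 for m in h):
                    yield from rec(i + 1, e2, hits + h)

        yield from rec(0, 0, [])

    # -- interpretation ------------------------------------------------
    def regions_of(self, occupancy_mask: int) -> frozenset[CandidateRegion]:
        out = []
        m = occupancy_mask
        while m:
            low = m & -m
            j = low.bit_length() - 1
            a2, a1 = divmod(j, self.block)
            out.append(
                CandidateRegion(
                    self.elig2[a2 - 1] if a2 else None,
                    self.elig1[a1 - 1] if a1 else None,
                )
            )
            m ^= low
        return frozenset(out)

    def induce(self, occupancy_mask: int):
        """Relation map and signature induced by an occupancy.

        Remaps the occupied regions to a compact bitspace first, so the cost
        per cross pair is a handful of small-integer operations even when
        the full region space is large.
        """
        t2c, t1c = self.problem.t2.concepts, self.problem.t1.concepts
        cm2 = dict.fromkeys(t2c, 0)
        cm1 = dict.fromkeys(t1c, 0)
        m = occupancy_mask
        pos = 0
        while m:
            low = m & -m
            j = low.bit_length() - 1
            a2, a1 = divmod(j, self.block)
            bit = 1 << pos
            if a2:
                for c in self.anc2[a2 - 1]:
                    cm2[c] |= bit
            if a1:
                for c in self.anc1[a1 - 1]:
                    cm1[c] |= bit
            pos += 1
            m ^= low
        EQ, GT, LT, OV, DJ = (
            BaseRelation.EQ, BaseRelation.GT, BaseRelation.LT,
            BaseRelation.OV, BaseRelation.DJ,
        )
        relations: dict[tuple[Concept, Concept], BaseRelation] = {}
        sig = bytearray()
        for x in t2c:
            a = cm2[x]
            for y in t1c:
                b = cm1[y]
                i = a & b
                if not i:
                    rel = DJ
                elif a == b:
                    rel = EQ
                elif i == a:
                    rel = LT
                elif i == b:
                    rel = GT
                else:
                    rel = OV
                relations[(x, y)] = rel
                sig.append(_REL_CODE[rel])
        return relations, bytes(sig)


# ---------------------------------------------------------------------------
# public operations


def candidate_regions(problem: AlignmentProblem) -> list[CandidateRegion]:
    """All (eligible-or-none, eligible-or-none) signatures except the dead
    (none, none); count is (e2+1)(e1+1) - 1."""
    enc = _Encoding(problem)
    slots2: list[Concept | None] = [None] + list(enc.elig2)
    slots1: list[Concept | None] = [None] + list(enc.elig1)
    return [
        CandidateRegion(a, b)
        for a in slots2
        for b in slots1
        if not (a is None and b is None)
    ]


def check_consistency(
    problem: AlignmentProblem,
) -> tuple[bool, frozenset[CandidateRegion] | None]:
    """Decide satisfiability; on success return a witness occupancy."""
    enc = _Encoding(problem)
    for empty, _hits in enc.branches():
        return True, enc.regions_of(enc.ALL & ~empty)
    return False, None


def _branch_worlds(enc: _Encoding, empty: int, must_hits: list[int],
                   worlds: dict, cap: int, node_cap: int) -> bool:
    """BFS over zone restrictions of one branch; returns True if exhausted."""
    f0 = enc.ALL & ~empty
    t2c, t1c = enc.problem.t2.concepts, enc.problem.t1.concepts
    seen = {f0}
    queue = deque([f0])
    nodes = 0
    exhausted = True
    while queue:
        f = queue.popleft()
        nodes += 1
        if nodes > node_cap:
            return False
        relations, sig = enc.induce(f)
        if sig not in worlds:
            if len(worlds) >= cap:
                return False
            worlds[sig] = World(relations, enc.regions_of(f))
        # regions pinned by a singleton must-hit can never be vacated;
        # if every free region is pinned, this branch has a unique model.
        forced = 0
        for h in must_hits:
            hf = h & f
            if hf and hf.bit_count() == 1:
                forced |= hf
        if f & ~forced == 0:
            continue
        for x in t2c:
            for y in t1c:
                for z in enc.zones(x, y):
                    zf = z & f
                    if zf == 0 or zf & forced:
                        continue
                    child = f & ~zf
                    if child in seen:
                        continue
                    seen.add(child)
                    if all(h & child for h in must_hits):
                        queue.append(child)
                    # an invalid restriction stays invalid under further
                    # restriction, so pruning here is complete
    return exhausted


def enumerate_worlds(
    problem: AlignmentProblem, cap: int | None = None, seed: int = 0
) -> tuple[list[World], bool]:
    """Enumerate distinct possible worlds, up to ``cap``.

    Worlds are identified by their induced cross-pair relation maps; many
    occupancies may realize the same world.  The search is fully
    deterministic (``seed`` is accepted for interface stability only).
    Returns (worlds, exhausted); ``exhausted`` is False when the cap or the
    internal node budget stopped the search early.
    """
    if cap is None:
        cap = problem.options.world_cap
    if cap < 1:
        raise ValueError("cap must be positive")
    enc = _Encoding(problem)
    worlds: dict[bytes, World] = {}
    exhausted = True
    any_branch = False
    node_cap = max(4096, 64 * cap)
    for empty, hits in enc.branches():
        any_branch = True
        if not _branch_worlds(enc, empty, hits, worlds, cap, node_cap):
            exhausted = False
            break
    if not any_branch:
        raise InconsistencyError(
            "input constraints are inconsistent; run diagnose() to find a "
            "minimal conflicting articulation subset"
        )
    return list(worlds.values()), exhausted


def compute_mir(
    problem: AlignmentProblem, cap: int | None = None, seed: int = 0
) -> MIRTable:
    """Compute the Maximally Informative Relation for every cross pair.

    If world enumeration exhausts under the cap, each cell is the union of
    the pair's relation over all worlds.  Otherwise a per-pair fallback asks,
    for each pair and base relation, whether the relation's witness pattern
    is satisfiable together with the branch constraints — exact even when
    enumeration was truncated.
    """
    worlds, exhausted = enumerate_worlds(problem, cap=cap, seed=seed)
    pairs = problem.cross_pairs()
    accum: dict[tuple[Concept, Concept], set[BaseRelation]] = {p: set() for p in pairs}
    for w in worlds:
        for p in pairs:
            accum[p].add(w.relations[p])

    if not exhausted:
        enc = _Encoding(problem)
        for empty, must_hits in enc.branches():
            f = enc.ALL & ~empty
            for x, y in pairs:
                got = accum[(x, y)]
                for rel in BaseRelation:
                    if rel in got:
                        continue
                    z, need = enc.pattern(rel, x, y)
                    rest = f & ~z
                    if all(h & rest for h in must_hits) and all(h & rest for h in need):
                        got.add(rel)

    cells = {p: RelationSet(rs) for p, rs in accum.items()}
    articulated = problem.articulated_pairs()
    provenance = {p: ("input" if p in articulated else "inferred") for p in pairs}
    return MIRTable(
        cells=cells,
        provenance=provenance,
        n_t2=len(problem.t2),
        n_t1=len(problem.t1),
        n_worlds=len(worlds),
        exhausted=exhausted,
    )


def diagnose(problem: AlignmentProblem) -> list[Articulation]:
    """Deletion-based minimal unsatisfiable articulation subset.

    Taxonomy structure is held fixed.  For a consistent problem the result
    is empty.  Otherwise the returned subset is unsatisfiable while every
    proper subset of it is satisfiable.
    """
    enc = _Encoding(problem)

    def satisfiable(arts: list[Articulation]) -> bool:
        for _ in enc.branches(arts):
            return True
        return False

    if satisfiable(problem.articulations):
        return []
    core = list(problem.articulations)
    for art in list(core):
        trial = [a for a in core if a is not art]
        if not satisfiable(trial):
            core = trial
    return core


def within_taxonomy_relation(tax: Taxonomy, a: Concept, b: Concept) -> BaseRelation:
    """Structural RCC-5 relation between two concepts of one taxonomy.

    An ancestor properly includes a descendant unless they are linked by a
    chain of monotypic, coverage-on concepts (then they are congruent);
    concepts in different subtrees are exclusive by sibling disjointness.
    These relations are derivable, hence not part of the MIR table.
    """
    if a is b:
        return BaseRelation.EQ

    def chain_congruent(anc: Concept, desc: Concept) -> bool:
        node = desc
        while node is not anc:
            parent = tax.parent(node)
            if parent is None:
                raise ValueError(f"{anc.label} is not an ancestor of {desc.label}")
            if len(tax.children(parent)) != 1 or not parent.coverage:
                return False
            node = parent
        return True

    if tax.is_ancestor_or_self(a, b):
        return BaseRelation.EQ if chain_congruent(a, b) else BaseRelation.GT
    if tax.is_ancestor_or_self(b, a):
        return BaseRelation.EQ if chain_congruent(b, a) else BaseRelation.LT
    return BaseRelation.DJ
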