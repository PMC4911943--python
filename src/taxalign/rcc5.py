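"""RCC-5 base relations on nonempty sets.

The five jointly-exhaustive, pairwise-disjoint relations between two
nonempty sets are congruence (``==``), proper inclusion (``>``), inverse
proper inclusion (``<``), overlap (``><``) and exclusion (``!``).  An
articulation may assert a disjunction of base relations; :class:`RelationSet`
models that.  The composition table used for propagation is shipped as data
and can be re-derived by brute force over a small universe with
:func:`derive_composition_table`.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable
from itertools import combinations

__all__ = [
    "BaseRelation",
    "RelationSet",
    "classify",
    "converse",
    "compose",
    "derive_composition_table",
    "COMPOSITION_TABLE",
]


class BaseRelation(enum.Enum):
    """One of the five RCC-5 base relations, read left-to-right.

    ``LT`` means the left set is properly included in the right one;
    ``GT`` is its converse.  ``EQ``, ``OV`` and ``DJ`` are self-converse.
    """

    EQ = "=="
    GT = ">"
    LT = "<"
    OV = "><"
    DJ = "!"

    @property
    def symbol(self) -> str:
        return self.value

    def converse(self) -> "BaseRelation":
        if self is BaseRelation.LT:
            return BaseRelation.GT
        if self is BaseRelation.GT:
            return BaseRelation.LT
        return self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.value}>"


#: canonical serialization order: ==, >, <, ><, !
RELATION_ORDER: tuple[BaseRelation, ...] = (
    BaseRelation.EQ,
    BaseRelation.GT,
    BaseRelation.LT,
    BaseRelation.OV,
    BaseRelation.DJ,
)

_SYMBOL_TO_RELATION = {r.value: r for r in BaseRelation}
# "|" is an accepted input alias for exclusion; "!" is always emitted.
_SYMBOL_TO_RELATION["|"] = BaseRelation.DJ

_NAME_TO_RELATION = {
    "equals": BaseRelation.EQ,
    "includes": BaseRelation.GT,
    "is_included_in": BaseRelation.LT,
    "overlaps": BaseRelation.OV,
    "disjoint": BaseRelation.DJ,
}
_RELATION_TO_NAME = {r: n for n, r in _NAME_TO_RELATION.items()}


class RelationSet(frozenset):
    """A nonempty set of base relations (a disjunctive articulation).

    Serializes in the fixed order ``==, >, <, ><, !``.
    """

    def __new__(cls, members: Iterable[BaseRelation]):
        members = frozenset(members)
        if not members:
            raise ValueError("a RelationSet must not be empty")
        for m in members:
            if not isinstance(m, BaseRelation):
                raise TypeError(f"not a BaseRelation: {m!r}")
        return super().__new__(cls, members)

    @classmethod
    def of(cls, *members: BaseRelation) -> "RelationSet":
        return cls(members)

    @classmethod
    def all(cls) -> "RelationSet":
        return cls(RELATION_ORDER)

    @classmethod
    def from_text(cls, text: str) -> "RelationSet":
        """Parse ``"=="``, ``"equals"`` or a brace form like ``"{> ><}"``."""
        text = text.strip()
        if text.startswith("{") and text.endswith("}"):
            tokens = text[1:-1].split()
        else:
            tokens = [text]
        members = []
        for tok in tokens:
            rel = _SYMBOL_TO_RELATION.get(tok) or _NAME_TO_RELATION.get(tok)
            if rel is None:
                raise ValueError(f"unknown RCC-5 relation token: {tok!r}")
            members.append(rel)
        return cls(members)

    @property
    def ordered(self) -> tuple[BaseRelation, ...]:
        return tuple(r for r in RELATION_ORDER if r in self)

    def to_symbols(self) -> str:
        """Symbolic text form: a bare symbol or ``{> ><}`` for disjunctions."""
        if len(self) == 1:
            return next(iter(self)).value
        return "{" + " ".join(r.value for r in self.ordered) + "}"

    def to_names(self) -> str:
        """Word form used by the alignment input dialect."""
        if len(self) == 1:
            return _RELATION_TO_NAME[next(iter(self))]
        return "{" + " ".join(_RELATION_TO_NAME[r] for r in self.ordered) + "}"

    def __repr__(self) -> str:
        return f"RelationSet({self.to_symbols()!r})"


def classify(x: frozenset | set, y: frozenset | set) -> BaseRelation:
    """Return the unique base relation holding between nonempty sets x and y."""
    if not x or not y:
        raise ValueError("RCC-5 relations are defined on nonempty sets only")
    x, y = set(x), set(y)
    if x == y:
        return BaseRelation.EQ
    if x < y:
        return BaseRelation.LT
    if x > y:
        return BaseRelation.GT
    if x.isdisjoint(y):
        return BaseRelation.DJ
    return BaseRelation.OV


def converse(r: RelationSet | BaseRelation) -> RelationSet:
    """Element-wise converse; an involution."""
    if isinstance(r, BaseRelation):
        return RelationSet.of(r.converse())
    return RelationSet(m.converse() for m in r)


def derive_composition_table(universe_size: int) -> dict:
    """Brute-force the 25-entry composition table over a finite universe.

    For each ordered pair (r, s) of base relations, enumerates every triple
    of nonempty subsets X, Y, Z of a ``universe_size``-element universe and
    records the relations of (X, Z) whenever X r Y and Y s Z.  The table is
    stable from size 6 onward, which is how the shipped table was produced.
    """
    if universe_size < 2:
        raise ValueError("universe_size must be >= 2")
    import numpy as np

    elems = range(universe_size)
    subsets = [frozenset(c) for k in range(1, universe_size + 1)
               for c in combinations(elems, k)]
    n = len(subsets)
    idx = {r: i for i, r in enumerate(RELATION_ORDER)}
    cls = np.empty((n, n), dtype=np.uint8)
    for i, a in enumerate(subsets):
        for j, b in enumerate(subsets):
            cls[i, j] = idx[classify(a, b)]
    seen = np.zeros((5, 5, 5), dtype=bool)
    # key trick: for each middle set Y, cross the column cls[:, y] with the
    # row cls[y, :]; every (r, s, t) combination realized gets marked.
    for y in range(n):
        r_col = cls[:, y]
        s_row = cls[y, :]
        t = cls  # t[x, z]
        key = (r_col[:, None].astype(np.int64) * 5 + s_row[None, :]) * 5 + t
        seen.reshape(-1)[np.unique(key)] = True
    table = {}
    for r in RELATION_ORDER:
        for s in RELATION_ORDER:
            members = [t for t in RELATION_ORDER if seen[idx[r], idx[s], idx[t]]]
            table[(r, s)] = RelationSet(members)
    return table


def _table_from_spec(spec: dict[tuple[str, str], str]) -> dict:
    return {
        (_SYMBOL_TO_RELATION[r], _SYMBOL_TO_RELATION[s]): RelationSet.from_text(t)
        for (r, s), t in spec.items()
    }


# Shipped table: equals derive_composition_table(6) (= size 7; regenerated in
# the test suite).  Row label composes first, column label second.
COMPOSITION_TABLE: dict[tuple[BaseRelation, BaseRelation], RelationSet] = _table_from_spec({
    ("==", "=="): "==",
    ("==", ">"): ">",
    ("==", "<"): "<",
    ("==", "><"): "><",
    ("==", "!"): "!",
    (">", "=="): ">",
    (">", ">"): ">",
    (">", "<"): "{== > < ><}",
    (">", "><"): "{> ><}",
    (">", "!"): "{> >< !}",
    ("<", "=="): "<",
    ("<", ">"): "{== > < >< !}",
    ("<", "<"): "<",
    ("<", "><"): "{< >< !}",
    ("<", "!"): "!",
    ("><", "=="): "><",
    ("><", ">"): "{> >< !}",
    ("><", "<"): "{< ><}",
    ("><", "><"): "{== > < >< !}",
    ("><", "!"): "{> >< !}",
    ("!", "=="): "!",
    ("!", ">"): "!",
    ("!", "<"): "{< >< !}",
    ("!", "><"): "{< >< !}",
    ("!", "!"): "{== > < >< !}",
})


def compose(r: BaseRelation, s: BaseRelation) -> RelationSet:
    """All base relations t for which sets X r Y, Y s Z, X t Z can coexist."""
    return COMPOSITION_TABLE[(r, s)]
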