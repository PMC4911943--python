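"""Domain model: taxonomic concepts, taxonomies, articulations, problems.

A *taxonomic concept* is a name as used according to a specific source
("name sec. author"); its qualified label is ``taxonomy_id.name``, e.g.
``1993.Microcebus_murinus``.  A taxonomy is a rooted forest of concepts
linked by parent/child (*is_a*) edges.  An articulation asserts an RCC-5
relation (possibly a disjunction) between one concept of the later taxonomy
(T2, always on the left) and one of the earlier taxonomy (T1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .rcc5 import RelationSet

__all__ = [
    "Concept",
    "Taxonomy",
    "Articulation",
    "AlignmentOptions",
    "AlignmentProblem",
    "ValidationError",
]


class ValidationError(ValueError):
    """A structural invariant of the domain model is violated."""


@dataclass(unsafe_hash=True)
class Concept:
    """A taxonomic concept, individuated by (taxonomy_id, name).

    ``coverage`` is the per-concept coverage flag: when True (the default),
    the concept's circumscription is exactly the union of its children; when
    False the concept may hold content beyond its children (an intensional
    reading).  ``rank`` defaults to "unranked" until a rank sidecar is
    attached.
    """

    taxonomy_id: str
    name: str
    rank: str = field(default="unranked", compare=False, hash=False)
    coverage: bool = field(default=True, compare=False, hash=False)

    @property
    def label(self) -> str:
        return f"{self.taxonomy_id}.{self.name}"

    def __repr__(self) -> str:
        return f"Concept({self.label})"


class Taxonomy:
    """A rooted forest of concepts with parent/child (is_a) edges."""

    def __init__(self, id: str, label: str = ""):
        self.id = id
        self.label = label or id
        self._by_name: dict[str, Concept] = {}
        self.parent_map: dict[Concept, Concept] = {}
        self._children: dict[Concept, list[Concept]] = {}

    # -- construction -------------------------------------------------
    def add_concept(self, name: str, coverage: bool = True) -> Concept:
        if name in self._by_name:
            raise ValidationError(f"duplicate concept name {name!r} in taxonomy {self.id}")
        if not name or any(ch.isspace() for ch in name):
            raise ValidationError(f"concept names must be whitespace-free tokens: {name!r}")
        c = Concept(self.id, name, coverage=coverage)
        self._by_name[name] = c
        self._children[c] = []
        return c

    def add_edge(self, parent: Concept, child: Concept) -> None:
        if child in self.parent_map:
            raise ValidationError(
                f"concept {child.label} already has parent "
                f"{self.parent_map[child].label}; trees allow exactly one"
            )
        self.parent_map[child] = parent
        self._children[parent].append(child)

    # -- access --------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Concept:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no concept {self.id}.{name}") from None

    def get(self, name: str) -> Concept | None:
        return self._by_name.get(name)

    @property
    def concepts(self) -> list[Concept]:
        """All concepts in declaration order."""
        return list(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def children(self, c: Concept) -> list[Concept]:
        return self._children[c]

    def parent(self, c: Concept) -> Concept | None:
        return self.parent_map.get(c)

    @property
    def roots(self) -> list[Concept]:
        return [c for c in self.concepts if c not in self.parent_map]

    def is_leaf(self, c: Concept) -> bool:
        return not self._children[c]

    def ancestors_or_self(self, c: Concept) -> list[Concept]:
        out = [c]
        while (p := self.parent_map.get(out[-1])) is not None:
            out.append(p)
        return out

    def descendants_or_self(self, c: Concept) -> list[Concept]:
        out = [c]
        stack = list(self._children[c])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        return out

    def is_ancestor_or_self(self, anc: Concept, desc: Concept) -> bool:
        return anc in self.ancestors_or_self(desc)

    def eligible_concepts(self) -> list[Concept]:
        """Concepts that may be the deepest container of an Euler region:
        leaves, plus internal concepts whose coverage flag is off."""
        return [c for c in self.concepts if self.is_leaf(c) or not c.coverage]

    def validate(self) -> None:
        if len(self) == 0:
            raise ValidationError(f"taxonomy {self.id} has no concepts")
        # acyclicity: walking up from each concept must terminate
        for c in self.concepts:
            seen = set()
            node: Concept | None = c
            while node is not None:
                if node in seen:
                    raise ValidationError(
                        f"cycle in parent/child lists of taxonomy {self.id} at {node.label}"
                    )
                seen.add(node)
                node = self.parent_map.get(node)

    def __repr__(self) -> str:
        return f"Taxonomy({self.id}, {len(self)} concepts)"


@dataclass(frozen=True)
class Articulation:
    """An RCC-5 statement between a T2 concept (left) and a T1 concept."""

    left: Concept
    relation: RelationSet
    right: Concept
    label: str = ""

    def __str__(self) -> str:
        return f"[{self.left.label} {self.relation.to_symbols()} {self.right.label}]"


@dataclass
class AlignmentOptions:
    sibling_disjointness: bool = True
    world_cap: int = 256


class AlignmentProblem:
    """Two taxonomies (T2 later, T1 earlier), articulations, and options."""

    def __init__(
        self,
        t2: Taxonomy,
        t1: Taxonomy,
        articulations: list[Articulation] | None = None,
        options: AlignmentOptions | None = None,
    ):
        self.t2 = t2
        self.t1 = t1
        self.articulations: list[Articulation] = list(articulations or [])
        self.options = options or AlignmentOptions()
        self.validate()

    def validate(self) -> None:
        if self.t2.id == self.t1.id:
            raise ValidationError("the two taxonomies must have distinct ids")
        self.t2.validate()
        self.t1.validate()
        for a in self.articulations:
            if a.left.taxonomy_id != self.t2.id or a.right.taxonomy_id != self.t1.id:
                raise ValidationError(
                    f"articulation {a} must relate a {self.t2.id} (T2) concept "
                    f"to a {self.t1.id} (T1) concept, in that order"
                )
            for tax, side in ((self.t2, a.left), (self.t1, a.right)):
                if tax.get(side.name) is not side:
                    raise ValidationError(f"articulation endpoint {side.label} is not in {tax.id}")

    def add_articulation(self, art: Articulation) -> None:
        self.articulations.append(art)

    def cross_pairs(self) -> list[tuple[Concept, Concept]]:
        """All |C2| x |C1| cross-taxonomy concept pairs, declaration order."""
        return [(x, y) for x in self.t2.concepts for y in self.t1.concepts]

    def articulated_pairs(self) -> set[tuple[Concept, Concept]]:
        return {(a.left, a.right) for a in self.articulations}

    def __repr__(self) -> str:
        return (
            f"AlignmentProblem(T2={self.t2.id}:{len(self.t2)} concepts, "
            f"T1={self.t1.id}:{len(self.t1)}, {len(self.articulations)} articulations)"
        )
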