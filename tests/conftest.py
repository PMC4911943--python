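"""Shared fixtures and small-problem builders."""

from __future__ import annotations

import random

import pytest

from taxalign.model import AlignmentProblem, Articulation, Taxonomy
from taxalign.rcc5 import RELATION_ORDER, RelationSet
from taxalign.fixtures import fixture_fig1


def build_tax(tid: str, edges: dict[str, list[str]], nocoverage: set[str] = frozenset()) -> Taxonomy:
    """Taxonomy from a parent -> children mapping; concepts auto-created."""
    tax = Taxonomy(tid)
    for parent, children in edges.items():
        p = tax.get(parent) or tax.add_concept(parent)
        for child in children:
            c = tax.get(child) or tax.add_concept(child)
            tax.add_edge(p, c)
    for name in nocoverage:
        tax[name].coverage = False
    tax.validate()
    return tax


def random_small_problem(seed: int) -> AlignmentProblem:
    """Random pair with at most 3 leaves per taxonomy and <= 20 candidate
    regions, with 0-3 random (possibly disjunctive) articulations."""
    rng = random.Random(seed)
    taxa = []
    for tid in ("a", "b"):
        tax = Taxonomy(tid)
        root = tax.add_concept("R")
        n_leaves = rng.randint(1, 3)
        for i in range(n_leaves):
            tax.add_edge(root, tax.add_concept(f"L{i}"))
        # a coverage-off root is eligible itself; keep the region count <= 20
        if n_leaves <= 2 and rng.random() < 0.3:
            root.coverage = False
        taxa.append(tax)
    t2, t1 = taxa
    pairs = [(x, y) for x in t2.concepts for y in t1.concepts]
    rng.shuffle(pairs)
    arts = [
        Articulation(x, RelationSet(rng.sample(RELATION_ORDER, rng.choice([1, 1, 1, 2]))), y)
        for x, y in pairs[: rng.randint(0, 3)]
    ]
    return AlignmentProblem(t2, t1, arts)


def world_key(world) -> tuple:
    """Hashable identity of a world: its full cross-pair relation map."""
    return tuple(sorted((x.label, y.label, r.value) for (x, y), r in world.relations.items()))


@pytest.fixture
def fig1() -> AlignmentProblem:
    return fixture_fig1()
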