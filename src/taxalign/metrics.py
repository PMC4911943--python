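"""Quantitative name:meaning analyses of a computed alignment.

Measures how taxonomic names track taxonomic meanings across the two
treatments: relation tallies over the MIR, the information-expression
ratio (MIR cells per input articulation), relative congruence (congruent
cells per concept of the concept-poorer taxonomy), per-rank name:meaning
categories, and the reliable:unreliable name ratio.

A *reliable* name is a same-rank concept pair that is taxonomically
congruent (==) under an identical name string; every other counted pairing
(congruent but renamed, or same-named but narrowed/widened/overlapping)
is unreliable.  All percentages and ratios print with one decimal,
rounding half away from zero like the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import Taxonomy, ValidationError
from .rcc5 import BaseRelation
from .reasoner import MIRTable, World

__all__ = [
    "CATEGORIES",
    "MetricsReport",
    "tally_relations",
    "expression_ratio",
    "relative_congruence",
    "name_meaning_table",
    "reliability_ratio",
    "compute_metrics",
]

#: the five name:meaning categories; "=" means identical name strings
CATEGORIES = ("==:=", "==:≠", ">:=", "<:=", "><:=")

_REL_TO_CATEGORY = {
    BaseRelation.GT: ">:=",
    BaseRelation.LT: "<:=",
    BaseRelation.OV: "><:=",
}


def _round1(value: float) -> float:
    """One decimal, half away from zero (printed-table style)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tally_relations(mir: MIRTable) -> dict[str, int]:
    """Count singleton MIR cells per relation; disjunctive cells are tallied
    separately as "ambiguous".  Tallies sum to |C2| x |C1|."""
    out = {r.value: 0 for r in BaseRelation}
    out["ambiguous"] = 0
    for relset in mir.cells.values():
        if len(relset) == 1:
            out[next(iter(relset)).value] += 1
        else:
            out["ambiguous"] += 1
    return out


def expression_ratio(mir_count: int, articulation_count: int) -> float | None:
    """MIR cells per input articulation, one decimal; None when undefined
    (no input articulations)."""
    if articulation_count < 1:
        return None
    return _round1(mir_count / articulation_count)


def relative_congruence(mir: MIRTable, poorer_concept_count: int) -> float:
    """Percent of the concept-poorer taxonomy matched by a congruent cell.

    May exceed 100 when the concept-richer taxonomy holds redundant
    (monotypic-chain) concepts, each congruent with the same counterpart.
    """
    if poorer_concept_count < 1:
        raise ValueError("poorer_concept_count must be >= 1")
    n_eq = sum(
        1 for rs in mir.cells.values() if len(rs) == 1 and BaseRelation.EQ in rs
    )
    return _round1(100.0 * n_eq / poorer_concept_count)


def name_meaning_table(
    mir: MIRTable, t2: Taxonomy, t1: Taxonomy, world: World | None = None
) -> dict[str, dict[str, int]]:
    """Per-rank counts of the five name:meaning categories.

    Only ranks present in both taxonomies are tabulated (rank labels
    compared case-insensitively after trimming); a pair is counted only
    when it is congruent and/or carries the same name string.  Exclusion
    under an identical name cannot occur in homonym-free inputs and is
    asserted absent.  Ambiguous cells require a chosen ``world``.
    """
    if all(c.rank == "unranked" for c in t2.concepts + t1.concepts):
        raise ValidationError(
            "no ranks attached; load a rank sidecar with attach_ranks() first"
        )

    def norm(rank: str) -> str:
        return rank.strip().lower()

    shared = {norm(c.rank) for c in t2.concepts} & {norm(c.rank) for c in t1.concepts}
    shared.discard("unranked")

    if world is not None:
        relmap = dict(world.relations)
    else:
        relmap = mir.singleton_cells()

    table: dict[str, dict[str, int]] = {}
    for (x, y), relset in mir.cells.items():
        rank = norm(x.rank)
        if rank != norm(y.rank) or rank not in shared:
            continue
        rel = relmap.get((x, y))
        if rel is None:
            raise ValidationError(
                f"ambiguous cell ({x.label}, {y.label}) = {relset.to_symbols()}; "
                "pass a chosen world to classify it"
            )
        same_name = x.name == y.name
        if rel is BaseRelation.EQ:
            cat = "==:=" if same_name else "==:≠"
        elif same_name and rel in _REL_TO_CATEGORY:
            cat = _REL_TO_CATEGORY[rel]
        elif same_name and rel is BaseRelation.DJ:
            raise ValidationError(
                f"exclusion under the identical name {x.label} / {y.label}: "
                "inputs contain a homonym, which this analysis assumes absent"
            )
        else:
            continue  # different name and not congruent: not counted
        row = table.setdefault(rank, dict.fromkeys(CATEGORIES, 0))
        row[cat] += 1
    return table


def reliability_ratio(
    table: dict[str, dict[str, int]] | int, unreliable: int | None = None
) -> tuple[int, int, str]:
    """(reliable, unreliable, normalized ratio text).

    Reliable is the total of ==:=; unreliable totals the other four
    categories; the text normalizes the smaller side to 1.  Accepts either
    a per-rank category table or the two raw counts.
    """
    if isinstance(table, dict):
        reliable = sum(row.get("==:=", 0) for row in table.values())
        unreliable = sum(
            row.get(cat, 0) for row in table.values() for cat in CATEGORIES[1:]
        )
    else:
        reliable = table
        if unreliable is None:
            raise TypeError("reliability_ratio(reliable, unreliable) needs both counts")
    if reliable == 0 and unreliable == 0:
        text = "0 : 0"  # nothing to compare
    elif reliable == unreliable:
        text = "1 : 1"
    elif reliable > unreliable:
        text = f"{_round1(reliable / max(unreliable, 1))} : 1" if unreliable else "1 : 0"
    else:
        text = f"1 : {_round1(unreliable / max(reliable, 1))}" if reliable else "0 : 1"
    return reliable, unreliable, text


@dataclass
class MetricsReport:
    """Bundle of all alignment metrics, with tabular serializations."""

    tallies: dict[str, int]
    n_articulations: int
    expression: float | None
    relative_congruence: float
    name_meaning: dict[str, dict[str, int]]
    reliable: int
    unreliable: int
    reliability: str

    def tally_frame(self) -> pd.DataFrame:
        order = [r.value for r in BaseRelation] + ["ambiguous"]
        return pd.DataFrame(
            [[self.tallies[k] for k in order]], columns=order, index=["MIR"]
        )

    def name_meaning_frame(self) -> pd.DataFrame:
        rows = {
            rank: [row[c] for c in CATEGORIES]
            for rank, row in sorted(self.name_meaning.items())
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))

    def summary_text(self) -> str:
        total = sum(self.tallies.values())
        expr = "undefined" if self.expression is None else f"{self.expression}x"
        lines = [
            f"MIR cells: {total} ({self.tallies['ambiguous']} ambiguous)",
            f"input articulations: {self.n_articulations}",
            f"information expression ratio: {expr}",
            f"relative congruence: {self.relative_congruence}%",
            f"reliable names: {self.reliable}",
            f"unreliable names: {self.unreliable}",
            f"reliability ratio: {self.reliability}",
        ]
        return "\n".join(lines) + "\n"


def compute_metrics(
    mir: MIRTable,
    t2: Taxonomy,
    t1: Taxonomy,
    n_articulations: int,
    world: World | None = None,
    with_name_meaning: bool = True,
) -> MetricsReport:
    """Assemble the full report from a computed MIR table."""
    tallies = tally_relations(mir)
    poorer = min(mir.n_t2, mir.n_t1)
    if with_name_meaning:
        nm = name_meaning_table(mir, t2, t1, world=world)
    else:
        nm = {}
    reliable, unreliable, ratio_text = reliability_ratio(nm)
    return MetricsReport(
        tallies=tallies,
        n_articulations=n_articulations,
        expression=expression_ratio(len(mir.cells), n_articulations),
        relative_congruence=relative_congruence(mir, poorer),
        name_meaning=nm,
        reliable=reliable,
        unreliable=unreliable,
        reliability=ratio_text,
    )
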