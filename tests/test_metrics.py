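"""Name:meaning metrics: tallies, ratios, categories, reliability."""

import pytest

from conftest import build_tax
from taxalign.fixtures import fixture_fig1_ranks
from taxalign.io import attach_ranks
from taxalign.model import AlignmentProblem, Articulation, ValidationError
from taxalign.metrics import (
    compute_metrics,
    expression_ratio,
    name_meaning_table,
    relative_congruence,
    reliability_ratio,
    tally_relations,
)
from taxalign.rcc5 import BaseRelation, RelationSet
from taxalign.reasoner import compute_mir, enumerate_worlds

R = BaseRelation


def test_fig1_tallies(fig1):
    tallies = tally_relations(compute_mir(fig1))
    assert tallies == {
        "==": 3, ">": 1, "<": 9, "><": 1, "!": 29, "ambiguous": 1,
    }
    assert sum(tallies.values()) == 44


def test_tally_conservation_identity_alignment():
    t2 = build_tax("a", {"R": ["u", "v", "w"]})
    t1 = build_tax("b", {"R": ["u", "v", "w"]})
    arts = [Articulation(t2[n], RelationSet.of(R.EQ), t1[n]) for n in "uvw"]
    tallies = tally_relations(compute_mir(AlignmentProblem(t2, t1, arts)))
    assert tallies["ambiguous"] == 0
    assert tallies["=="] == 4          # three leaves plus the two roots
    assert sum(tallies.values()) == 16


@pytest.mark.parametrize(
    "mir_count, art_count, expected",
    [(153111, 402, 380.9), (736, 23, 32.0), (44, 9, 4.9)],
)
def test_expression_ratio_printed_values(mir_count, art_count, expected):
    assert expression_ratio(mir_count, art_count) == expected


def test_expression_ratio_undefined_without_articulations():
    assert expression_ratio(25, 0) is None


class _FakeMIR:
    """Minimal stand-in (synthetic) carrying only EQ-singleton counts."""

    def __init__(self, n_eq, n_other):
        eq = RelationSet.of(R.EQ)
        dj = RelationSet.of(R.DJ)
        self.cells = {("x", i): eq for i in range(n_eq)}
        self.cells.update({("y", i): dj for i in range(n_other)})


@pytest.mark.parametrize(
    "n_eq, poorer, expected",
    [(74, 77, 96.1), (98, 114, 86.0), (0, 9, 0.0)],
)
def test_relative_congruence_printed_values(n_eq, poorer, expected):
    assert relative_congruence(_FakeMIR(n_eq, 5), poorer) == expected


def test_relative_congruence_may_exceed_hundred():
    assert relative_congruence(_FakeMIR(24, 0), 23) == 104.3


def test_fig1_name_meaning_categories(fig1):
    attach_ranks(fig1, fixture_fig1_ranks())
    worlds, _ = enumerate_worlds(fig1)
    mir = compute_mir(fig1)
    ov_world = next(
        w for w in worlds
        if w.relations[(fig1.t2["Microcebus"], fig1.t1["Microcebus_murinus"])] is R.OV
    )
    table = name_meaning_table(mir, fig1.t2, fig1.t1, world=ov_world)
    assert table["species"] == {"==:=": 1, "==:≠": 1, ">:=": 0, "<:=": 1, "><:=": 0}
    assert table["genus"] == {"==:=": 0, "==:≠": 0, ">:=": 0, "<:=": 0, "><:=": 1}


def test_name_meaning_requires_ranks(fig1):
    mir = compute_mir(fig1)
    with pytest.raises(ValidationError) as err:
        name_meaning_table(mir, fig1.t2, fig1.t1)
    assert "attach_ranks" in str(err.value)


def test_identical_taxonomies_all_reliable():
    t2 = build_tax("a", {"R": ["u", "v"]})
    t1 = build_tax("b", {"R": ["u", "v"]})
    arts = [Articulation(t2[n], RelationSet.of(R.EQ), t1[n]) for n in ("u", "v")]
    problem = AlignmentProblem(t2, t1, arts)
    for c in t2.concepts + t1.concepts:
        c.rank = "genus" if c.name == "R" else "species"
    table = name_meaning_table(compute_mir(problem), t2, t1)
    assert table == {
        "genus": {"==:=": 1, "==:≠": 0, ">:=": 0, "<:=": 0, "><:=": 0},
        "species": {"==:=": 2, "==:≠": 0, ">:=": 0, "<:=": 0, "><:=": 0},
    }
    assert reliability_ratio(table) == (3, 0, "1 : 0")


def test_narrowed_homonym_counts_inverse_inclusion():
    """k narrowed concepts below one old concept yield k inverse inclusions
    but only one same-name category entry (the homonymous child)."""
    t2 = build_tax("a", {"R": ["u", "u_sp1", "u_sp2"]})
    t1 = build_tax("b", {"R": ["u"]})
    arts = [
        Articulation(t2[n], RelationSet.of(R.LT), t1["u"])
        for n in ("u", "u_sp1", "u_sp2")
    ] + [Articulation(t2["R"], RelationSet.of(R.EQ), t1["R"])]
    problem = AlignmentProblem(t2, t1, arts)
    for c in t2.concepts + t1.concepts:
        c.rank = "genus" if c.name == "R" else "species"
    mir = compute_mir(problem)
    narrowed_column = [
        rs for (x, y), rs in mir.cells.items()
        if y.name == "u" and rs == RelationSet.of(R.LT)
    ]
    assert len(narrowed_column) == 3
    table = name_meaning_table(mir, t2, t1)
    assert table["species"]["<:="] == 1


@pytest.mark.parametrize(
    "reliable, unreliable, expected",
    [(203, 97, "2.1 : 1"), (8, 12, "1 : 1.5"), (14, 14, "1 : 1")],
)
def test_reliability_ratio_printed_values(reliable, unreliable, expected):
    assert reliability_ratio(reliable, unreliable)[2] == expected


def test_reliability_ratio_degenerate_cases():
    assert reliability_ratio(0, 0)[2] == "0 : 0"
    assert reliability_ratio(0, 7)[2] == "0 : 1"


def test_compute_metrics_bundles_fig1(fig1):
    attach_ranks(fig1, fixture_fig1_ranks())
    worlds, _ = enumerate_worlds(fig1)
    mir = compute_mir(fig1)
    report = compute_metrics(mir, fig1.t2, fig1.t1, 9, world=worlds[0])
    assert report.expression == 4.9
    assert report.relative_congruence == 75.0   # 3 congruent cells / 4 concepts
    assert report.reliable + report.unreliable == 4
    assert "reliability ratio" in report.summary_text()
    assert list(report.tally_frame().columns) == ["==", ">", "<", "><", "!", "ambiguous"]
    assert report.name_meaning_frame().loc["species", "<:="] == 1
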