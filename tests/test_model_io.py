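"""Domain model invariants and the text/CSV readers and writers."""

import pytest

from taxalign.io import (
    ParseError,
    attach_ranks,
    parse_alignment,
    read_mir_csv,
    read_rank_table,
    write_alignment,
    write_mir_csv,
)
from taxalign.model import AlignmentProblem, Articulation, Taxonomy, ValidationError
from taxalign.rcc5 import BaseRelation, RelationSet
from taxalign.reasoner import compute_mir
from taxalign.fixtures import fixture_fig1, fixture_fig1_ranks

MINIMAL = """
taxonomy a left
taxonomy b right
articulation demo a-b
[a.X equals b.Y]
"""


def test_taxonomy_rejects_duplicates_and_double_parents():
    tax = Taxonomy("t")
    tax.add_concept("A")
    with pytest.raises(ValidationError):
        tax.add_concept("A")
    b, c = tax.add_concept("B"), tax.add_concept("C")
    tax.add_edge(tax["A"], b)
    with pytest.raises(ValidationError):
        tax.add_edge(c, b)


def test_problem_requires_t2_t1_orientation():
    t2, t1 = Taxonomy("x"), Taxonomy("y")
    a, b = t2.add_concept("A"), t1.add_concept("B")
    with pytest.raises(ValidationError):
        AlignmentProblem(t2, t1, [Articulation(b, RelationSet.of(BaseRelation.EQ), a)])


def test_parse_minimal_single_concepts():
    text = MINIMAL.replace("taxonomy a left", "taxonomy a left\n(X)").replace(
        "taxonomy b right", "taxonomy b right\n(Y)"
    )
    problem = parse_alignment(text)
    assert len(problem.t2) == 1 and len(problem.t1) == 1
    assert len(problem.articulations) == 1
    assert problem.articulations[0].relation == RelationSet.of(BaseRelation.EQ)


def test_parse_fig1_counts_via_roundtrip(fig1):
    problem = parse_alignment(write_alignment(fig1))
    assert len(problem.t2) == 11 and len(problem.t1) == 4
    assert len(problem.articulations) == 9
    assert [c.name for c in problem.t2.concepts] == [c.name for c in fig1.t2.concepts]
    assert problem.t2.parent_map.keys() == {
        problem.t2[c.name] for c in fig1.t2.parent_map
    }
    assert [
        (a.left.label, a.relation.to_symbols(), a.right.label)
        for a in problem.articulations
    ] == [
        (a.left.label, a.relation.to_symbols(), a.right.label)
        for a in fig1.articulations
    ]
    # second round trip is byte-stable
    assert write_alignment(problem) == write_alignment(fig1)


def test_parse_disjunction_and_nocoverage_roundtrip(fig1):
    fig1.t2["Microcebus"].coverage = False
    fig1.articulations[0] = Articulation(
        fig1.articulations[0].left,
        RelationSet.of(BaseRelation.EQ, BaseRelation.OV),
        fig1.articulations[0].right,
        "fig1",
    )
    text = write_alignment(fig1)
    assert "{equals overlaps}" in text
    assert "nocoverage 2005.Microcebus" in text
    again = parse_alignment(text)
    assert not again.t2["Microcebus"].coverage
    assert again.articulations[0].relation == RelationSet.of(BaseRelation.EQ, BaseRelation.OV)


def test_empty_articulation_block_roundtrip():
    t2, t1 = Taxonomy("a"), Taxonomy("b")
    t2.add_concept("X"), t1.add_concept("Y")
    problem = AlignmentProblem(t2, t1, [])
    again = parse_alignment(write_alignment(problem))
    assert again.articulations == []


@pytest.mark.parametrize(
    "mangle, fragment",
    [
        (lambda t: t.replace("(Mirza Mirza_coquereli)", "(Microcebus Mirza)"),
         "duplicate parent"),
        (lambda t: t + "[2005.Nonexistens equals 1993.Microcebus]\n", "unknown concept"),
        (lambda t: t + "[2005.Microcebus bogus_rel 1993.Microcebus]\n", "unknown RCC-5"),
        (lambda t: t.replace("articulation fig1 2005-1993",
                             "articulation fig1 2005-1993\n[1993.Microcebus equals 2005.Microcebus]"),
         "must run T2-T1"),
    ],
)
def test_parse_errors_are_line_numbered(fig1, mangle, fragment):
    text = mangle(write_alignment(fig1))
    with pytest.raises(ParseError) as err:
        parse_alignment(text)
    assert fragment in str(err.value)
    assert err.value.line is not None


def test_parse_detects_cycle():
    text = "taxonomy a A\n(X Y)\n(Y X)\ntaxonomy b B\n(Z)\narticulation l a-b\n"
    with pytest.raises(ParseError) as err:
        parse_alignment(text)
    msg = str(err.value)
    assert "cycle" in msg or "already has parent" in msg


def test_t2_directive_overrides_block_order():
    text = (
        "taxonomy b earlier\n(Y)\n"
        "taxonomy a later\n(X)\n"
        "t2 a\n"
        "articulation demo a-b\n[a.X equals b.Y]\n"
    )
    problem = parse_alignment(text)
    assert problem.t2.id == "a" and problem.t1.id == "b"


def test_attach_ranks_and_errors(fig1):
    attach_ranks(fig1, fixture_fig1_ranks())
    assert fig1.t2["Microcebus"].rank == "genus"
    assert fig1.t1["Microcebus_murinus"].rank == "species"
    with pytest.raises(ValidationError) as err:
        attach_ranks(fig1, [("2005", "Nonexistens", "species")])
    assert "2005.Nonexistens" in str(err.value)


def test_attach_ranks_empty_table_keeps_unranked(fig1):
    attach_ranks(fig1, read_rank_table(""))
    assert all(c.rank == "unranked" for c in fig1.t2.concepts)


def test_mir_csv_fig1_rows_and_roundtrip(fig1):
    mir = compute_mir(fig1)
    text = write_mir_csv(mir)
    rows = read_mir_csv(text)
    assert len(rows) == 44
    assert [r[:2] for r in rows] == sorted(r[:2] for r in rows)
    by_pair = {(a, b): rs for a, b, rs, _ in rows}
    assert by_pair[("2005.Microcebus", "1993.Microcebus_murinus")].to_symbols() == "{> ><}"
    prov = {(a, b): p for a, b, _, p in rows}
    assert prov[("2005.Microcebus_rufus", "1993.Microcebus_rufus")] == "input"
    assert prov[("2005.Microcebus", "1993.Microcebus")] == "inferred"


def test_mir_csv_minimal_problem():
    t2, t1 = Taxonomy("a"), Taxonomy("b")
    x, y = t2.add_concept("X"), t1.add_concept("Y")
    problem = AlignmentProblem(t2, t1, [Articulation(x, RelationSet.of(BaseRelation.EQ), y)])
    text = write_mir_csv(compute_mir(problem))
    assert text.splitlines() == [
        "taxon2,taxon1,relation,provenance",
        "a.X,b.Y,==,input",
    ]


def test_mir_csv_rejects_incomplete_table(fig1):
    mir = compute_mir(fig1)
    mir.cells.pop(next(iter(mir.cells)))
    with pytest.raises(ValidationError):
        write_mir_csv(mir)
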