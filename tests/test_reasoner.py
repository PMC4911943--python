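"""Consistency, possible worlds, MIR and diagnosis."""

import pytest

from conftest import build_tax
from taxalign.model import AlignmentProblem, Articulation
from taxalign.rcc5 import BaseRelation, RelationSet
from taxalign.reasoner import (
    InconsistencyError,
    candidate_regions,
    check_consistency,
    compute_mir,
    diagnose,
    enumerate_worlds,
    within_taxonomy_relation,
)

R = BaseRelation


def one_by_one(relations=None):
    t2 = build_tax("a", {"X": []})
    t1 = build_tax("b", {"Y": []})
    arts = []
    if relations:
        arts = [Articulation(t2["X"], RelationSet(relations), t1["Y"])]
    return AlignmentProblem(t2, t1, arts)


# -- candidate regions ----------------------------------------------------

def test_region_count_fig1(fig1):
    assert len(candidate_regions(fig1)) == 39  # (9+1)(3+1)-1


def test_region_count_minimal():
    assert len(candidate_regions(one_by_one())) == 3  # (1+1)(1+1)-1


def test_region_count_with_coverage_off(fig1):
    fig1.t2["Microcebus"].coverage = False  # the genus becomes eligible too
    assert len(candidate_regions(fig1)) == 43  # (10+1)(3+1)-1


# -- consistency ----------------------------------------------------------

def test_fig1_is_consistent(fig1):
    ok, witness = check_consistency(fig1)
    assert ok and witness


def test_1x1_disjoint_is_satisfiable():
    ok, witness = check_consistency(one_by_one([R.DJ]))
    assert ok
    labels = {(r.deepest_t2 and r.deepest_t2.name, r.deepest_t1 and r.deepest_t1.name)
              for r in witness}
    assert ("X", None) in labels and (None, "Y") in labels


def test_contradictory_pair_is_unsatisfiable():
    problem = one_by_one()
    x, y = problem.t2["X"], problem.t1["Y"]
    problem.articulations = [
        Articulation(x, RelationSet.of(R.EQ), y),
        Articulation(x, RelationSet.of(R.DJ), y),
    ]
    assert check_consistency(problem) == (False, None)


def test_fig1_plus_impossible_congruence_is_inconsistent(fig1):
    # berthae is excluded from the whole 1993 genus, so it cannot equal rufus
    fig1.add_articulation(Articulation(
        fig1.t2["Microcebus_berthae"], RelationSet.of(R.EQ), fig1.t1["Microcebus_rufus"]
    ))
    assert not check_consistency(fig1)[0]
    with pytest.raises(InconsistencyError):
        enumerate_worlds(fig1)


def test_sibling_disjointness_off_is_rejected(fig1):
    fig1.options.sibling_disjointness = False
    with pytest.raises(ValueError):
        check_consistency(fig1)


# -- worlds ---------------------------------------------------------------

def test_fig1_has_exactly_two_worlds(fig1):
    worlds, exhausted = enumerate_worlds(fig1)
    assert exhausted and len(worlds) == 2
    genus2, murinus1 = fig1.t2["Microcebus"], fig1.t1["Microcebus_murinus"]
    cells = {w.relations[(genus2, murinus1)] for w in worlds}
    assert cells == {R.GT, R.OV}  # the only unforced pair
    # every other pair is forced
    for pair in fig1.cross_pairs():
        if pair != (genus2, murinus1):
            assert len({w.relations[pair] for w in worlds}) == 1


def test_identity_alignment_single_world():
    t2 = build_tax("a", {"R": ["u", "v"]})
    t1 = build_tax("b", {"R": ["u", "v"]})
    arts = [Articulation(t2[n], RelationSet.of(R.EQ), t1[n]) for n in ("u", "v")]
    worlds, exhausted = enumerate_worlds(AlignmentProblem(t2, t1, arts))
    assert exhausted and len(worlds) == 1
    w = worlds[0].relations
    assert w[(t2["u"], t1["u"])] is R.EQ
    assert w[(t2["R"], t1["R"])] is R.EQ
    assert w[(t2["u"], t1["v"])] is R.DJ


def test_unarticulated_1x1_has_five_worlds():
    worlds, exhausted = enumerate_worlds(one_by_one())
    assert exhausted
    assert {next(iter(w.relations.values())) for w in worlds} == set(R)


def test_world_cap_reports_truncation():
    worlds, exhausted = enumerate_worlds(one_by_one(), cap=3)
    assert not exhausted and len(worlds) == 3


def test_deterministic_world_order(fig1):
    first = [sorted((x.label, y.label, r.value) for (x, y), r in w.relations.items())
             for w in enumerate_worlds(fig1)[0]]
    second = [sorted((x.label, y.label, r.value) for (x, y), r in w.relations.items())
              for w in enumerate_worlds(fig1)[0]]
    assert first == second


# -- MIR ------------------------------------------------------------------

def test_fig1_mir_cells_and_tallies(fig1):
    mir = compute_mir(fig1)
    assert len(mir.cells) == 44 == mir.n_t2 * mir.n_t1
    singles = mir.singleton_cells()
    from collections import Counter
    tally = Counter(r for r in singles.values())
    assert tally == {R.DJ: 29, R.LT: 9, R.EQ: 3, R.GT: 1, R.OV: 1}
    amb = mir.ambiguous_cells()
    assert len(amb) == 1
    ((x, y), rs), = amb.items()
    assert (x.label, y.label) == ("2005.Microcebus", "1993.Microcebus_murinus")
    assert rs == RelationSet.of(R.GT, R.OV)


def test_fig1_monotypic_congruence_rows_identical(fig1):
    """A monotypic genus is congruent with its only child under coverage,
    so their MIR rows coincide."""
    mir = compute_mir(fig1)
    mirza, mirza_c = fig1.t2["Mirza"], fig1.t2["Mirza_coquereli"]
    for y in fig1.t1.concepts:
        assert mir.cells[(mirza, y)] == mir.cells[(mirza_c, y)]
    assert mir.cells[(mirza, fig1.t1["Microcebus_coquereli"])] == RelationSet.of(R.EQ)


def test_mir_respects_input_articulations(fig1):
    mir = compute_mir(fig1)
    for art in fig1.articulations:
        cell = mir.cells[(art.left, art.right)]
        assert cell <= art.relation and len(cell) >= 1
        assert mir.provenance[(art.left, art.right)] == "input"


def test_all_singletons_iff_single_world():
    t2 = build_tax("a", {"R": ["u", "v"]})
    t1 = build_tax("b", {"R": ["u", "v"]})
    arts = [Articulation(t2[n], RelationSet.of(R.EQ), t1[n]) for n in ("u", "v")]
    problem = AlignmentProblem(t2, t1, arts)
    mir = compute_mir(problem)
    assert mir.n_worlds == 1 and not mir.ambiguous_cells()


def test_mir_fallback_agrees_with_enumeration():
    """Truncated enumeration plus per-pair queries equals the exhaustive
    union over worlds."""
    problem = one_by_one()
    full = compute_mir(problem, cap=16)
    truncated = compute_mir(problem, cap=2)  # 5 worlds exist: cap forces fallback
    assert not truncated.exhausted and full.exhausted
    assert truncated.cells == full.cells


def test_congruence_substitutivity(fig1):
    """EQ-singleton partners have identical MIR columns."""
    mir = compute_mir(fig1)
    for (x, y), rs in mir.cells.items():
        if rs == RelationSet.of(R.EQ):
            for (x2, y2), rs2 in mir.cells.items():
                if x2 is x and rs2 == RelationSet.of(R.EQ):
                    for x3 in fig1.t2.concepts:
                        assert mir.cells[(x3, y)] == mir.cells[(x3, y2)]


def test_root_propagation_with_coverage():
    """A later leaf exclusive of the earlier root forces the later root to
    properly include or overlap the earlier root."""
    t2 = build_tax("a", {"R": ["u", "n"]})
    t1 = build_tax("b", {"R": ["u"]})
    arts = [
        Articulation(t2["u"], RelationSet.of(R.EQ), t1["u"]),
        Articulation(t2["n"], RelationSet.of(R.DJ), t1["R"]),
    ]
    mir = compute_mir(AlignmentProblem(t2, t1, arts))
    assert mir.cells[(t2["R"], t1["R"])] <= RelationSet.of(R.GT, R.OV)


# -- diagnosis ------------------------------------------------------------

def test_diagnose_consistent_is_empty(fig1):
    assert diagnose(fig1) == []


def test_diagnose_minimal_core_fig1(fig1):
    extra = Articulation(
        fig1.t2["Microcebus_berthae"], RelationSet.of(R.EQ), fig1.t1["Microcebus_rufus"]
    )
    fig1.add_articulation(extra)
    core = diagnose(fig1)
    assert extra in core
    assert len(core) >= 2  # the contradiction needs at least one partner
    # minimality: every proper subset is satisfiable
    sub = AlignmentProblem(fig1.t2, fig1.t1, [])
    for leave_out in core:
        sub.articulations = [a for a in core if a is not leave_out]
        assert check_consistency(sub)[0]
    sub.articulations = core
    assert not check_consistency(sub)[0]


def test_diagnose_two_articulation_core():
    problem = one_by_one()
    x, y = problem.t2["X"], problem.t1["Y"]
    problem.articulations = [
        Articulation(x, RelationSet.of(R.EQ), y),
        Articulation(x, RelationSet.of(R.DJ), y),
    ]
    assert set(diagnose(problem)) == set(problem.articulations)


# -- within-taxonomy helper ----------------------------------------------

def test_within_taxonomy_relations(fig1):
    t2 = fig1.t2
    assert within_taxonomy_relation(t2, t2["Mirza"], t2["Mirza_coquereli"]) is R.EQ
    assert within_taxonomy_relation(t2, t2["Microcebus"], t2["Microcebus_rufus"]) is R.GT
    assert within_taxonomy_relation(t2, t2["Microcebus_rufus"], t2["Microcebus"]) is R.LT
    assert within_taxonomy_relation(t2, t2["Microcebus"], t2["Mirza"]) is R.DJ
    assert within_taxonomy_relation(t2, t2["Mirza"], t2["Mirza"]) is R.EQ
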