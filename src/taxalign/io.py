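"""Readers and writers for the alignment text dialect and tabular outputs.

The input dialect is line-oriented (``#`` starts a comment):

.. code-block:: text

    taxonomy 2005 MSW3_Microcebus_Mirza
    (Microcebus Microcebus_berthae Microcebus_griseorufus ...)
    (Mirza Mirza_coquereli)
    taxonomy 1993 MSW2_Microcebus
    (Microcebus Microcebus_murinus Microcebus_rufus Microcebus_coquereli)
    nocoverage 2005.Microcebus          # optional per-concept coverage opt-out
    articulation fig1 2005-1993
    [2005.Microcebus_griseorufus is_included_in 1993.Microcebus_murinus]
    [2005.Microcebus_rufus equals 1993.Microcebus_rufus]
    [2005.Microcebus {equals overlaps} 1993.Microcebus]

The first taxonomy block is T2 (the later treatment) unless a ``t2 <id>``
directive says otherwise.  Relation words are ``equals``, ``includes``,
``is_included_in``, ``overlaps``, ``disjoint``; the bare RCC-5 symbols are
accepted as well ("|" is read as "!").

The rank sidecar is a 3-column TSV (taxonomy_id, name, rank) without header.
The MIR table is written as CSV ``taxon2,taxon1,relation,provenance``.
"""

from __future__ import annotations

import csv
import io as _io
import re

from .model import (
    AlignmentOptions,
    AlignmentProblem,
    Articulation,
    Taxonomy,
    ValidationError,
)
from .rcc5 import RelationSet

__all__ = [
    "ParseError",
    "parse_alignment",
    "write_alignment",
    "read_rank_table",
    "attach_ranks",
    "write_mir_csv",
    "read_mir_csv",
]


class ParseError(ValueError):
    """A malformed alignment input; carries the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


_STATEMENT_RE = re.compile(
    r"^\[\s*(?P<left>\S+)\s+(?P<rel>\{[^}]*\}|\S+)\s+(?P<right>\S+)\s*\]$"
)


def _split_label(token: str, line_no: int) -> tuple[str, str]:
    if "." not in token:
        raise ParseError(f"expected a qualified concept label 'id.name', got {token!r}", line_no)
    tax_id, name = token.split(".", 1)
    if not tax_id or not name:
        raise ParseError(f"malformed qualified concept label {token!r}", line_no)
    return tax_id, name


def parse_alignment(text: str) -> AlignmentProblem:
    """Parse the alignment dialect into a validated :class:`AlignmentProblem`."""
    taxonomies: list[Taxonomy] = []
    by_id: dict[str, Taxonomy] = {}
    parent_lines_seen: dict[tuple[str, str], int] = {}
    current_tax: Taxonomy | None = None
    current_art_label = ""
    in_articulation = False
    articulation_raw: list[tuple[int, str, str, str]] = []  # line, left, rel, right
    nocoverage_raw: list[tuple[int, str]] = []
    t2_override: str | None = None
    tax_header_line: dict[str, int] = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("("):
            if not line.endswith(")"):
                raise ParseError("unterminated parent/child list", line_no)
            if current_tax is None or in_articulation:
                raise ParseError("parent/child list outside a taxonomy block", line_no)
            tokens = line[1:-1].split()
            if not tokens:
                raise ParseError("empty parent/child list", line_no)
            key = (current_tax.id, tokens[0])
            if key in parent_lines_seen:
                raise ParseError(
                    f"duplicate parent/child list for {current_tax.id}.{tokens[0]} "
                    f"(first at line {parent_lines_seen[key]})",
                    line_no,
                )
            parent_lines_seen[key] = line_no
            try:
                parent = current_tax.get(tokens[0]) or current_tax.add_concept(tokens[0])
                for name in tokens[1:]:
                    child = current_tax.get(name)
                    if child is None:
                        child = current_tax.add_concept(name)
                    current_tax.add_edge(parent, child)
            except ValidationError as exc:
                raise ParseError(str(exc), line_no) from exc
            continue
        if line.startswith("["):
            if not in_articulation:
                raise ParseError("articulation statement outside an articulation block", line_no)
            m = _STATEMENT_RE.match(line)
            if m is None:
                raise ParseError(f"malformed articulation statement {line!r}", line_no)
            articulation_raw.append((line_no, m["left"], m["rel"], m["right"]))
            continue
        keyword, _, rest = line.partition(" ")
        keyword = keyword.rstrip(":")
        rest = rest.strip()
        if keyword == "taxonomy":
            parts = rest.split(None, 1)
            if not parts:
                raise ParseError("taxonomy directive needs an id", line_no)
            tax_id = parts[0]
            if tax_id in by_id:
                raise ParseError(f"duplicate taxonomy id {tax_id!r}", line_no)
            current_tax = Taxonomy(tax_id, parts[1] if len(parts) > 1 else tax_id)
            taxonomies.append(current_tax)
            by_id[tax_id] = current_tax
            tax_header_line[tax_id] = line_no
            in_articulation = False
        elif keyword == "nocoverage":
            if not rest:
                raise ParseError("nocoverage directive needs a qualified concept label", line_no)
            nocoverage_raw.append((line_no, rest))
        elif keyword == "articulation":
            parts = rest.split()
            if not parts:
                raise ParseError("articulation directive needs a label", line_no)
            current_art_label = parts[0]
            in_articulation = True
        elif keyword == "t2":
            if not rest:
                raise ParseError("t2 directive needs a taxonomy id", line_no)
            t2_override = rest.split()[0]
        else:
            raise ParseError(f"unrecognized directive {keyword!r}", line_no)

    if len(taxonomies) != 2:
        raise ParseError(f"expected exactly two taxonomy blocks, found {len(taxonomies)}")
    for tax in taxonomies:
        try:
            tax.validate()
        except ValidationError as exc:
            raise ParseError(str(exc), tax_header_line[tax.id]) from exc

    if t2_override is not None:
        if t2_override not in by_id:
            raise ParseError(f"t2 directive names unknown taxonomy {t2_override!r}")
        t2 = by_id[t2_override]
        t1 = next(t for t in taxonomies if t is not t2)
    else:
        t2, t1 = taxonomies  # first block read is T2, the later treatment

    for line_no, token in nocoverage_raw:
        tax_id, name = _split_label(token, line_no)
        tax = by_id.get(tax_id)
        if tax is None or name not in tax:
            raise ParseError(f"nocoverage names unknown concept {token!r}", line_no)
        tax[name].coverage = False

    articulations = []
    for line_no, left_tok, rel_tok, right_tok in articulation_raw:
        lt_id, lt_name = _split_label(left_tok, line_no)
        rt_id, rt_name = _split_label(right_tok, line_no)
        for tok, tax_id, name in ((left_tok, lt_id, lt_name), (right_tok, rt_id, rt_name)):
            tax = by_id.get(tax_id)
            if tax is None or name not in tax:
                raise ParseError(f"articulation references unknown concept {tok!r}", line_no)
        if (lt_id, rt_id) != (t2.id, t1.id):
            raise ParseError(
                f"articulations must run T2-T1 ({t2.id}.x <rel> {t1.id}.y); got {lt_id}-{rt_id}",
                line_no,
            )
        try:
            relset = RelationSet.from_text(rel_tok)
        except ValueError as exc:
            raise ParseError(str(exc), line_no) from exc
        articulations.append(
            Articulation(by_id[lt_id][lt_name], relset, by_id[rt_id][rt_name], current_art_label)
        )

    try:
        return AlignmentProblem(t2, t1, articulations)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_alignment(problem: AlignmentProblem) -> str:
    """Serialize a problem so that ``parse_alignment`` round-trips it.

    Taxonomies are written T2 first (so no ``t2`` directive is needed),
    concepts and articulations in declaration order.
    """
    out: list[str] = []
    for tax in (problem.t2, problem.t1):
        out.append(f"taxonomy {tax.id} {tax.label}")
        for c in tax.concepts:
            kids = tax.children(c)
            if kids:
                out.append("(" + " ".join([c.name] + [k.name for k in kids]) + ")")
            elif tax.parent(c) is None:
                out.append(f"({c.name})")  # childless root still needs declaring
    for tax in (problem.t2, problem.t1):
        for c in tax.concepts:
            if not c.coverage:
                out.append(f"nocoverage {c.label}")
    label = problem.articulations[0].label if problem.articulations else "alignment"
    out.append(f"articulation {label or 'alignment'} {problem.t2.id}-{problem.t1.id}")
    for a in problem.articulations:
        out.append(f"[{a.left.label} {a.relation.to_names()} {a.right.label}]")
    return "\n".join(out) + "\n"


def read_rank_table(text: str) -> list[tuple[str, str, str]]:
    """Read the 3-column, headerless rank sidecar TSV."""
    rows = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"rank sidecar rows need 3 tab-separated columns, got {len(parts)}", line_no
            )
        rows.append((parts[0].strip(), parts[1].strip(), parts[2].strip()))
    return rows


def attach_ranks(
    problem: AlignmentProblem, rank_table: list[tuple[str, str, str]]
) -> AlignmentProblem:
    """Assign ranks from (taxonomy_id, name, rank) rows; unlisted concepts
    keep rank "unranked".  Unknown concept references are collected and
    reported together."""
    by_id = {problem.t2.id: problem.t2, problem.t1.id: problem.t1}
    offenders = []
    for tax_id, name, rank in rank_table:
        tax = by_id.get(tax_id)
        if tax is None or name not in tax:
            offenders.append(f"{tax_id}.{name}")
            continue
        tax[name].rank = rank
    if offenders:
        raise ValidationError(
            "rank sidecar references unknown concepts: " + ", ".join(offenders)
        )
    return problem


def write_rank_table(problem: AlignmentProblem) -> str:
    """Serialize current ranks as the sidecar TSV (skips "unranked")."""
    lines = []
    for tax in (problem.t2, problem.t1):
        for c in tax.concepts:
            if c.rank != "unranked":
                lines.append(f"{c.taxonomy_id}\t{c.name}\t{c.rank}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_mir_csv(mir) -> str:
    """Serialize a complete MIR table as CSV.

    Header ``taxon2,taxon1,relation,provenance``; one row per cross-taxonomy
    pair, sorted by the qualified labels; relation is a single symbol or a
    brace-delimited disjunction; provenance is "input" for directly
    articulated pairs, else "inferred".
    """
    expected = mir.n_t2 * mir.n_t1
    if len(mir.cells) != expected:
        raise ValidationError(
            f"incomplete MIR table: {len(mir.cells)} cells, expected {expected}"
        )
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["taxon2", "taxon1", "relation", "provenance"])
    rows = sorted(mir.cells.items(), key=lambda kv: (kv[0][0].label, kv[0][1].label))
    for (x, y), relset in rows:
        writer.writerow([x.label, y.label, relset.to_symbols(), mir.provenance[(x, y)]])
    return buf.getvalue()


def read_mir_csv(text: str) -> list[tuple[str, str, RelationSet, str]]:
    """Parse a MIR CSV back into (taxon2, taxon1, relations, provenance) rows."""
    reader = csv.reader(_io.StringIO(text))
    header = next(reader, None)
    if header != ["taxon2", "taxon1", "relation", "provenance"]:
        raise ParseError(f"unexpected MIR CSV header: {header}")
    return [(r[0], r[1], RelationSet.from_text(r[2]), r[3]) for r in reader if r]
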