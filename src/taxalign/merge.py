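"""Merge visualizations: reduced containment graph and combined concepts.

The merge taxonomy groups concepts into congruence classes (gray rounded
boxes in the published style), draws containment after transitive
reduction, and shows overlap as dashed blue edges.  The combined-concept
view resolves each overlap between A and B into the Euler subregions A*B
(in both), A\\B and B\\A, turning overlap into plain containment.  Output
is GraphViz DOT text; rendering is left to external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model import AlignmentProblem, Concept, Taxonomy
from .rcc5 import BaseRelation
from .reasoner import MIRTable, World, within_taxonomy_relation

__all__ = [
    "MergeNode",
    "EulerSubregionNode",
    "MergeGraph",
    "build_merge",
    "combined_concepts",
    "to_dot",
    "input_dot",
]

#: node fill styles keyed by origin, after the published legend
_STYLES = {
    "t2": ("box", "palegreen"),          # later treatment, noncongruent
    "t1": ("octagon", "khaki"),          # earlier treatment, noncongruent
    "congruent": ("box", "lightgray"),   # congruent class, rounded
    "subregion": ("box", "lightblue"),   # Euler subregion of an overlap
}


@dataclass(frozen=True)
class MergeNode:
    """A congruence class: concepts pairwise congruent in the chosen world."""

    members: tuple[Concept, ...]
    origin: str  # "t2" | "t1" | "congruent"

    @property
    def label(self) -> str:
        return " = ".join(c.label for c in self.members)

    @property
    def key(self) -> str:
        return self.members[0].label

    def __repr__(self) -> str:
        return f"MergeNode({self.label})"


@dataclass(frozen=True)
class EulerSubregionNode:
    """A*B / A\\B / B\\A region introduced by an overlapping pair."""

    name: str

    @property
    def label(self) -> str:
        return self.name

    @property
    def key(self) -> str:
        return self.name

    @property
    def origin(self) -> str:
        return "subregion"


@dataclass
class MergeGraph:
    nodes: list
    containment_edges: list[tuple]          # (parent_node, child_node)
    overlap_edges: list[tuple]              # (node, node), unordered pairs
    world: World | None = None
    added_subregions: int = 0
    _class_of: dict[Concept, MergeNode] = field(default_factory=dict, repr=False)

    def node_of(self, concept: Concept) -> MergeNode:
        return self._class_of[concept]

    def congruent_nodes(self) -> list[MergeNode]:
        return [n for n in self.nodes if n.origin == "congruent"]


def _relation_map(mir: MIRTable, world: World | None):
    if world is not None:
        return world.relations
    ambiguous = mir.ambiguous_cells()
    if ambiguous:
        pairs = ", ".join(f"({x.label}, {y.label})" for x, y in list(ambiguous)[:3])
        raise ValueError(
            f"MIR has {len(ambiguous)} ambiguous cells (e.g. {pairs}); pass a "
            "chosen World from enumerate_worlds() to build the merge graph"
        )
    return mir.singleton_cells()


def build_merge(mir: MIRTable, t2: Taxonomy, t1: Taxonomy, world: World | None = None) -> MergeGraph:
    """Group concepts by congruence and build the reduced containment graph.

    Requires an all-singleton MIR (unique world) or an explicitly chosen
    world.  Cross-taxonomy congruence comes from EQ cells; within-taxonomy
    congruence from monotypic coverage chains.  Containment edges come from
    GT/LT cells and within-taxonomy parenthood, then transitive reduction;
    OV cells become overlap edges.
    """
    relmap = _relation_map(mir, world)

    parent_uf: dict[Concept, Concept] = {}

    def find(c: Concept) -> Concept:
        while parent_uf.get(c, c) is not c:
            parent_uf[c] = parent_uf.get(parent_uf[c], parent_uf[c])
            c = parent_uf[c]
        return c

    def union(a: Concept, b: Concept) -> None:
        ra, rb = find(a), find(b)
        if ra is not rb:
            parent_uf[ra] = rb

    for (x, y), rel in relmap.items():
        if rel is BaseRelation.EQ:
            union(x, y)
    for tax in (t2, t1):
        for child, parent in tax.parent_map.items():
            if within_taxonomy_relation(tax, parent, child) is BaseRelation.EQ:
                union(parent, child)

    order = {c: i for i, c in enumerate(t2.concepts + t1.concepts)}
    classes: dict[Concept, list[Concept]] = {}
    for c in order:
        classes.setdefault(find(c), []).append(c)

    nodes: list[MergeNode] = []
    class_of: dict[Concept, MergeNode] = {}
    for members in classes.values():
        members = tuple(sorted(members, key=lambda c: (c.taxonomy_id, c.name)))
        taxa = {c.taxonomy_id for c in members}
        origin = "congruent" if len(members) > 1 or len(taxa) == 2 else (
            "t2" if members[0].taxonomy_id == t2.id else "t1"
        )
        node = MergeNode(members, origin)
        nodes.append(node)
        for c in members:
            class_of[c] = node
    nodes.sort(key=lambda n: n.key)

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for tax in (t2, t1):
        for child, parent in tax.parent_map.items():
            pn, cn = class_of[parent], class_of[child]
            if pn is not cn:
                g.add_edge(pn, cn)
    overlap: set[frozenset] = set()
    for (x, y), rel in relmap.items():
        xn, yn = class_of[x], class_of[y]
        if xn is yn:
            continue
        if rel is BaseRelation.GT:
            g.add_edge(xn, yn)
        elif rel is BaseRelation.LT:
            g.add_edge(yn, xn)
        elif rel is BaseRelation.OV:
            overlap.add(frozenset((xn, yn)))

    if not nx.is_directed_acyclic_graph(g):  # pragma: no cover - guarded by consistency
        raise ValueError("containment graph is cyclic; the chosen world is not consistent")
    reduced = nx.transitive_reduction(g)

    containment = sorted(reduced.edges, key=lambda e: (e[0].key, e[1].key))
    overlap_edges = sorted(
        (tuple(sorted(pair, key=lambda n: n.key)) for pair in overlap),
        key=lambda e: (e[0].key, e[1].key),
    )
    graph = MergeGraph(
        nodes=nodes,
        containment_edges=containment,
        overlap_edges=overlap_edges,
        world=world,
        _class_of=class_of,
    )
    return graph


def _extension(world: World, concept: Concept, t2: Taxonomy, t1: Taxonomy):
    """Occupied witness regions lying inside a concept's circumscription."""
    tax = t2 if concept.taxonomy_id == t2.id else t1
    out = set()
    for r in world.witness:
        deepest = r.deepest_t2 if tax is t2 else r.deepest_t1
        if deepest is not None and tax.is_ancestor_or_self(concept, deepest):
            out.add(r)
    return out


def combined_concepts(
    graph: MergeGraph, t2: Taxonomy, t1: Taxonomy
) -> MergeGraph:
    """Resolve each overlap edge (A, B) into Euler subregion nodes.

    A*B becomes a child of both A and B; A\\B and B\\A are added only where
    nonempty in the chosen world (for a genuine overlap all three are
    occupied; the emptiness check matters only when a caller hands in a
    hand-built graph).
    """
    nodes = list(graph.nodes)
    containment = list(graph.containment_edges)
    added = 0
    for a, b in graph.overlap_edges:
        la, lb = a.key, b.key
        if graph.world is not None:
            ext_a = _extension(graph.world, a.members[0], t2, t1)
            ext_b = _extension(graph.world, b.members[0], t2, t1)
            pieces = [
                (f"{la}*{lb}", bool(ext_a & ext_b), (a, b)),
                (f"{la}\\{lb}", bool(ext_a - ext_b), (a,)),
                (f"{lb}\\{la}", bool(ext_b - ext_a), (b,)),
            ]
        else:
            pieces = [
                (f"{la}*{lb}", True, (a, b)),
                (f"{la}\\{lb}", True, (a,)),
                (f"{lb}\\{la}", True, (b,)),
            ]
        for name, nonempty, parents in pieces:
            if not nonempty:
                continue
            sub = EulerSubregionNode(name)
            nodes.append(sub)
            added += 1
            for parent in parents:
                containment.append((parent, sub))
    return MergeGraph(
        nodes=nodes,
        containment_edges=containment,
        overlap_edges=[],
        world=graph.world,
        added_subregions=added,
        _class_of=dict(graph._class_of),
    )


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(graph: MergeGraph, name: str = "merge") -> str:
    """Serialize as deterministic GraphViz DOT text."""
    ids = {node: f"n{i}" for i, node in enumerate(graph.nodes)}
    lines = [f"digraph {name} {{", "  rankdir=TB;", '  node [fontname="Helvetica"];']
    for node in graph.nodes:
        shape, color = _STYLES[node.origin]
        style = "rounded,filled" if node.origin == "congruent" else "filled"
        if isinstance(node, MergeNode):
            label = "\\n".join(_dot_escape(c.label) for c in node.members)
        else:
            label = _dot_escape(node.label)
        lines.append(
            f'  {ids[node]} [label="{label}", shape={shape}, '
            f'style="{style}", fillcolor={color}];'
        )
    for parent, child in graph.containment_edges:
        lines.append(f"  {ids[parent]} -> {ids[child]};")
    for a, b in graph.overlap_edges:
        lines.append(
            f'  {ids[a]} -> {ids[b]} [dir=none, style=dashed, color=blue];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def input_dot(problem: AlignmentProblem, name: str = "input") -> str:
    """DOT view of the two input taxonomies plus the input articulations."""
    ids: dict[Concept, str] = {}
    lines = [f"digraph {name} {{", "  rankdir=TB;", '  node [fontname="Helvetica"];']
    for origin, tax in (("t2", problem.t2), ("t1", problem.t1)):
        shape, color = _STYLES[origin]
        for c in tax.concepts:
            ids[c] = f"{origin}_{len(ids)}"
            lines.append(
                f'  {ids[c]} [label="{_dot_escape(c.label)}", shape={shape}, '
                f'style="filled", fillcolor={color}];'
            )
    for tax in (problem.t2, problem.t1):
        for child, parent in sorted(
            tax.parent_map.items(), key=lambda cp: (cp[1].label, cp[0].label)
        ):
            lines.append(f"  {ids[parent]} -> {ids[child]};")
    for a in problem.articulations:
        label = _dot_escape(a.relation.to_symbols())
        lines.append(
            f'  {ids[a.left]} -> {ids[a.right]} '
            f'[dir=none, style=dotted, color=red, label="{label}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
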