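"""Brute-force reference semantics for small alignment problems.

Enumerates *every* nonempty subset of the candidate regions, keeps the
subsets that satisfy nonemptiness and all articulations, and deduplicates
them by the cross-pair relation map they induce.  Exact by construction and
deliberately capped at 20 regions (about a million subsets); its only job
is to ground-truth the reasoner on small instances.
"""

from __future__ import annotations

import numpy as np

from .model import AlignmentProblem, Concept
from .rcc5 import BaseRelation, RelationSet
from .reasoner import InconsistencyError, MIRTable, World, _Encoding

__all__ = ["OracleCapacityError", "oracle_worlds", "oracle_mir"]

_CODE_REL = dict(enumerate(BaseRelation))  # 0:EQ 1:GT 2:LT 3:OV 4:DJ
_REL_CODE = {r: c for c, r in _CODE_REL.items()}


class OracleCapacityError(ValueError):
    """Instance too large for exhaustive occupancy enumeration."""


def _region_bits(enc: _Encoding) -> list[int]:
    """Live region bit positions (the dead outside/outside bit excluded)."""
    return [j for j in range(enc.n_bits) if (enc.ALL >> j) & 1]


def oracle_worlds(problem: AlignmentProblem, max_regions: int = 20) -> list[World]:
    """Ground-truth possible worlds by exhaustive occupancy enumeration."""
    enc = _Encoding(problem)
    bits = _region_bits(enc)
    k = len(bits)
    if k > max_regions:
        raise OracleCapacityError(
            f"{k} candidate regions exceed the oracle cap of {max_regions}"
        )

    def compress(mask: int) -> int:
        return sum(((mask >> b) & 1) << i for i, b in enumerate(bits))

    subs = np.arange(1, 1 << k, dtype=np.int64)
    valid = np.ones(subs.shape, dtype=bool)
    for h in enc.global_hits:  # nonemptiness of every concept
        valid &= (subs & compress(h)) != 0
    for art in problem.articulations:
        mi, ml, mr = (compress(z) for z in enc.zones(art.left, art.right))
        ei = (subs & mi) != 0
        el = (subs & ml) != 0
        er = (subs & mr) != 0
        ok = np.zeros(subs.shape, dtype=bool)
        for rel in art.relation:
            if rel is BaseRelation.EQ:
                ok |= ~el & ~er
            elif rel is BaseRelation.GT:
                ok |= el & ~er
            elif rel is BaseRelation.LT:
                ok |= ~el & er
            elif rel is BaseRelation.OV:
                ok |= ei & el & er
            else:  # DJ
                ok |= ~ei
        valid &= ok
    subs = subs[valid]
    if subs.size == 0:
        return []

    # relation map per subset, encoded as a base-5 signature over cross pairs
    pairs = problem.cross_pairs()
    sig = np.zeros(subs.shape, dtype=object)  # object: signatures can be wide
    for x, y in pairs:
        mi, ml, mr = (compress(z) for z in enc.zones(x, y))
        ei = (subs & mi) != 0
        el = (subs & ml) != 0
        er = (subs & mr) != 0
        code = np.full(subs.shape, _REL_CODE[BaseRelation.OV], dtype=np.int64)
        code[~ei] = _REL_CODE[BaseRelation.DJ]
        code[ei & ~el & ~er] = _REL_CODE[BaseRelation.EQ]
        code[ei & ~el & er] = _REL_CODE[BaseRelation.LT]
        code[ei & el & ~er] = _REL_CODE[BaseRelation.GT]
        sig = sig * 5 + code

    worlds: list[World] = []
    seen: set = set()
    for s, occ in zip(sig.tolist(), subs.tolist()):
        if s in seen:
            continue
        seen.add(s)
        relations: dict[tuple[Concept, Concept], BaseRelation] = {}
        v = s
        for p in reversed(pairs):
            relations[p] = _CODE_REL[v % 5]
            v //= 5
        full_mask = sum(1 << b for i, b in enumerate(bits) if (occ >> i) & 1)
        worlds.append(World(relations, enc.regions_of(full_mask)))
    return worlds


def oracle_mir(problem: AlignmentProblem, max_regions: int = 20) -> MIRTable:
    """Ground-truth MIR: per-pair union of relations over the oracle worlds."""
    worlds = oracle_worlds(problem, max_regions=max_regions)
    if not worlds:
        raise InconsistencyError(
            "inconsistent problem: the oracle found no valid occupancy"
        )
    pairs = problem.cross_pairs()
    cells = {
        p: RelationSet({w.relations[p] for w in worlds}) for p in pairs
    }
    articulated = problem.articulated_pairs()
    provenance = {p: ("input" if p in articulated else "inferred") for p in pairs}
    return MIRTable(
        cells=cells,
        provenance=provenance,
        n_t2=len(problem.t2),
        n_t1=len(problem.t1),
        n_worlds=len(worlds),
        exhausted=True,
    )
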