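"""Order, orient and link contigs of one family into super contigs.

Assemblies fragment when regions are unsequenced or fall below the
homology-search sensitivity; the fragments of one gene can still be
ordered and oriented by their alignment spans on the family profile HMM
and linked by paired-end reads whose mates land in different contigs.
Two contigs are grouped when an insert-consistent paired-end link joins
them, or when their model spans are disjoint, compatible in order and
separated by at most ``max_model_gap_aa``.  Contigs with overlapping
model spans and no paired-end link are deliberately NOT merged: they are
the signature of paralogs aligned to the same model region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .graph_simplify import SupportRegistry
from .traversal import ContigPath

__all__ = ["ScaffoldParams", "SuperContig", "scaffold_contigs", "emit_supercontig_sequences"]

logger = logging.getLogger(__name__)


@dataclass
class ScaffoldParams:
    max_model_gap_aa: int = 50
    pe_insert_mean: Optional[float] = None
    pe_insert_sd: float = 0.0
    insert_tolerance_sd: float = 3.0


@dataclass
class SuperContig:
    """An ordered, oriented group of contigs from one scaffold.

    ``members`` holds (contig_id, orientation, offset_bp, gap_after_bp)
    sorted by model-span start; ``offset_bp`` is the member's start in
    the emitted sequence and ``gap_after_bp`` the estimated gap to the
    next member (0 for the last).
    """

    super_id: str
    members: list[tuple[str, str, int, int]]
    supporting_pe_links: dict[tuple[str, str], int] = field(default_factory=dict)
    sequence: str = ""


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            ra, rb = sorted((ra, rb))
            self.parent[rb] = ra


def _aa_gap(span1: tuple[int, int], span2: tuple[int, int]) -> int:
    """Residues strictly between two disjoint 1-based inclusive spans."""
    (s1, e1), (s2, e2) = sorted((span1, span2))
    return max(0, s2 - e1 - 1)


def _spans_disjoint(span1, span2) -> bool:
    (s1, e1), (s2, e2) = sorted((span1, span2))
    return s2 > e1


def _pe_links(
    contigs: Sequence[ContigPath], registry: SupportRegistry, params: ScaffoldParams
) -> dict[tuple[str, str], int]:
    """Count insert-consistent pe links between contig pairs via node homes."""
    node_home: dict[str, list[int]] = {}
    for idx, c in enumerate(contigs):
        for n in c.node_ids:
            node_home.setdefault(n, []).append(idx)
    links: dict[tuple[str, str], int] = {}
    ids = [_contig_id(i, c) for i, c in enumerate(contigs)]
    for sup in registry.pe_pairs:
        homes_a = node_home.get(sup.node_a, [])
        homes_b = node_home.get(sup.node_b, [])
        for ia in homes_a:
            for ib in homes_b:
                if ia == ib:
                    continue
                key = tuple(sorted((ids[ia], ids[ib])))
                links[key] = links.get(key, 0) + 1
    return links


def _contig_id(index: int, contig: ContigPath) -> str:
    return f"{contig.family_id or 'family'}|{index}"


def scaffold_contigs(
    contigs: Sequence[ContigPath],
    registry: Optional[SupportRegistry] = None,
    params: Optional[ScaffoldParams] = None,
) -> list[SuperContig]:
    """Group, order and gap-estimate contigs into super contigs.

    The estimated gap between consecutive members is 3x the residue gap
    between their model spans (unknown untranslated or intergenic
    sequence is not modelled); overlapping-span members get gap 0.
    """
    params = params or ScaffoldParams()
    registry = registry or SupportRegistry()
    ids = [_contig_id(i, c) for i, c in enumerate(contigs)]
    by_id = dict(zip(ids, contigs))
    uf = _UnionFind(ids)
    links = _pe_links(contigs, registry, params)
    for (a, b), _count in links.items():
        uf.union(a, b)
    # model-coordinate adjacency joins (disjoint spans only: paralog safety)
    order = sorted(ids, key=lambda i: (by_id[i].model_span_aa, i))
    for i1 in order:
        for i2 in order:
            if i1 >= i2:
                continue
            c1, c2 = by_id[i1], by_id[i2]
            if not c1.model_span_aa[1] or not c2.model_span_aa[1]:
                continue
            if _spans_disjoint(c1.model_span_aa, c2.model_span_aa) and _aa_gap(
                c1.model_span_aa, c2.model_span_aa
            ) <= params.max_model_gap_aa:
                uf.union(i1, i2)
    groups: dict[str, list[str]] = {}
    for cid in ids:
        if not by_id[cid].model_span_aa[1]:
            logger.warning("contig %s lacks a model span; kept as singleton", cid)
            groups.setdefault(f"__nospan__{cid}", []).append(cid)
        else:
            groups.setdefault(uf.find(cid), []).append(cid)
    supers = []
    for gi, root in enumerate(sorted(groups)):
        members_ids = sorted(
            groups[root], key=lambda i: (by_id[i].model_span_aa, i)
        )
        members: list[tuple[str, str, int, int]] = []
        offset = 0
        for j, cid in enumerate(members_ids):
            c = by_id[cid]
            gap = 0
            spacer = 0
            if j + 1 < len(members_ids):
                nxt = by_id[members_ids[j + 1]]
                if _spans_disjoint(c.model_span_aa, nxt.model_span_aa):
                    gap = 3 * _aa_gap(c.model_span_aa, nxt.model_span_aa)
                spacer = max(gap, 1)  # distinct contigs get >=1 N even at gap 0
            members.append((cid, "+", offset, gap))
            offset += len(c.sequence) + spacer
        family = by_id[members_ids[0]].family_id or "family"
        sc = SuperContig(super_id=f"{family}|super{gi}", members=members)
        sc.supporting_pe_links = {
            k: v
            for k, v in links.items()
            if k[0] in members_ids and k[1] in members_ids
        }
        supers.append(sc)
    return emit_supercontig_sequences(supers, by_id)


def emit_supercontig_sequences(
    supers: list[SuperContig], contigs_by_id: dict[str, ContigPath]
) -> list[SuperContig]:
    """Fill in super-contig sequences: members joined by N runs of the gap."""
    for sc in supers:
        parts = []
        for j, (cid, _ori, _off, gap) in enumerate(sc.members):
            parts.append(contigs_by_id[cid].sequence)
            if j + 1 < len(sc.members):
                parts.append("N" * max(1, gap))
        sc.sequence = "".join(parts)
    return supers
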