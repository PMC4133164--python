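"""Family-specific overlap graph construction.

Edges are created from the consistency between two kinds of overlap:

* alignment overlap ``Oa`` — the intersection of two reads' alignment
  intervals on the family profile HMM, converted from amino acids to bp
  (3 bp per residue);
* sequence overlap ``Os`` — the longest suffix of the earlier read that
  matches a prefix of the later read within a Hamming allowance ``m``.

An edge u -> v is created iff (i) u aligns earlier on the model than v,
(ii) the alignment intervals overlap by at least ``min_align_overlap_bp``
and (iii) the relative overlap difference d = |Oa - Os| / max(Oa, Os)
is at most ``tau``.  Criterion (iii) is what separates reads of the same
gene (consistent overlaps) from reads of homologous genes, whose
translated similarity can produce a large alignment overlap with only a
short exact sequence overlap.  It also admits *small* sequence overlaps
in low-coverage regions, because a random short overlap is unlikely to
agree with the alignment overlap.

Construction sorts reads by alignment start and only compares pairs
whose alignment overlap passes the gate, avoiding all-against-all
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .classify import FamilyBin
from .io_formats import AlignmentHit

__all__ = [
    "OverlapParams",
    "GraphNode",
    "aa_overlap_to_bp",
    "suffix_prefix_overlap",
    "relative_overlap_difference",
    "edge_consistent",
    "alignment_order_key",
    "build_graph",
]


@dataclass
class OverlapParams:
    """Edge-creation thresholds.

    ``min_align_overlap_bp`` is the alignment-overlap gate (default 20
    bp; ~20% of the read length is a good rule of thumb).  ``tau`` caps
    the relative overlap difference (default 0.15).  ``max_mismatches``
    is the Hamming allowance in the sequence overlap, tunable to the
    platform's substitution error rate.  ``min_seq_overlap_bp`` is a
    small floor on any sequence overlap, guarding against 1-2 bp
    coincidences that the consistency rule alone would admit.
    """

    min_align_overlap_bp: int = 20
    tau: float = 0.15
    max_mismatches: int = 2
    min_seq_overlap_bp: int = 10

    def __post_init__(self) -> None:
        if self.min_align_overlap_bp <= 0:
            raise ValueError("min_align_overlap_bp must be > 0")
        if not (0 <= self.tau < 1):
            raise ValueError("tau must be in [0, 1)")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_seq_overlap_bp < 1:
            raise ValueError("min_seq_overlap_bp must be >= 1")


@dataclass
class GraphNode:
    """One non-duplicate read: node payload of the raw overlap graph.

    Duplicate reads (identical sequence after strand normalization)
    collapse into one node; ``member_reads`` lists all of them and
    ``multiplicity`` feeds node coverage downstream.
    """

    node_id: str
    sequence: str
    hit: AlignmentHit
    member_reads: list[str] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.member_reads)


def aa_overlap_to_bp(n_aa: int) -> int:
    """Convert an amino-acid overlap length to nucleotides (3 bp per aa)."""
    if n_aa < 0:
        raise ValueError(f"negative aa overlap: {n_aa}")
    return 3 * n_aa


def suffix_prefix_overlap(
    r1: str, r2: str, m: int, min_len: int
) -> Optional[tuple[int, int]]:
    """Longest suffix of ``r1`` matching a prefix of ``r2`` within ``m`` mismatches.

    Returns ``(length, hamming)`` for the longest L >= ``min_len`` such
    that Hamming(suffix(r1, L), prefix(r2, L)) <= m, or None if no such
    L exists.  L is capped at min(len(r1), len(r2)).
    """
    if not r1 or not r2:
        raise ValueError("empty sequence in overlap computation")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n1, n2 = len(r1), len(r2)
    for L in range(min(n1, n2), min_len - 1, -1):
        dist = 0
        off = n1 - L
        for k in range(L):
            if r1[off + k] != r2[k]:
                dist += 1
                if dist > m:
                    break
        else:
            return L, dist
    return None


def relative_overlap_difference(oa: int, os_: int) -> float:
    """d = |Oa - Os| / max(Oa, Os), the consistency measure in [0, 1)."""
    if oa <= 0 or os_ <= 0:
        raise ValueError("overlaps must be positive")
    return abs(oa - os_) / max(oa, os_)


def edge_consistent(oa: int, os_: int, tau: float) -> bool:
    """Criterion (iii): overlap consistency d <= tau."""
    return relative_overlap_difference(oa, os_) <= tau


def alignment_order_key(node: GraphNode):
    """Total order implementing edge criterion (i).

    Primary key: alignment start on the model.  Ties (reads whose codon
    windows coincide although they start 1-2 bp apart on the gene) are
    broken by model end, then by how far the alignment sits *into* the
    read: a larger read offset means the read extends further left of
    the shared model window, i.e. it starts earlier on the gene, so it
    must precede.  The read id is the final, arbitrary tie-break.
    """
    h = node.hit
    return (h.model_start_aa, h.model_end_aa, -h.read_start_bp, node.node_id)


def collapse_duplicates(bin_: FamilyBin) -> list[GraphNode]:
    """One node per distinct (strand-normalized) sequence.

    The representative read id is the lexicographically smallest member;
    the representative hit is the member hit with the best E-value.
    """
    by_seq: dict[str, list[tuple] ] = {}
    for read, hit in bin_.members:
        by_seq.setdefault(read.sequence, []).append((read, hit))
    nodes = []
    for seq, members in by_seq.items():
        members.sort(key=lambda rh: rh[0].read_id)
        best_hit = min(members, key=lambda rh: (rh[1].evalue, rh[0].read_id))[1]
        nodes.append(
            GraphNode(
                node_id=members[0][0].read_id,
                sequence=seq,
                hit=best_hit,
                member_reads=[r.read_id for r, _h in members],
            )
        )
    nodes.sort(key=alignment_order_key)
    return nodes


def pair_edge(
    n1: GraphNode, n2: GraphNode, params: OverlapParams
) -> Optional[dict]:
    """Evaluate criteria (ii)-(iii) for an ordered candidate pair.

    Returns edge attributes (os, oa, hamming, d) or None.  Criterion (i)
    — n1 aligned before n2 — is the caller's responsibility.
    """
    h1, h2 = n1.hit, n2.hit
    inter_aa = min(h1.model_end_aa, h2.model_end_aa) - max(
        h1.model_start_aa, h2.model_start_aa
    ) + 1
    if inter_aa <= 0:
        return None
    oa = aa_overlap_to_bp(inter_aa)
    if oa < params.min_align_overlap_bp:
        return None
    got = suffix_prefix_overlap(
        n1.sequence, n2.sequence, params.max_mismatches, params.min_seq_overlap_bp
    )
    if got is None:
        return None
    os_, ham = got
    d = relative_overlap_difference(oa, os_)
    if d > params.tau:
        return None
    return {"os": os_, "oa": oa, "hamming": ham, "d": d}


def build_graph(bin_: FamilyBin, params: Optional[OverlapParams] = None) -> nx.DiGraph:
    """Build the family overlap graph by a sweep over alignment-sorted reads.

    Nodes carry a :class:`GraphNode` under the ``data`` attribute; edges
    carry ``os``, ``oa``, ``hamming`` and ``d``.  Criterion (i) ties
    (equal model start) are ordered by (model end, read id), so each
    unordered pair yields at most one directed edge.
    """
    params = params or OverlapParams()
    g = nx.DiGraph(family_id=bin_.family_id)
    nodes = collapse_duplicates(bin_)
    for n in nodes:
        g.add_node(n.node_id, data=n)
    min_aa = -(-params.min_align_overlap_bp // 3)  # ceil
    for i, n1 in enumerate(nodes):
        e1 = n1.hit.model_end_aa
        for n2 in nodes[i + 1 :]:
            # sorted by model start: once the start is past the last
            # position that can still give min_aa overlap, stop.
            if n2.hit.model_start_aa > e1 - min_aa + 1:
                break
            attrs = pair_edge(n1, n2, params)
            if attrs is not None:
                g.add_edge(n1.node_id, n2.node_id, **attrs)
    return g
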