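"""Pruning and optimization of the raw overlap graph.

Four passes, in a fixed order:

1. inferior-edge removal — an edge is dropped when, against another
   edge sharing its head or tail, its sequence overlap is less than half
   as long AND it has strictly more mismatches (random overlaps are
   short and error-rich);
2. transitive-edge removal — an edge whose endpoints are also joined by
   an alternative directed path is redundant for connectivity; it is
   removed but the node pair is recorded, because a transitive edge is
   evidence that the two nodes come from the same gene region (it acts
   like a paired-end link with a tiny insert);
3. tip removal — short dead-end chains hanging off a branch are pruned
   by topology, as in de Bruijn assemblers;
4. chain merging — maximal unambiguous chains (single out-edge into a
   single in-edge) collapse into one node whose coverage is the total
   read length divided by the assembled length.

The inferior pass runs first so that junk edges do not mask legitimate
transitive reductions.  Transitive detection in the production path is
bounded to alternative paths of 2-3 hops, which covers read-tiling
geometry; full reachability serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .overlap_graph import GraphNode

__all__ = [
    "PESupport",
    "SupportRegistry",
    "MergedNode",
    "SimplifyParams",
    "remove_inferior_edges",
    "remove_transitive_edges",
    "remove_tips",
    "merge_chains",
    "simplify",
]


@dataclass(frozen=True)
class PESupport:
    """A paired-end link between two graph nodes.

    ``pos_a``/``pos_b`` are the mate start offsets inside each node's
    assembled sequence and ``len_a``/``len_b`` the mate lengths; they
    let the traversal check that the implied path distance of the pair
    is consistent with the library insert size (``insert_size_bp``,
    0 when the library insert is unknown).
    """

    node_a: str
    node_b: str
    pos_a: int
    pos_b: int
    len_a: int
    len_b: int
    insert_size_bp: int = 0


@dataclass
class SupportRegistry:
    """Evidence that two non-merged nodes co-occur in one gene.

    ``transitive_pairs`` holds unordered pairs recorded before
    transitive-edge removal; none of them is joined by a surviving
    direct edge.  ``pe_pairs`` holds paired-end links between distinct
    nodes; links between adjacent nodes are kept because they are the
    only evidence able to disambiguate a fork right after a shared node
    (isoform junctions).
    """

    transitive_pairs: set[frozenset] = field(default_factory=set)
    pe_pairs: list[PESupport] = field(default_factory=list)

    def add_transitive(self, a: str, b: str) -> None:
        if a != b:
            self.transitive_pairs.add(frozenset((a, b)))

    def has_transitive(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.transitive_pairs

    def pe_between(self, a: str, b: str) -> list[PESupport]:
        return [
            p
            for p in self.pe_pairs
            if {p.node_a, p.node_b} == {a, b}
        ]

    def partners(self, node: str) -> set[str]:
        out = set()
        for pair in self.transitive_pairs:
            if node in pair:
                out |= set(pair) - {node}
        for p in self.pe_pairs:
            if p.node_a == node:
                out.add(p.node_b)
            elif p.node_b == node:
                out.add(p.node_a)
        return out

    def rekey(self, mapping: dict[str, str], graph: Optional[nx.DiGraph] = None) -> "SupportRegistry":
        """Map node ids through ``mapping`` (e.g. after chain merging).

        Pairs collapsing into one node are dropped; transitive pairs
        joined by a surviving direct edge in ``graph`` are dropped too.
        """
        out = SupportRegistry()
        for pair in self.transitive_pairs:
            mapped = {mapping.get(x, x) for x in pair}
            if len(mapped) != 2:
                continue
            a, b = sorted(mapped)
            if graph is not None and (graph.has_edge(a, b) or graph.has_edge(b, a)):
                continue
            out.add_transitive(a, b)
        for p in self.pe_pairs:
            a = mapping.get(p.node_a, p.node_a)
            b = mapping.get(p.node_b, p.node_b)
            if a == b:
                continue
            out.pe_pairs.append(
                PESupport(a, b, p.pos_a, p.pos_b, p.len_a, p.len_b, p.insert_size_bp)
            )
        return out


@dataclass
class MergedNode:
    """A maximal unambiguous chain collapsed into one node.

    ``coverage`` is the total read length carried by the node (duplicate
    multiplicity included) divided by the assembled sequence length.
    ``read_offsets`` locate each member read inside ``sequence`` so that
    paired-end distances can be computed along traversal paths.
    """

    node_id: str
    member_reads: list[str]
    sequence: str
    coverage: float
    model_span_aa: tuple[int, int]
    read_offsets: dict[str, int] = field(default_factory=dict)
    read_lengths: dict[str, int] = field(default_factory=dict)
    total_read_bp: int = 0
    multiplicity: int = 1


@dataclass
class SimplifyParams:
    """``tip_len_bp`` defaults to 2x the mean read length of the graph."""

    tip_len_bp: Optional[int] = None
    insert_size_bp: int = 0


def remove_inferior_edges(graph: nx.DiGraph) -> nx.DiGraph:
    """Drop edges inferior to a sibling edge sharing their head or tail.

    e1 is inferior to e2 iff os(e1) < os(e2)/2 and hamming(e1) >
    hamming(e2).  Decisions are taken on a stable snapshot: deletions do
    not cascade within the pass.
    """
    doomed = set()
    for node in graph:
        for sibling_set in (graph.out_edges(node, data=True), graph.in_edges(node, data=True)):
            edges = list(sibling_set)
            for u1, v1, d1 in edges:
                for u2, v2, d2 in edges:
                    if (u1, v1) == (u2, v2):
                        continue
                    if d1["os"] * 2 < d2["os"] and d1["hamming"] > d2["hamming"]:
                        doomed.add((u1, v1))
    graph.remove_edges_from(doomed)
    return graph


def remove_transitive_edges(
    graph: nx.DiGraph, max_hops: int = 3
) -> tuple[nx.DiGraph, SupportRegistry]:
    """Remove edges whose endpoints are joined by an alternative path.

    Alternative paths of 2..``max_hops`` hops are detected against the
    pre-pass snapshot; every removed edge's node pair is recorded in the
    returned registry.  Removing only edges that have alternatives keeps
    reachability intact.
    """
    registry = SupportRegistry()
    succ = {n: set(graph.successors(n)) for n in graph}
    pred = {n: set(graph.predecessors(n)) for n in graph}
    doomed = []
    for u, w in graph.edges():
        # 2-hop: u -> x -> w
        mids = (succ[u] & pred[w]) - {u, w}
        alt = bool(mids)
        if not alt and max_hops >= 3:
            for x in succ[u] - {w, u}:
                if (succ[x] & pred[w]) - {u, w, x}:
                    alt = True
                    break
        if alt:
            doomed.append((u, w))
            registry.add_transitive(u, w)
    graph.remove_edges_from(doomed)
    return graph, registry


def _chain_bp(graph: nx.DiGraph, chain: Sequence[str]) -> int:
    total = len(graph.nodes[chain[0]]["data"].sequence)
    for a, b in zip(chain, chain[1:]):
        os_ = (graph.edges[a, b] if graph.has_edge(a, b) else graph.edges[b, a])["os"]
        total += len(graph.nodes[b]["data"].sequence) - os_
    return total


def remove_tips(graph: nx.DiGraph, tip_len_bp: int) -> nx.DiGraph:
    """Iteratively remove short dead-end chains attached at a branch.

    A tip is a chain hanging from a node that has an alternative branch;
    the chain is removed when its assembled length is below
    ``tip_len_bp``.  Isolated linear chains (whole low-coverage genes)
    are never removed.  Runs to fixpoint.
    """
    if tip_len_bp <= 0:
        raise ValueError("tip_len_bp must be > 0")
    changed = True
    while changed:
        changed = False
        for node in sorted(graph.nodes):
            if node not in graph:
                continue
            chain = _dead_end_chain(graph, node, forward=True)
            if chain is None:
                chain = _dead_end_chain(graph, node, forward=False)
            if chain is None:
                continue
            if _chain_bp(graph, chain) < tip_len_bp:
                graph.remove_nodes_from(chain)
                changed = True
    return graph


def _dead_end_chain(graph: nx.DiGraph, start: str, forward: bool):
    """Chain from a dead end to (excluding) a junction with an alternative.

    Returns the removable chain node list, or None if ``start`` is not a
    removable dead end (no junction, or structure keeps branching).
    """
    indeg = graph.in_degree
    outdeg = graph.out_degree
    step = graph.successors if forward else graph.predecessors
    near, far = (indeg, outdeg) if forward else (outdeg, indeg)
    if near(start) != 0:
        return None
    chain = [start]
    cur = start
    while True:
        if far(cur) == 0:
            return None  # isolated chain: keep
        if far(cur) > 1:
            return None  # chain itself branches: not a simple tip
        nxt = next(iter(step(cur)))
        if near(nxt) >= 2:
            return chain  # junction with an alternative branch
        if far(nxt) > 1:
            return None
        chain.append(nxt)
        cur = nxt


def _as_merged(node_id: str, payload) -> MergedNode:
    if isinstance(payload, MergedNode):
        return payload
    assert isinstance(payload, GraphNode)
    L = len(payload.sequence)
    return MergedNode(
        node_id=node_id,
        member_reads=list(payload.member_reads),
        sequence=payload.sequence,
        coverage=float(payload.multiplicity),
        model_span_aa=(payload.hit.model_start_aa, payload.hit.model_end_aa),
        read_offsets={r: 0 for r in payload.member_reads},
        read_lengths={r: L for r in payload.member_reads},
        total_read_bp=payload.multiplicity * L,
        multiplicity=payload.multiplicity,
    )


def _splice(seq: str, w_seq: int, nxt: str, w_nxt: int, os_: int) -> str:
    """Append ``nxt`` consuming an overlap of ``os_`` bp.

    Mismatches inside the overlap are resolved by multiplicity-weighted
    majority; ties keep the earlier read's base.
    """
    if os_ > len(seq) or os_ > len(nxt):
        raise ValueError(
            f"inconsistent splice: overlap {os_} exceeds member length "
            f"({len(seq)} / {len(nxt)})"
        )
    left = seq[len(seq) - os_ :]
    right = nxt[:os_]
    if left != right:
        merged = [
            (rb if w_nxt > w_seq else lb) for lb, rb in zip(left, right)
        ]
        seq = seq[: len(seq) - os_] + "".join(merged)
    return seq + nxt[os_:]


def _chains(graph: nx.DiGraph) -> list[list[str]]:
    """Maximal unambiguous chains, deterministic order."""
    def mergeable(u, v):
        return graph.out_degree(u) == 1 and graph.in_degree(v) == 1

    heads = []
    for n in sorted(graph.nodes):
        preds = list(graph.predecessors(n))
        if len(preds) == 1 and mergeable(preds[0], n):
            continue
        heads.append(n)
    chains = []
    seen = set()
    for head in heads:
        chain = [head]
        seen.add(head)
        cur = head
        while graph.out_degree(cur) == 1:
            nxt = next(iter(graph.successors(cur)))
            if graph.in_degree(nxt) != 1 or nxt in seen:
                break
            chain.append(nxt)
            seen.add(nxt)
            cur = nxt
        chains.append(chain)
    # pure cycles have no head; break each at its smallest node id
    for n in sorted(graph.nodes):
        if n in seen:
            continue
        chain = [n]
        seen.add(n)
        cur = n
        while True:
            nxt = next(iter(graph.successors(cur)))
            if nxt in seen:
                break
            chain.append(nxt)
            seen.add(nxt)
            cur = nxt
        chains.append(chain)
    return chains


def merge_chains(
    graph: nx.DiGraph,
    registry: Optional[SupportRegistry] = None,
    mate_pairs: Optional[Iterable[tuple[str, str]]] = None,
    insert_size_bp: int = 0,
) -> tuple[nx.DiGraph, SupportRegistry]:
    """Collapse maximal unambiguous chains into :class:`MergedNode`s.

    Sequences are concatenated with overlap-consumed splices; coverage
    is recomputed per merged node.  The support registry is re-keyed to
    merged node ids and paired-end supports are populated from mates
    whose reads sit in different merged nodes.
    """
    registry = registry or SupportRegistry()
    chains = _chains(graph)
    mapping: dict[str, str] = {}
    merged_nodes: dict[str, MergedNode] = {}
    for chain in chains:
        head = chain[0]
        parts = [_as_merged(n, graph.nodes[n]["data"]) for n in chain]
        seq = parts[0].sequence
        offsets = {head: 0}
        weight = parts[0].multiplicity
        for prev, node, part in zip(chain, chain[1:], parts[1:]):
            os_ = graph.edges[prev, node]["os"]
            offsets[node] = len(seq) - os_
            seq = _splice(seq, weight, part.sequence, part.multiplicity, os_)
            weight = part.multiplicity
        member_reads: list[str] = []
        read_offsets: dict[str, int] = {}
        read_lengths: dict[str, int] = {}
        total_bp = 0
        for node, part in zip(chain, parts):
            member_reads.extend(part.member_reads)
            for r in part.member_reads:
                read_offsets[r] = offsets[node] + part.read_offsets[r]
                read_lengths[r] = part.read_lengths[r]
            total_bp += part.total_read_bp
            mapping[node] = head
        merged_nodes[head] = MergedNode(
            node_id=head,
            member_reads=member_reads,
            sequence=seq,
            coverage=total_bp / len(seq),
            model_span_aa=(
                min(p.model_span_aa[0] for p in parts),
                max(p.model_span_aa[1] for p in parts),
            ),
            read_offsets=read_offsets,
            read_lengths=read_lengths,
            total_read_bp=total_bp,
            multiplicity=sum(p.multiplicity for p in parts),
        )
    out = nx.DiGraph(**graph.graph)
    for node_id, data in merged_nodes.items():
        out.add_node(node_id, data=data)
    for u, v, attrs in graph.edges(data=True):
        mu, mv = mapping[u], mapping[v]
        if mu != mv:  # interior chain edges are consumed by the merge
            out.add_edge(mu, mv, **attrs)
    new_registry = registry.rekey(mapping, out)
    if mate_pairs:
        read_home = {
            r: nid for nid, data in merged_nodes.items() for r in data.member_reads
        }
        for ra, rb in mate_pairs:
            na, nb = read_home.get(ra), read_home.get(rb)
            if na is None or nb is None or na == nb:
                continue
            da, db = merged_nodes[na], merged_nodes[nb]
            new_registry.pe_pairs.append(
                PESupport(
                    node_a=na,
                    node_b=nb,
                    pos_a=da.read_offsets[ra],
                    pos_b=db.read_offsets[rb],
                    len_a=da.read_lengths[ra],
                    len_b=db.read_lengths[rb],
                    insert_size_bp=insert_size_bp,
                )
            )
    return out, new_registry


def default_tip_len(graph: nx.DiGraph) -> int:
    """2x the mean member-read length of the graph (>= 1)."""
    lengths = []
    for _n, data in graph.nodes(data="data"):
        if isinstance(data, MergedNode):
            lengths.extend(data.read_lengths.values())
        else:
            lengths.append(len(data.sequence))
    if not lengths:
        return 1
    return max(1, int(round(2 * sum(lengths) / len(lengths))))


def simplify(
    graph: nx.DiGraph,
    params: Optional[SimplifyParams] = None,
    mate_pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> tuple[nx.DiGraph, SupportRegistry]:
    """Full pruning pass: inferior edges, transitive edges, tips, merge."""
    params = params or SimplifyParams()
    g = graph.copy()
    remove_inferior_edges(g)
    g, registry = remove_transitive_edges(g)
    tip_len = params.tip_len_bp or default_tip_len(g)
    remove_tips(g, tip_len)
    return merge_chains(
        g, registry, mate_pairs=mate_pairs, insert_size_bp=params.insert_size_bp
    )
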