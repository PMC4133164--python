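"""Support-guided bounded DFS over the simplified overlap graph.

Genes sharing a similar subsequence meet in *chimeric nodes*; naive
traversal through such nodes splices different genes into one contig.
Three kinds of information steer the search away from chimeric paths:

* **critical supports** — a transitive-edge record or an
  insert-consistent paired-end link between a branch successor and a
  node already on the path; it tells the traversal which branch belongs
  to the current gene;
* **coverage continuity** — sequencing depth along one gene varies
  gradually, so at an unsupported branch the successor whose coverage is
  closest to the current path's is preferred, and only if the ratio is
  bounded;
* **paired-end expectation** — in paired mode, if a mate pair spanning
  from a visited node to the candidate would be geometrically feasible
  at the library insert size yet no support of any kind links the
  candidate to the path, the candidate likely belongs to a different
  gene or isoform: the path is emitted as-is and a new path starts at
  the candidate.

The DFS is bounded: it branches only on critical supports, follows at
most one successor otherwise, and each node can seed at most one new
path after a truncation, so the number of emitted paths stays linear in
the graph size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .graph_simplify import MergedNode, SupportRegistry, _splice

__all__ = [
    "TraversalParams",
    "ContigPath",
    "is_chimeric_node",
    "classify_supports",
    "traverse",
    "resolve_isoforms",
]

logger = logging.getLogger(__name__)

CRITICAL = "critical"
NON_CRITICAL = "non_critical"
NONE = "none"


@dataclass
class TraversalParams:
    """Knobs of the guided traversal.

    ``coverage_ratio_max`` bounds the ratio between consecutive
    non-chimeric node coverages still considered "similar" (scale-free,
    default 2.0).  ``min_critical_supports`` is the per-path emission
    threshold; the default 0 emits every generated path, and raising it
    restricts output to well-supported paths in complex data (paths in
    branch-free components are always emitted).  Insert statistics
    enable the paired-end rules; a pe link counts only when the implied
    path distance is within ``insert_tolerance_sd`` standard deviations
    of the mean.
    """

    coverage_ratio_max: float = 2.0
    min_critical_supports: int = 0
    pe_insert_mean: Optional[float] = None
    pe_insert_sd: float = 0.0
    insert_tolerance_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.coverage_ratio_max <= 1:
            raise ValueError("coverage_ratio_max must be > 1")
        if self.min_critical_supports < 0:
            raise ValueError("min_critical_supports must be >= 0")


@dataclass
class ContigPath:
    """An emitted traversal path and its assembled sequence."""

    node_ids: list[str]
    sequence: str
    critical_support_count: int
    family_id: str = ""
    model_span_aa: tuple[int, int] = (0, 0)

    @property
    def member_reads(self) -> list[str]:
        return self._member_reads

    _member_reads: list[str] = field(default_factory=list, repr=False)
    read_offsets: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def n_reads(self) -> int:
        return len(self._member_reads)


def is_chimeric_node(graph: nx.DiGraph, node: str) -> bool:
    """Shared-node signature: joined from >=2 genes on both sides."""
    return graph.in_degree(node) >= 2 and graph.out_degree(node) >= 2


def _node(graph: nx.DiGraph, n: str) -> MergedNode:
    return graph.nodes[n]["data"]


def _pe_consistent(
    sup, v: str, off_v: int, off_c: int, params: TraversalParams
) -> bool:
    """Is the implied path distance of a pe link consistent with the insert?"""
    if params.pe_insert_mean is None:
        return True
    if sup.node_a == v:
        pos_v, pos_c, len_c = sup.pos_a, sup.pos_b, sup.len_b
    else:
        pos_v, pos_c, len_c = sup.pos_b, sup.pos_a, sup.len_a
    implied = (off_c + pos_c + len_c) - (off_v + pos_v)
    tol = params.insert_tolerance_sd * params.pe_insert_sd
    return abs(implied - params.pe_insert_mean) <= tol


def _supported_by(
    graph: nx.DiGraph,
    path: list[str],
    offsets: list[int],
    candidate: str,
    off_c: int,
    registry: SupportRegistry,
    params: TraversalParams,
) -> bool:
    for v, off_v in zip(path, offsets):
        if registry.has_transitive(v, candidate):
            return True
        for sup in registry.pe_between(v, candidate):
            if _pe_consistent(sup, v, off_v, off_c, params):
                return True
    return False


def classify_supports(
    graph: nx.DiGraph,
    path: list[str],
    offsets: list[int],
    candidate: str,
    registry: SupportRegistry,
    params: TraversalParams,
) -> str:
    """Classify the support status of extending ``path`` by ``candidate``.

    *critical* — a support links the candidate to a visited node AND the
    path's last node has >=2 successors, so the support disambiguates a
    real branch; *non_critical* — a support exists but the last node has
    a single successor (any path through it must take the candidate
    anyway); *none* otherwise.  Paired-end supports count only when
    their implied path distance matches the insert size.
    """
    last = path[-1]
    data_last = _node(graph, last)
    off_c = offsets[-1] + len(data_last.sequence) - graph.edges[last, candidate]["os"]
    linked = _supported_by(graph, path, offsets, candidate, off_c, registry, params)
    if not linked:
        return NONE
    return CRITICAL if graph.out_degree(last) >= 2 else NON_CRITICAL


def _typical_read_len(graph: nx.DiGraph) -> int:
    lens = []
    for _n, data in graph.nodes(data="data"):
        lens.extend(data.read_lengths.values())
    if not lens:
        return 0
    lens.sort()
    return lens[len(lens) // 2]


def _pe_expected_but_absent(
    graph: nx.DiGraph,
    path: list[str],
    offsets: list[int],
    candidate: str,
    off_c: int,
    registry: SupportRegistry,
    params: TraversalParams,
    read_len: int,
) -> bool:
    """Paired-end expectation rule (see module docstring).

    For each visited node ``v`` not overlapping the candidate, a mate
    pair (one mate wholly in ``v``, the other wholly in the candidate)
    is *expected* when a fragment of the mean insert size fits the
    implied path geometry with at least one insert-sd of slack.  If any
    such expected pair is absent (no pe link, no transitive pair), the
    candidate likely belongs to a different gene or isoform.
    """
    if params.pe_insert_mean is None or not registry.pe_pairs or read_len <= 0:
        return False
    len_c = len(_node(graph, candidate).sequence)
    margin = params.pe_insert_sd
    for v, off_v in zip(path, offsets):
        if graph.has_edge(v, candidate):
            continue
        len_v = len(_node(graph, v).sequence)
        min_frag = off_c - off_v - len_v + 2 * read_len
        max_frag = off_c + len_c - off_v
        if not (min_frag + margin <= params.pe_insert_mean <= max_frag - margin):
            continue
        if registry.has_transitive(v, candidate):
            continue
        if any(
            _pe_consistent(sup, v, off_v, off_c, params)
            for sup in registry.pe_between(v, candidate)
        ):
            continue
        return True
    return False


def _assemble(graph: nx.DiGraph, path: list[str]) -> ContigPath:
    first = _node(graph, path[0])
    seq = first.sequence
    node_offsets = {path[0]: 0}
    weight = first.multiplicity
    for prev, cur in zip(path, path[1:]):
        data = _node(graph, cur)
        os_ = graph.edges[prev, cur]["os"]
        node_offsets[cur] = len(seq) - os_
        seq = _splice(seq, weight, data.sequence, data.multiplicity, os_)
        weight = data.multiplicity
    members: list[str] = []
    read_offsets: dict[str, int] = {}
    for n in path:
        data = _node(graph, n)
        members.extend(data.member_reads)
        for r in data.member_reads:
            read_offsets[r] = node_offsets[n] + data.read_offsets[r]
    spans = [_node(graph, n).model_span_aa for n in path]
    cp = ContigPath(
        node_ids=list(path),
        sequence=seq,
        critical_support_count=0,
        family_id=graph.graph.get("family_id", ""),
        model_span_aa=(min(s[0] for s in spans), max(s[1] for s in spans)),
    )
    cp._member_reads = members
    cp.read_offsets = read_offsets
    return cp


def _last_nonchimeric_coverage(graph: nx.DiGraph, path: list[str]) -> float:
    for n in reversed(path):
        if not is_chimeric_node(graph, n):
            return _node(graph, n).coverage
    return _node(graph, path[-1]).coverage


def traverse(
    graph: nx.DiGraph,
    registry: Optional[SupportRegistry] = None,
    params: Optional[TraversalParams] = None,
) -> list[ContigPath]:
    """Emit contig paths from the simplified graph (see module docstring).

    The DFS starts from every in-degree-0 node (and, after the main
    pass, from any node still unreached, to cover cycles and truncation
    fragments).  Successors are explored in ascending node id, so output
    is deterministic.
    """
    registry = registry or SupportRegistry()
    params = params or TraversalParams()
    read_len = _typical_read_len(graph)
    if not graph:
        return []

    branchy: dict[str, bool] = {}
    for comp in nx.weakly_connected_components(graph):
        has_branch = any(
            graph.out_degree(n) >= 2 or graph.in_degree(n) >= 2 for n in comp
        )
        for n in comp:
            branchy[n] = has_branch

    max_paths = 4 * graph.number_of_nodes() + 16
    emitted: list[tuple[list[str], int]] = []
    visited: set[str] = set()
    started: set[str] = set()
    pending: list[str] = sorted(n for n in graph if graph.in_degree(n) == 0)
    started.update(pending)

    def emit(path: list[str], crit: int) -> None:
        emitted.append((path, crit))
        visited.update(path)

    def enqueue(node: str) -> None:
        if node not in started:
            started.add(node)
            pending.append(node)

    def extend(path: list[str], offsets: list[int], crit: int) -> None:
        stack = [(path, offsets, crit)]
        while stack:
            path, offsets, crit = stack.pop()
            if len(emitted) >= max_paths:
                logger.warning("path budget exhausted; emitting truncated result")
                emit(path, crit)
                continue
            last = path[-1]
            visited.add(last)
            succs = sorted(graph.successors(last))
            cands = [s for s in succs if s not in path]
            if len(cands) < len(succs):
                logger.warning("cycle back-edge broken at node %s", last)
            if not cands:
                emit(path, crit)
                continue

            def off_of(c: str) -> int:
                return offsets[-1] + len(_node(graph, last).sequence) - graph.edges[
                    last, c
                ]["os"]

            if len(succs) == 1:
                c = cands[0]
                oc = off_of(c)
                if _pe_expected_but_absent(
                    graph, path, offsets, c, oc, registry, params, read_len
                ):
                    emit(path, crit)
                    enqueue(c)
                    continue
                stack.append((path + [c], offsets + [oc], crit))
                continue

            # branch: critical supports first
            crits = [
                c
                for c in cands
                if classify_supports(graph, path, offsets, c, registry, params)
                == CRITICAL
            ]
            if crits:
                for c in reversed(crits):
                    stack.append((path + [c], offsets + [off_of(c)], crit + 1))
                continue

            # coverage continuity among non-chimeric successors
            ref = _last_nonchimeric_coverage(graph, path)
            pool = []
            for c in cands:
                if is_chimeric_node(graph, c):
                    continue
                cov = _node(graph, c).coverage
                ratio = max(cov, ref) / max(min(cov, ref), 1e-12)
                if ratio <= params.coverage_ratio_max:
                    pool.append((ratio, -cov, c))
            if pool:
                pool.sort()
                c = pool[0][2]
                oc = off_of(c)
                if not _pe_expected_but_absent(
                    graph, path, offsets, c, oc, registry, params, read_len
                ):
                    stack.append((path + [c], offsets + [oc], crit))
                    continue
            # no appropriate successor: output and restart from successors
            emit(path, crit)
            for c in cands:
                enqueue(c)

    while pending:
        start = pending.pop(0)
        if start in graph:
            extend([start], [0], 0)

    # cover cycles and components unreached from any root
    for n in sorted(graph.nodes):
        if n not in visited:
            enqueue(n)
    while pending:
        start = pending.pop(0)
        extend([start], [0], 0)

    out: list[ContigPath] = []
    seen_paths = set()
    for path, crit in emitted:
        key = tuple(path)
        if key in seen_paths:
            continue
        seen_paths.add(key)
        if branchy.get(path[0], False) and crit < params.min_critical_supports:
            continue
        cp = _assemble(graph, path)
        cp.critical_support_count = crit
        out.append(cp)
    out.sort(key=lambda c: c.node_ids)
    return out


def resolve_isoforms(
    graph: nx.DiGraph,
    registry: SupportRegistry,
    params: Optional[TraversalParams] = None,
) -> list[ContigPath]:
    """Traverse an isoform-structured graph into per-isoform contig paths.

    Distinct splice forms correspond to distinct root-to-sink paths;
    paired-end supports at the splice forks let the DFS follow every
    isoform branch, and the paired-end expectation rule truncates
    chimeric chains whose halves come from different isoforms.
    """
    return traverse(graph, registry, params)
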