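"""Deterministic synthetic data for every pipeline stage.

Families of homologous genes with tunable pairwise identity, alternative
splicing (AS) isoform groups, heterogeneous but gradually varying
coverage, paired-end reads with a stated insert size, and substitution
errors — everything the assembler consumes — are generated from a seed,
so the whole pipeline is testable without external searches or
downloads.  Alignment hits are synthesized from the true read positions
(model coordinate = codon index, optionally jittered), which emulates a
profile-HMM search over well-conserved families.

Besides the read-level generator, this module builds small assembly
graphs directly (the shared-block two-gene graph and the four AS case
graphs), mirroring the structures that arise when two genes or two
isoforms share a subsequence; these drive the traversal tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .classify import reverse_complement
from .graph_simplify import MergedNode, PESupport, SupportRegistry
from .io_formats import AlignmentHit, ReadRecord, TruthTable
from .metrics_eval import GeneSegment

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_family",
    "gene_segment_example",
    "GeneSegmentExample",
    "shared_block_graph",
    "as_case_graph",
    "AS_CASES",
]

AS_CASES = ("A", "B", "C", "D")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one simulated family.

    Defaults emulate a typical short-read experiment over one family:
    ~1 kb coding genes, 100 bp paired reads at 20x mean depth with a
    300 +- 30 bp insert, smooth (sinusoidal) positional depth modulation
    of amplitude 0.3, and a 0.2% substitution error rate.  ``identity``
    is the pairwise identity of each additional homolog to the first
    gene.  ``hit_jitter_aa`` perturbs the synthesized alignment
    coordinates to emulate imprecise alignment ends.
    """

    seed: int = 0
    n_genes: int = 1
    identity: float = 0.85
    gene_length: int = 999
    depth: float = 20.0
    coverage_amplitude: float = 0.3
    read_length: int = 100
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    as_case: Optional[str] = None
    hit_jitter_aa: int = 0
    family_id: str = "fam1"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.gene_length < 3 * self.read_length:
            raise ValueError("need >=1 gene and gene_length >= 3 read lengths")
        if not (0 < self.identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if self.n_genes > 1 and self.identity == 1:
            raise ValueError("multi-gene families need identity < 1")
        if self.as_case is not None and self.as_case not in AS_CASES:
            raise ValueError(f"as_case must be one of {AS_CASES}")
        if self.as_case is not None and self.n_genes > 1 and self.identity < 0.95:
            raise ValueError(
                "identity too low to retain the shared blocks the AS case requires"
            )


@dataclass
class SimOutput:
    """Reads, synthesized hits, truth tables and source sequences."""

    reads: list[ReadRecord]
    hits: list[AlignmentHit]
    truth: TruthTable
    genes: dict[str, str]
    mate_pairs: list[tuple[str, str]] = field(default_factory=list)
    family_id: str = "fam1"
    config: Optional[SimConfig] = None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position with probability ``rate`` (never to itself)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def _paralog(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Derive a homolog at the target identity by quasi-periodic substitution.

    Coding-sequence divergence recurs every few codons (synonymous sites
    keep accumulating changes), so substitutions are spread with
    near-regular spacing rather than iid: inter-substitution gaps are
    drawn uniformly from mean-gap +- 2 bp.  This also bounds the longest
    exact run shared between the homologs, giving the two-homolog
    stress scenario a defined shared-block structure.
    """
    rate = 1 - identity
    if rate <= 0:
        return seq
    mean_gap = 1.0 / rate
    arr = bytearray(seq.encode())
    pos = int(round(rng.uniform(max(1.0, mean_gap - 2), mean_gap + 2))) - 1
    while pos < len(arr):
        choices = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
        pos += max(2, int(round(rng.uniform(mean_gap - 2, mean_gap + 2))))
    return arr.decode()


def _positional_weights(
    rng: np.random.Generator, n_starts: int, amplitude: float
) -> np.ndarray:
    phase = rng.uniform(0, 2 * math.pi)
    x = np.arange(n_starts)
    w = 1.0 + amplitude * np.sin(2 * math.pi * x / max(n_starts, 1) + phase)
    w = np.clip(w, 1e-6, None)
    return w / w.sum()


def _codon_hit(start_bp: int, end_bp: int) -> Optional[tuple[int, int, int, int]]:
    """Fully covered codon window of a source interval.

    Returns (model_start_aa, model_end_aa, offset of the codon window
    inside the interval, window length in bp), or None if no full codon
    is covered.
    """
    c0 = -(-start_bp // 3)  # first fully covered codon (0-based)
    c1 = end_bp // 3  # one past the last fully covered codon
    if c1 <= c0:
        return None
    return c0 + 1, c1, 3 * c0 - start_bp, 3 * (c1 - c0)


def _isoform_structures(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Two isoform sequences for the requested AS case group.

    A: exon skipping; B: shared internal region with exclusive flanks on
    opposite sides (alternative first/last exons); C: intron retention;
    D: mutually exclusive exons.  Region lengths scale with the
    configured gene length.
    """
    L = cfg.gene_length - cfg.gene_length % 3
    unit = max(3 * (L // 15), 3 * cfg.read_length // 3)
    flank = 2 * unit
    mid = unit
    r1 = _random_seq(rng, flank)
    r2 = _random_seq(rng, flank)
    case = cfg.as_case
    if case == "A":
        ex = _random_seq(rng, mid)
        return {"iso1": r1 + ex + r2, "iso2": r1 + r2}
    if case == "B":
        shared = _random_seq(rng, mid)
        return {"iso1": r1 + shared, "iso2": shared + r2}
    if case == "C":
        intron = _random_seq(rng, mid)
        return {"iso1": r1 + intron + r2, "iso2": r1 + r2}
    if case == "D":
        ea = _random_seq(rng, mid)
        eb = _random_seq(rng, mid)
        return {"iso1": r1 + ea + r2, "iso2": r1 + eb + r2}
    raise AssertionError(case)


def simulate_family(cfg: SimConfig) -> SimOutput:
    """Generate one family: sequences, reads, hits and truth tables.

    Paralogs are produced by seeded point substitution of the first gene
    down to the target identity.  Reads are tiled by sampling fragment
    start positions from the smooth positional depth profile; paired
    mates sit at the sampled insert distance, the second mate
    reverse-complemented.  Hits mirror the true codon coordinates (plus
    optional jitter), so downstream stages see the geometry a homology
    search would report for a well-conserved family.
    """
    rng = np.random.default_rng(cfg.seed)
    # separate stream so coordinate jitter never shifts read sampling
    jitter_rng = np.random.default_rng((cfg.seed, 1))
    sources: dict[str, tuple[str, str]] = {}  # source_id -> (sequence, isoform_id)
    if cfg.as_case is not None:
        for iso_id, seq in _isoform_structures(cfg, rng).items():
            sources[iso_id] = (seq, iso_id)
    else:
        L = cfg.gene_length - cfg.gene_length % 3
        g1 = _random_seq(rng, L)
        sources["g1"] = (g1, "g1")
        for k in range(2, cfg.n_genes + 1):
            sources[f"g{k}"] = (_paralog(rng, g1, cfg.identity), f"g{k}")

    truth = TruthTable()
    for sid, (seq, _iso) in sources.items():
        truth.gene_lengths[sid] = len(seq)

    reads: list[ReadRecord] = []
    hits: list[AlignmentHit] = []
    mate_pairs: list[tuple[str, str]] = []
    rl = cfg.read_length

    def add_read(rid, seq, gene, start, iso, mate_id=None, mate_index=None, minus=False):
        err_seq = _mutate(rng, seq, cfg.error_rate)
        record_seq = reverse_complement(err_seq) if minus else err_seq
        reads.append(
            ReadRecord(
                read_id=rid,
                sequence=record_seq,
                mate_id=mate_id,
                mate_index=mate_index,
            )
        )
        truth.reads[rid] = (gene, start, start + len(seq), iso)
        ch = _codon_hit(start, start + len(seq))
        if ch is None:
            return
        m0, m1, off, span = ch
        if cfg.hit_jitter_aa:
            j = int(jitter_rng.integers(-cfg.hit_jitter_aa, cfg.hit_jitter_aa + 1))
            k = int(jitter_rng.integers(-cfg.hit_jitter_aa, cfg.hit_jitter_aa + 1))
            m0, m1 = max(1, m0 + j), max(1, m1 + k)
            if m1 < m0:
                m0, m1 = m1, m0
        rs, re_ = off, off + span
        if minus:
            rs, re_ = len(seq) - re_, len(seq) - rs
        hits.append(
            AlignmentHit(
                read_id=rid,
                family_id=cfg.family_id,
                evalue=float(10.0 ** -max(1.0, span / 10.0)),
                model_start_aa=m0,
                model_end_aa=m1,
                read_start_bp=rs,
                read_end_bp=re_,
                strand="-" if minus else "+",
                frame=0,
            )
        )

    for sid in sorted(sources):
        seq, iso = sources[sid]
        L = len(seq)
        n_reads = int(round(cfg.depth * L / rl))
        if cfg.paired:
            n_frags = max(1, n_reads // 2)
            frag_lens = np.clip(
                np.round(rng.normal(cfg.insert_mean, cfg.insert_sd, n_frags)),
                2 * rl,
                L,
            ).astype(int)
            max_start = L - frag_lens
            weights = _positional_weights(rng, L, cfg.coverage_amplitude)
            for i in range(n_frags):
                w = weights[: max_start[i] + 1]
                s = int(rng.choice(max_start[i] + 1, p=w / w.sum()))
                f = int(frag_lens[i])
                r1_id, r2_id = f"{sid}_{i:05d}/1", f"{sid}_{i:05d}/2"
                add_read(r1_id, seq[s : s + rl], sid, s, iso, mate_id=r2_id, mate_index=1)
                add_read(
                    r2_id,
                    seq[s + f - rl : s + f],
                    sid,
                    s + f - rl,
                    iso,
                    mate_id=r1_id,
                    mate_index=2,
                    minus=True,
                )
                mate_pairs.append((r1_id, r2_id))
        else:
            weights = _positional_weights(rng, L - rl + 1, cfg.coverage_amplitude)
            starts = rng.choice(L - rl + 1, size=n_reads, p=weights)
            for i, s in enumerate(sorted(int(x) for x in starts)):
                add_read(f"{sid}_{i:05d}", seq[s : s + rl], sid, s, iso)

    return SimOutput(
        reads=reads,
        hits=hits,
        truth=truth,
        genes={sid: seq for sid, (seq, _i) in sources.items()},
        mate_pairs=mate_pairs,
        family_id=cfg.family_id,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Worked evaluation example
# ---------------------------------------------------------------------------


@dataclass
class GeneSegmentExample:
    """The textbook gene-segment example used to pin the metric definitions.

    Gene 1 (1000 bp) is covered by contig C1 (segment on gene bases
    0-400) and contig C2 (gene bases 500-800); contig C3 correctly
    spans gene 1 and gene 2 entirely, with pure (single-origin) reads in
    both of its segments.
    """

    gene_lengths: dict[str, int]
    contig_segments: dict[str, list[GeneSegment]]


def gene_segment_example() -> GeneSegmentExample:
    genes = {"gene1": 1000, "gene2": 800}
    segs = {
        "C1": [
            GeneSegment("C1", "gene1", (50, 450), (0, 400), is_chimeric=False)
        ],
        "C2": [
            GeneSegment("C2", "gene1", (0, 300), (500, 800), is_chimeric=False)
        ],
        "C3": [
            GeneSegment("C3", "gene1", (100, 1100), (0, 1000), is_chimeric=False),
            GeneSegment("C3", "gene2", (1150, 1950), (0, 800), is_chimeric=False),
        ],
    }
    return GeneSegmentExample(gene_lengths=genes, contig_segments=segs)


# ---------------------------------------------------------------------------
# Constructed assembly graphs (shared-block and AS cases)
# ---------------------------------------------------------------------------


def _graph_node(
    node_id: str,
    sequence: str,
    coverage: float,
    span_aa: tuple[int, int],
    read_len: int,
) -> MergedNode:
    rep = f"{node_id}_rep"
    return MergedNode(
        node_id=node_id,
        member_reads=[rep],
        sequence=sequence,
        coverage=coverage,
        model_span_aa=span_aa,
        read_offsets={rep: 0},
        read_lengths={rep: read_len},
        total_read_bp=int(coverage * len(sequence)),
        multiplicity=max(1, int(coverage)),
    )


def _add_pe_supports(
    registry: SupportRegistry,
    node_intervals: dict[str, tuple[int, int]],
    iso_len: int,
    read_len: int,
    insert: int,
    step: int = 10,
) -> None:
    """Tile fragments of exactly ``insert`` bp along one isoform and
    register every mate pair whose mates lie wholly in different nodes."""
    seen = set()
    for s in range(0, iso_len - insert + 1, step):
        m1 = (s, s + read_len)
        m2 = (s + insert - read_len, s + insert)
        homes1 = [
            (n, m1[0] - iv[0])
            for n, iv in node_intervals.items()
            if iv[0] <= m1[0] and m1[1] <= iv[1]
        ]
        homes2 = [
            (n, m2[0] - iv[0])
            for n, iv in node_intervals.items()
            if iv[0] <= m2[0] and m2[1] <= iv[1]
        ]
        for na, pa in homes1:
            for nb, pb in homes2:
                if na == nb:
                    continue
                key = (na, nb, pa, pb)
                if key in seen:
                    continue
                seen.add(key)
                registry.pe_pairs.append(
                    PESupport(na, nb, pa, pb, read_len, read_len, insert)
                )


def shared_block_graph(
    seed: int = 0,
    block_len: int = 150,
    flank_len: int = 260,
    overlap: int = 40,
    cov_a: float = 20.0,
    cov_b: float = 22.0,
    pe_support: bool = True,
) -> tuple[nx.DiGraph, SupportRegistry, dict[str, str]]:
    """Two genes sharing an identical internal block, post-merge shape.

    Gene A = Pa + X + Sa and gene B = Pb + X + Sb share the block X, so
    the merged graph has one shared (chimeric) node ``x`` with two
    entries and two exits.  Supports: a transitive pair joins gene A's
    flanks; a paired-end pair joins gene B's flanks (when ``pe_support``).
    Returns (graph, registry, node->gene map); the chimeric node maps to
    "shared".
    """
    rng = np.random.default_rng(seed)
    pa, sa = _random_seq(rng, flank_len), _random_seq(rng, flank_len)
    pb, sb = _random_seq(rng, flank_len), _random_seq(rng, flank_len)
    x = _random_seq(rng, block_len)
    nodes = {
        "a1": pa + x[:overlap],
        "b1": pb + x[:overlap],
        "x": x,
        "a2": x[-overlap:] + sa,
        "b2": x[-overlap:] + sb,
    }
    cov = {"a1": cov_a, "a2": cov_a, "b1": cov_b, "b2": cov_b, "x": cov_a + cov_b}
    span = {
        "a1": (1, (flank_len + overlap) // 3),
        "b1": (1, (flank_len + overlap) // 3),
        "x": (flank_len // 3, (flank_len + block_len) // 3),
        "a2": ((flank_len + block_len - overlap) // 3, (2 * flank_len + block_len) // 3),
        "b2": ((flank_len + block_len - overlap) // 3, (2 * flank_len + block_len) // 3),
    }
    g = nx.DiGraph(family_id="fam_shared")
    for nid, seq in nodes.items():
        g.add_node(nid, data=_graph_node(nid, seq, cov[nid], span[nid], 100))
    for u, v in (("a1", "x"), ("b1", "x"), ("x", "a2"), ("x", "b2")):
        g.add_edge(u, v, os=overlap, oa=3 * (overlap // 3), hamming=0, d=0.0)
    registry = SupportRegistry()
    registry.add_transitive("a1", "a2")
    if pe_support:
        registry.pe_pairs.append(
            PESupport("b1", "b2", flank_len - 50, 10, 100, 100, 0)
        )
    origin = {"a1": "geneA", "a2": "geneA", "b1": "geneB", "b2": "geneB", "x": "shared"}
    return g, registry, origin


def as_case_graph(
    case: str, seed: int = 0
) -> tuple[nx.DiGraph, SupportRegistry, dict[str, str], dict[str, str]]:
    """Post-merge overlap graph of one AS case group, with paired truth.

    Returns (graph, registry, node->label, isoform sequences); labels
    are "shared", "iso1" or "iso2".  Geometry uses 100 bp reads and a
    300 bp insert; paired-end supports are tiled along each isoform, so
    splice forks carry the evidence the traversal needs while
    cross-isoform node pairs have none.
    """
    if case not in AS_CASES:
        raise ValueError(f"unknown AS case {case!r}")
    rng = np.random.default_rng(seed)
    rl, insert = 100, 300
    g = nx.DiGraph(family_id=f"fam_as{case}")
    registry = SupportRegistry()

    if case in ("A", "C", "D"):
        r1 = _random_seq(rng, 300)
        r2 = _random_seq(rng, 300)
        mid1 = _random_seq(rng, 150)
        mid2 = _random_seq(rng, 150) if case == "D" else None
        iso1 = r1 + mid1 + r2
        iso2 = r1 + (mid2 if case == "D" else "") + r2
        labels = {"r1": "shared", "r2": "shared"}
        nodes = {
            "r1": (r1, (1, 100)),
            "r2": (r2, (151, 250)),
        }
        # isoform-1 branch
        if case == "C":
            # intron retention: two-node retained branch
            nodes["m1a"] = (iso1[240:400], (81, 133))
            nodes["m1b"] = (iso1[360:510], (121, 170))
            labels.update(m1a="iso1", m1b="iso1")
            edges1 = [("r1", "m1a", 60), ("m1a", "m1b", 40), ("m1b", "r2", 60)]
            iv1 = {"r1": (0, 300), "m1a": (240, 400), "m1b": (360, 510), "r2": (450, 750)}
        else:
            nodes["m1"] = (iso1[240:510], (81, 170))
            labels["m1"] = "iso1"
            edges1 = [("r1", "m1", 60), ("m1", "r2", 60)]
            iv1 = {"r1": (0, 300), "m1": (240, 510), "r2": (450, 750)}
        # isoform-2 branch
        if case == "D":
            nodes["m2"] = (iso2[240:510], (81, 170))
            labels["m2"] = "iso2"
            edges2 = [("r1", "m2", 60), ("m2", "r2", 60)]
            iv2 = {"r1": (0, 300), "m2": (240, 510), "r2": (450, 750)}
        else:
            nodes["j2"] = (iso2[240:360], (81, 170))
            labels["j2"] = "iso2"
            edges2 = [("r1", "j2", 60), ("j2", "r2", 60)]
            iv2 = {"r1": (0, 300), "j2": (240, 360), "r2": (300, 600)}
        for nid, (seq, span) in nodes.items():
            cov = 20.0 if labels[nid] == "shared" else 10.0
            g.add_node(nid, data=_graph_node(nid, seq, cov, span, rl))
        for u, v, os_ in edges1 + edges2:
            g.add_edge(u, v, os=os_, oa=3 * (os_ // 3), hamming=0, d=0.0)
        _add_pe_supports(registry, iv1, len(iso1), rl, insert)
        _add_pe_supports(registry, iv2, len(iso2), rl, insert)
        return g, registry, labels, {"iso1": iso1, "iso2": iso2}

    # case B: shared internal region, exclusive flanks on opposite sides
    gpart = _random_seq(rng, 250)
    shared = _random_seq(rng, 150)
    ppart = _random_seq(rng, 250)
    iso1 = gpart + shared
    iso2 = shared + ppart
    nodes = {
        "gx": (iso1[0:310], (1, 103)),
        "s": (shared, (84, 133)),
        "px": (iso2[90:400], (114, 217)),
    }
    labels = {"gx": "iso1", "s": "shared", "px": "iso2"}
    for nid, (seq, span) in nodes.items():
        cov = 20.0 if labels[nid] == "shared" else 10.0
        g.add_node(nid, data=_graph_node(nid, seq, cov, span, rl))
    g.add_edge("gx", "s", os=60, oa=60, hamming=0, d=0.0)
    g.add_edge("s", "px", os=60, oa=60, hamming=0, d=0.0)
    _add_pe_supports(registry, {"gx": (0, 310), "s": (250, 400)}, len(iso1), rl, insert)
    _add_pe_supports(registry, {"s": (0, 150), "px": (90, 400)}, len(iso2), rl, insert)
    return g, registry, labels, {"iso1": iso1, "iso2": iso2}
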