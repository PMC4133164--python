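"""Evaluation metrics for targeted gene assembly.

Contigs are compared against a set of reference (target) genes.  The
part of a contig that aligns within one target gene is a *gene segment*,
the unit of evaluation.  Four metrics summarize an assembly:

* **gene coverage** — fraction of a reference gene's bases covered by at
  least one gene segment (union, not sum);
* **chimera rate** — fraction of gene segments whose constituent reads
  derive from more than one source gene;
* **contig length** — mean emitted contig length in bp;
* **contig coverage** — a segment's length divided by its target gene's
  length, so long reference genes do not dominate the average.

A single contig recovering more than 90% of a gene isoform is a
*complete contig*.  All metrics are computed per family first and then
averaged (unweighted) over families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import TruthTable
from .traversal import ContigPath

__all__ = [
    "GeneSegment",
    "FamilyReport",
    "merge_intervals",
    "gene_coverage",
    "contig_coverage",
    "chimera_rate",
    "complete_contig_stats",
    "per_family_average",
    "segments_from_truth",
    "read_blast6_segments",
    "evaluate_family",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSegment:
    """The part of one contig lying within one target gene.

    Intervals are 0-based half-open; ``contig_interval`` on the contig,
    ``gene_interval`` on the gene.  ``is_chimeric`` flags segments whose
    reads originate from more than one source gene.
    """

    contig_id: str
    gene_id: str
    contig_interval: tuple[int, int]
    gene_interval: tuple[int, int]
    is_chimeric: bool = False

    @property
    def length(self) -> int:
        return self.gene_interval[1] - self.gene_interval[0]


@dataclass
class FamilyReport:
    """Per-family metric bundle; rates are fractions in [0, 1]."""

    family_id: str
    gene_coverage: float = 0.0
    chimera_rate: float = 0.0
    mean_contig_length: float = 0.0
    mean_contig_coverage: float = 0.0
    pct_complete_contigs: float = 0.0
    pct_nonchimeric_among_complete: float = 0.0


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivals = sorted(i for i in intervals if i[1] > i[0])
    out: list[tuple[int, int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def gene_coverage(gene_len: int, segments: Sequence[GeneSegment]) -> float:
    """Fraction of the gene's bases covered by >=1 gene segment."""
    if gene_len <= 0:
        raise ValueError("gene_len must be positive")
    for seg in segments:
        s, e = seg.gene_interval
        if s < 0 or e > gene_len:
            raise ValueError(
                f"segment {seg.contig_id!r} outside gene (interval {s}..{e}, "
                f"gene length {gene_len})"
            )
    covered = sum(e - s for s, e in merge_intervals(s.gene_interval for s in segments))
    return covered / gene_len


def contig_coverage(segment: GeneSegment, gene_len: int) -> float:
    """Segment length normalized by the target gene length."""
    if gene_len <= 0:
        raise ValueError("gene_len must be positive")
    return segment.length / gene_len


def chimera_rate(segments: Sequence[GeneSegment], strict: bool = False) -> float:
    """Fraction of chimeric gene segments among all gene segments."""
    if not segments:
        if not strict:
            warnings.warn("chimera_rate of an empty segment list is 0 by convention")
            return 0.0
        raise ValueError("no segments")
    return sum(1 for s in segments if s.is_chimeric) / len(segments)


def complete_contig_stats(
    contig_segments: Mapping[str, Sequence[GeneSegment]],
    isoform_lengths: Mapping[str, int],
    threshold: float = 0.90,
) -> tuple[float, float]:
    """(fraction of complete contigs, fraction non-chimeric among them).

    A contig is complete when its segments on one isoform cover strictly
    more than ``threshold`` of that isoform; it is a chimeric complete
    contig when any of its segments is chimeric.
    """
    if not contig_segments:
        return 0.0, 0.0
    n_complete = 0
    n_complete_pure = 0
    for _cid, segs in contig_segments.items():
        by_iso: dict[str, list[GeneSegment]] = {}
        for s in segs:
            if s.gene_id in isoform_lengths:
                by_iso.setdefault(s.gene_id, []).append(s)
        complete = False
        for iso, iso_segs in by_iso.items():
            if gene_coverage(isoform_lengths[iso], iso_segs) > threshold:
                complete = True
                break
        if complete:
            n_complete += 1
            if not any(s.is_chimeric for s in segs):
                n_complete_pure += 1
    frac_complete = n_complete / len(contig_segments)
    frac_pure = (n_complete_pure / n_complete) if n_complete else 0.0
    return frac_complete, frac_pure


def per_family_average(reports: Sequence[FamilyReport]) -> FamilyReport:
    """Unweighted mean of each metric over families."""
    if not reports:
        raise ValueError("need at least one family report")
    n = len(reports)
    return FamilyReport(
        family_id="__average__",
        gene_coverage=sum(r.gene_coverage for r in reports) / n,
        chimera_rate=sum(r.chimera_rate for r in reports) / n,
        mean_contig_length=sum(r.mean_contig_length for r in reports) / n,
        mean_contig_coverage=sum(r.mean_contig_coverage for r in reports) / n,
        pct_complete_contigs=sum(r.pct_complete_contigs for r in reports) / n,
        pct_nonchimeric_among_complete=sum(
            r.pct_nonchimeric_among_complete for r in reports
        )
        / n,
    )


def segments_from_truth(
    contig: ContigPath,
    truth: TruthTable,
    contig_id: Optional[str] = None,
    strict: bool = True,
) -> list[GeneSegment]:
    """Derive a contig's gene segments from read-origin truth.

    Reads are grouped by source gene; each gene's segment spans the
    union of its reads on the gene and the matching stretch of the
    contig.  A segment is chimeric when a read from a *different* source
    gene lies inside the segment's contig interval.
    """
    cid = contig_id or f"{contig.family_id}|0"
    by_gene: dict[str, list[str]] = {}
    for rid in contig.member_reads:
        if rid not in truth.reads:
            if strict:
                raise ValueError(f"read {rid!r} has no truth entry")
            logger.warning("read %s skipped: no truth entry", rid)
            continue
        by_gene.setdefault(truth.reads[rid][0], []).append(rid)
    segments = []
    for gene, rids in sorted(by_gene.items()):
        gene_start = min(truth.reads[r][1] for r in rids)
        gene_end = max(truth.reads[r][2] for r in rids)
        c_start = min(contig.read_offsets[r] for r in rids)
        c_end = max(
            contig.read_offsets[r] + (truth.reads[r][2] - truth.reads[r][1])
            for r in rids
        )
        foreign = False
        for other_gene, other_rids in by_gene.items():
            if other_gene == gene:
                continue
            for r in other_rids:
                ro = contig.read_offsets[r]
                rlen = truth.reads[r][2] - truth.reads[r][1]
                if ro < c_end and ro + rlen > c_start:
                    foreign = True
                    break
            if foreign:
                break
        segments.append(
            GeneSegment(
                contig_id=cid,
                gene_id=gene,
                contig_interval=(c_start, c_end),
                gene_interval=(gene_start, gene_end),
                is_chimeric=foreign,
            )
        )
    return segments


def read_blast6_segments(path) -> list[GeneSegment]:
    """Load precomputed contig-to-gene alignments in BLAST outfmt-6 layout.

    Columns used: qseqid sseqid ... qstart qend sstart send (1-based
    inclusive, converted to internal 0-based half-open).  Chimera flags
    cannot be derived from alignments alone and default to False.
    """
    from .io_formats import FormatError, to_internal

    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: expected >=10 blast6 columns")
            qs, qe = to_internal(int(f[6]), int(f[7]))
            ss, se = sorted(to_internal(*sorted((int(f[8]), int(f[9])))))
            segments.append(
                GeneSegment(
                    contig_id=f[0],
                    gene_id=f[1],
                    contig_interval=(qs, qe),
                    gene_interval=(ss, se),
                )
            )
    return segments


def evaluate_family(
    family_id: str,
    contigs: Sequence[ContigPath],
    truth: TruthTable,
    target_genes: Optional[Sequence[str]] = None,
) -> FamilyReport:
    """Compute the full metric bundle for one family against truth."""
    contig_ids = [f"{family_id}|{i}" for i in range(len(contigs))]
    contig_segments = {
        cid: segments_from_truth(c, truth, contig_id=cid)
        for cid, c in zip(contig_ids, contigs)
    }
    all_segments = [s for segs in contig_segments.values() for s in segs]
    genes = list(target_genes) if target_genes else sorted(truth.gene_lengths)
    gene_covs = []
    for gene in genes:
        segs = [s for s in all_segments if s.gene_id == gene]
        gene_covs.append(gene_coverage(truth.gene_lengths[gene], segs))
    ccov = [
        contig_coverage(s, truth.gene_lengths[s.gene_id]) for s in all_segments
    ]
    frac_complete, frac_pure = complete_contig_stats(
        contig_segments, truth.gene_lengths
    )
    return FamilyReport(
        family_id=family_id,
        gene_coverage=sum(gene_covs) / len(gene_covs) if gene_covs else 0.0,
        chimera_rate=chimera_rate(all_segments) if all_segments else 0.0,
        mean_contig_length=(
            sum(len(c.sequence) for c in contigs) / len(contigs) if contigs else 0.0
        ),
        mean_contig_coverage=sum(ccov) / len(ccov) if ccov else 0.0,
        pct_complete_contigs=frac_complete,
        pct_nonchimeric_among_complete=frac_pure,
    )
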