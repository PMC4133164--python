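"""Readers and writers for the on-disk formats the assembler touches.

This module is the single home for coordinate-convention conversion:
internally every interval is 0-based half-open; HMMER tables and all
emitted files use 1-based inclusive coordinates.  Profile-HMM (model)
coordinates are in amino acids, read coordinates in nucleotides.
"""

from __future__ import annotations

import gzip
import os
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "AlignmentHit",
    "TruthTable",
    "FormatError",
    "to_internal",
    "to_external",
    "read_fastx",
    "read_paired_fastx",
    "read_domtblout",
    "read_hits_tsv",
    "write_hits_tsv",
    "write_contigs",
    "read_contigs",
    "write_supercontigs",
    "read_truth_tables",
]

_PAIR_SUFFIX = re.compile(r"(?:/([12])| ([12])(?::\S*)?)$")

HITS_TSV_COLUMNS = (
    "read_id",
    "family_id",
    "evalue",
    "model_start_aa",
    "model_end_aa",
    "read_start_bp",
    "read_end_bp",
    "strand",
    "frame",
)


class FormatError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclass
class ReadRecord:
    """One sequencing read.

    ``mate_id`` links the two reads of a pair; ``mate_index`` is 1 or 2.
    """

    read_id: str
    sequence: str
    quality: Optional[str] = None
    mate_id: Optional[str] = None
    mate_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")


@dataclass
class AlignmentHit:
    """One read's alignment to one family profile HMM.

    Model coordinates are 1-based inclusive amino-acid positions on the
    profile; read coordinates are 0-based half-open nucleotide positions
    on the read's forward strand.  ``frame`` is the offset (0..2) of the
    translated frame, ``strand`` is '+' or '-'.
    """

    read_id: str
    family_id: str
    evalue: float
    model_start_aa: int
    model_end_aa: int
    read_start_bp: int
    read_end_bp: int
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for read {self.read_id!r}")
        if self.model_start_aa > self.model_end_aa:
            raise ValueError(
                f"model interval reversed for read {self.read_id!r}: "
                f"{self.model_start_aa}..{self.model_end_aa}"
            )
        if not (0 <= self.read_start_bp < self.read_end_bp):
            raise ValueError(f"bad read interval for read {self.read_id!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TruthTable:
    """Read-origin and gene-length truth used by synthetic evaluation.

    ``reads`` maps read_id -> (source_gene_id, gene_start, gene_end,
    isoform_id); coordinates are 0-based half-open on the source gene.
    """

    reads: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for rid, (gene, start, end, _iso) in self.reads.items():
            if gene not in self.gene_lengths:
                raise ValueError(f"read {rid!r} references unknown gene {gene!r}")
            if not (0 <= start < end <= self.gene_lengths[gene]):
                raise ValueError(f"read {rid!r} coordinates outside gene {gene!r}")


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (inverse of :func:`to_internal`)."""
    return start0 + 1, end0


def _open_text(path: str | os.PathLike) -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise FormatError(f"{path}: not FASTA/FASTQ (first record starts {line[:20]!r})")
    return "fasta"  # empty file: treat as empty FASTA


def split_pair_name(name: str) -> tuple[str, Optional[int]]:
    """Strip a /1, /2, ' 1', ' 2' mate suffix; return (stem, mate_index)."""
    m = _PAIR_SUFFIX.search(name)
    if m:
        idx = int(m.group(1) or m.group(2))
        return name[: m.start()], idx
    return name, None


def read_fastx(path: str | os.PathLike, mate_index: Optional[int] = None) -> Iterator[ReadRecord]:
    """Stream reads from a FASTA/FASTQ file (gzip accepted).

    When ``mate_index`` is given, or a read name carries a /1 or /2
    suffix, mate links are set (``mate_id`` = the partner's read id).
    """
    path = os.fspath(path)
    fmt = _sniff_format(path)
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                stem, idx = split_pair_name(rec.id)
                if mate_index is not None:
                    idx = mate_index
                    if stem == rec.id:
                        stem = rec.id
                mate_id = None
                if idx is not None:
                    mate_id = f"{stem}/{1 if idx == 2 else 2}"
                qual = None
                if "phred_quality" in rec.letter_annotations:
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                read_id = f"{stem}/{idx}" if idx is not None else rec.id
                yield ReadRecord(
                    read_id=read_id,
                    sequence=str(rec.seq).upper(),
                    quality=qual,
                    mate_id=mate_id,
                    mate_index=idx,
                )
        except ValueError as exc:
            raise FormatError(f"{path}: malformed record ({exc})") from exc


def read_paired_fastx(path1: str | os.PathLike, path2: str | os.PathLike) -> Iterator[ReadRecord]:
    """Stream two mate files in lockstep; errors on mismatched pair counts."""
    it1 = read_fastx(path1, mate_index=1)
    it2 = read_fastx(path2, mate_index=2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise FormatError(
                f"mismatched pair counts between {path1} and {path2} after {n} pairs"
            )
        n += 1
        yield r1
        yield r2


_STRAND_FRAME = re.compile(r"^(?P<stem>.*)#(?P<strand>[+-])(?P<frame>[012])$")


def parse_translated_name(name: str) -> tuple[str, str, int]:
    """Decode the ``<read_id>#<strand><frame>`` translated-query convention."""
    m = _STRAND_FRAME.match(name)
    if not m:
        return name, "+", 0
    return m.group("stem"), m.group("strand"), int(m.group("frame"))


def frame_to_forward_bp(
    ali_from_aa: int, ali_to_aa: int, strand: str, frame: int, read_len: int
) -> tuple[int, int]:
    """Map an aa interval on a translated frame back to forward-strand bp.

    ``ali_from_aa``/``ali_to_aa`` are 1-based inclusive on the translated
    sequence of the given frame.  Returns a 0-based half-open bp interval
    on the original (forward) read.
    """
    start = frame + 3 * (ali_from_aa - 1)
    end = frame + 3 * ali_to_aa
    if strand == "+":
        return start, end
    return read_len - end, read_len - start


def read_domtblout(
    path: str | os.PathLike, read_lengths: Optional[dict[str, int]] = None
) -> Iterator[AlignmentHit]:
    """Stream AlignmentHits from a HMMER3 per-domain table (domtblout).

    The target (sequence) name may carry the ``#<strand><frame>``
    suffix produced by the classify stage's six-frame translation; when
    present, alignment coordinates (in aa on the translated frame) are
    mapped back to forward-strand bp, which requires ``read_lengths``
    for minus-strand hits.  Alignment columns (ali-from/ali-to) are
    used, not the envelope.
    """
    path = os.fspath(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise FormatError(
                    f"{path}:{lineno}: expected >=22 domtblout columns, got {len(fields)}"
                )
            target = fields[0]
            family_id = fields[3]
            try:
                evalue = float(fields[6])
                hmm_from, hmm_to = int(fields[15]), int(fields[16])
                ali_from, ali_to = int(fields[17]), int(fields[18])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric field ({exc})")
            if evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value {evalue}")
            read_id, strand, frame = parse_translated_name(target)
            if strand == "-":
                if not read_lengths or read_id not in read_lengths:
                    raise FormatError(
                        f"{path}:{lineno}: minus-strand hit for {read_id!r} "
                        "needs the read length to map coordinates"
                    )
                rlen = read_lengths[read_id]
            else:
                rlen = 0  # unused on '+'
            rs, re_ = frame_to_forward_bp(ali_from, ali_to, strand, frame, rlen)
            yield AlignmentHit(
                read_id=read_id,
                family_id=family_id,
                evalue=evalue,
                model_start_aa=hmm_from,
                model_end_aa=hmm_to,
                read_start_bp=rs,
                read_end_bp=re_,
                strand=strand,
                frame=frame,
            )


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | os.PathLike) -> None:
    """Write hits in the internal TSV dialect (external 1-based model coords)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(HITS_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.read_id,
                        h.family_id,
                        f"{h.evalue:g}",
                        h.model_start_aa,
                        h.model_end_aa,
                        h.read_start_bp,
                        h.read_end_bp,
                        h.strand,
                        h.frame,
                    )
                )
                + "\n"
            )


def read_hits_tsv(path: str | os.PathLike) -> Iterator[AlignmentHit]:
    path = os.fspath(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(HITS_TSV_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(HITS_TSV_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                yield AlignmentHit(
                    read_id=fields[0],
                    family_id=fields[1],
                    evalue=float(fields[2]),
                    model_start_aa=int(fields[3]),
                    model_end_aa=int(fields[4]),
                    read_start_bp=int(fields[5]),
                    read_end_bp=int(fields[6]),
                    strand=fields[7],
                    frame=int(fields[8]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_contigs(contigs: Sequence, path: str | os.PathLike) -> None:
    """Write contigs as FASTA with structured headers.

    Header layout: ``family|contig_index|length|n_reads|supports``.
    Accepts any objects with ``sequence``, ``family_id``, ``node_ids``
    (or ``n_reads``) and ``critical_support_count`` attributes.
    """
    with open(path, "w") as fh:
        for i, c in enumerate(contigs):
            seq = c.sequence
            if not seq:
                raise ValueError(f"contig {i} of family {c.family_id!r} is empty")
            n_reads = getattr(c, "n_reads", 0) or len(getattr(c, "node_ids", []))
            header = (
                f"{c.family_id}|{i}|{len(seq)}|{n_reads}|"
                f"{getattr(c, 'critical_support_count', 0)}"
            )
            fh.write(f">{header}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")


@dataclass
class ContigRecord:
    """A contig read back from a FASTA written by :func:`write_contigs`."""

    contig_id: str
    family_id: str
    sequence: str
    n_reads: int
    critical_support_count: int


def read_contigs(path: str | os.PathLike) -> list[ContigRecord]:
    out = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) >= 5:
            family, idx, _length, n_reads, supports = parts[:5]
            out.append(
                ContigRecord(
                    contig_id=f"{family}|{idx}",
                    family_id=family,
                    sequence=str(rec.seq),
                    n_reads=int(n_reads),
                    critical_support_count=int(supports),
                )
            )
        else:
            out.append(
                ContigRecord(
                    contig_id=rec.id,
                    family_id=rec.id,
                    sequence=str(rec.seq),
                    n_reads=0,
                    critical_support_count=0,
                )
            )
    return out


def write_supercontigs(supers: Sequence, fasta_path, tsv_path) -> None:
    """Write super-contig sequences (FASTA) and membership table (TSV).

    TSV columns: super_id, contig_id, order, orientation, estimated_gap_bp
    (gap following the member; 0 for the last member).
    """
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("#super_id\tcontig_id\torder\torientation\testimated_gap_bp\n")
        for sc in supers:
            if not sc.sequence:
                raise ValueError(f"super contig {sc.super_id!r} has empty sequence")
            fa.write(f">{sc.super_id}|{len(sc.sequence)}|{len(sc.members)}\n")
            for j in range(0, len(sc.sequence), 70):
                fa.write(sc.sequence[j : j + 70] + "\n")
            for order, (contig_id, orientation, _offset, gap) in enumerate(sc.members):
                tsv.write(f"{sc.super_id}\t{contig_id}\t{order}\t{orientation}\t{gap}\n")


def read_truth_tables(reads_tsv, genes_tsv) -> TruthTable:
    """Load truth tables: reads (read_id, gene_id, start, end, isoform_id)
    and gene lengths (gene_id, length).  Coordinates 0-based half-open."""
    tt = TruthTable()
    with _open_text(genes_tsv) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{genes_tsv}:{lineno}: expected 2 columns")
            tt.gene_lengths[fields[0]] = int(fields[1])
    with _open_text(reads_tsv) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"{reads_tsv}:{lineno}: expected 5 columns")
            tt.reads[fields[0]] = (fields[1], int(fields[2]), int(fields[3]), fields[4])
    tt.validate()
    return tt


def write_truth_tables(tt: TruthTable, reads_tsv, genes_tsv) -> None:
    with open(genes_tsv, "w") as fh:
        fh.write("#gene_id\tlength\n")
        for gene, length in sorted(tt.gene_lengths.items()):
            fh.write(f"{gene}\t{length}\n")
    with open(reads_tsv, "w") as fh:
        fh.write("#read_id\tgene_id\tstart\tend\tisoform_id\n")
        for rid in sorted(tt.reads):
            gene, start, end, iso = tt.reads[rid]
            fh.write(f"{rid}\t{gene}\t{start}\t{end}\t{iso}\n")
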