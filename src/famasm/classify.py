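"""Stage 1: profile-HMM homology search and family binning.

Reads are translated in six frames and searched against each family's
profile HMM; hits at E-value <= 10 (the search tool's default reporting
threshold) classify a read into a family.  Because related families can
share similarity, a read is kept in at most the three families with the
smallest E-values.  Within a family bin every member is normalized to
the model's forward strand so that downstream overlap computation can
work on plain suffix-prefix matches.

The search itself is optional: the pipeline's contract is the
:class:`~famasm.io_formats.AlignmentHit` stream, which may equally come
from a precomputed per-domain table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .io_formats import AlignmentHit, ReadRecord, frame_to_forward_bp

__all__ = [
    "ClassifyParams",
    "FamilyBin",
    "six_frame_translations",
    "search_reads",
    "assign_families",
    "bin_reads",
    "reverse_complement",
    "normalize_member",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ClassifyParams:
    """E-value cutoff and the per-read family cap."""

    evalue_max: float = 10.0
    max_families_per_read: int = 3

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.max_families_per_read < 1:
            raise ValueError("max_families_per_read must be >= 1")


@dataclass
class FamilyBin:
    """All reads classified into one family, with their best hit each.

    Members are strand-normalized: minus-strand reads are stored
    reverse-complemented with mirrored read coordinates, so every
    member is forward with respect to the model.
    """

    family_id: str
    model_length_aa: int = 0
    members: list[tuple[ReadRecord, AlignmentHit]] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for read, hit in self.members:
            if hit.family_id != self.family_id:
                raise ValueError(f"hit family {hit.family_id!r} in bin {self.family_id!r}")
            key = (read.read_id, hit.strand, hit.frame)
            if key in seen:
                raise ValueError(f"duplicate member {key} in bin {self.family_id!r}")
            seen.add(key)
            if self.model_length_aa and hit.model_end_aa > self.model_length_aa:
                raise ValueError(
                    f"hit beyond model length in bin {self.family_id!r}: {hit}"
                )


def six_frame_translations(read: ReadRecord) -> Iterator[tuple[str, str, int, str]]:
    """Yield (translated_name, strand, frame, peptide) for all six frames.

    Translated query names follow the ``<read_id>#<strand><frame>``
    convention so that coordinates can be mapped back after the search.
    """
    from Bio.Seq import Seq

    seqs = {"+": read.sequence, "-": reverse_complement(read.sequence)}
    for strand, seq in seqs.items():
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            pep = str(Seq(sub).translate())
            yield f"{read.read_id}#{strand}{frame}", strand, frame, pep


def search_reads(
    reads: Sequence[ReadRecord],
    hmm_files: Sequence[str],
    params: Optional[ClassifyParams] = None,
) -> Iterator[AlignmentHit]:
    """Search six-frame translated reads against profile HMMs via pyhmmer.

    Emits one hit per reported domain with E-value <= ``evalue_max``,
    decoded strand/frame, and read-space (forward strand, bp)
    coordinates.  Requires the optional ``pyhmmer`` dependency.
    """
    import pyhmmer

    params = params or ClassifyParams()
    alphabet = pyhmmer.easel.Alphabet.amino()
    hmms = []
    for path in hmm_files:
        with pyhmmer.plan7.HMMFile(path) as hf:
            for hmm in hf:
                if hmm.M <= 0:
                    raise ValueError(f"zero-length model in {path}")
                hmms.append(hmm)
    read_lens = {r.read_id: len(r.sequence) for r in reads}
    queries = []
    for read in reads:
        for name, _strand, _frame, pep in six_frame_translations(read):
            queries.append(
                pyhmmer.easel.TextSequence(name=name.encode(), sequence=pep).digitize(
                    alphabet
                )
            )
    def _name(x) -> str:
        return x.decode() if isinstance(x, bytes) else x

    from .io_formats import parse_translated_name

    for top_hits in pyhmmer.hmmsearch(hmms, queries, E=params.evalue_max, cpus=1):
        family_id = _name(top_hits.query.name)
        for hit in top_hits:
            if hit.evalue > params.evalue_max:
                continue
            read_id, strand, frame = parse_translated_name(_name(hit.name))
            for dom in hit.domains.reported:
                ali = dom.alignment
                rs, re_ = frame_to_forward_bp(
                    ali.target_from, ali.target_to, strand, frame, read_lens[read_id]
                )
                yield AlignmentHit(
                    read_id=read_id,
                    family_id=family_id,
                    evalue=hit.evalue,
                    model_start_aa=ali.hmm_from,
                    model_end_aa=ali.hmm_to,
                    read_start_bp=rs,
                    read_end_bp=re_,
                    strand=strand,
                    frame=frame,
                )


def assign_families(
    hits: Iterable[AlignmentHit], params: Optional[ClassifyParams] = None
) -> dict[str, list[str]]:
    """Per read, keep the families with the k smallest (best) E-values.

    Each family is scored by its best hit for the read; ties are broken
    lexicographically by family id.  Hits above the E-value cutoff are
    dropped first.
    """
    params = params or ClassifyParams()
    best: dict[str, dict[str, float]] = {}
    for h in hits:
        if h.evalue > params.evalue_max:
            continue
        fam = best.setdefault(h.read_id, {})
        if h.family_id not in fam or h.evalue < fam[h.family_id]:
            fam[h.family_id] = h.evalue
    out: dict[str, list[str]] = {}
    for read_id, fams in best.items():
        ranked = sorted(fams.items(), key=lambda kv: (kv[1], kv[0]))
        out[read_id] = [f for f, _e in ranked[: params.max_families_per_read]]
    return out


def normalize_member(read: ReadRecord, hit: AlignmentHit) -> tuple[ReadRecord, AlignmentHit]:
    """Return a forward-strand (read, hit) pair.

    Minus-strand reads are reverse-complemented and the read interval is
    mirrored; normalization is idempotent (a '+' hit is returned as-is).
    """
    if hit.strand == "+":
        return read, hit
    L = len(read.sequence)
    new_read = ReadRecord(
        read_id=read.read_id,
        sequence=reverse_complement(read.sequence),
        quality=read.quality[::-1] if read.quality else None,
        mate_id=read.mate_id,
        mate_index=read.mate_index,
    )
    new_hit = AlignmentHit(
        read_id=hit.read_id,
        family_id=hit.family_id,
        evalue=hit.evalue,
        model_start_aa=hit.model_start_aa,
        model_end_aa=hit.model_end_aa,
        read_start_bp=L - hit.read_end_bp,
        read_end_bp=L - hit.read_start_bp,
        strand="+",
        frame=hit.frame,
    )
    return new_read, new_hit


def bin_reads(
    reads: Iterable[ReadRecord],
    assignments: dict[str, list[str]],
    hits: Iterable[AlignmentHit],
    model_lengths: Optional[dict[str, int]] = None,
) -> list[FamilyBin]:
    """Partition reads into per-family bins carrying their best hit.

    A read assigned to several families appears in each of those bins.
    Minus-strand members are strand-normalized.  Hits referencing
    unknown reads are an error.
    """
    read_by_id = {r.read_id: r for r in reads}
    # best hit per (read, family): smallest (evalue, read interval) for determinism
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        if h.read_id not in read_by_id:
            raise ValueError(f"hit references unknown read {h.read_id!r}")
        key = (h.read_id, h.family_id)
        cur = best.get(key)
        if cur is None or (h.evalue, h.read_start_bp) < (cur.evalue, cur.read_start_bp):
            best[key] = h
    bins: dict[str, FamilyBin] = {}
    for read_id in sorted(assignments):
        for family_id in assignments[read_id]:
            hit = best.get((read_id, family_id))
            if hit is None:
                continue
            b = bins.setdefault(
                family_id,
                FamilyBin(
                    family_id=family_id,
                    model_length_aa=(model_lengths or {}).get(family_id, 0),
                ),
            )
            b.members.append(normalize_member(read_by_id[read_id], hit))
    out = [bins[f] for f in sorted(bins)]
    for b in out:
        b.validate()
    return out
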