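"""End-to-end wiring: classify -> graph -> simplify -> traverse -> scaffold.

Families are processed independently (the per-family design is what
keeps the memory footprint small and makes the tool embarrassingly
parallel); results are merged in family-id order so a rerun with the
same configuration and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields
from typing import Iterable, Optional, Sequence

from . import classify as _classify
from . import graph_simplify as _simplify
from . import overlap_graph as _og
from . import scaffold as _scaffold
from . import traversal as _traversal
from .io_formats import AlignmentHit, ReadRecord, write_contigs, write_supercontigs

__all__ = ["PipelineConfig", "FamilyResult", "assemble_family", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat bundle of all stage parameters.

    ``min_align_overlap`` accepts the literal string ``"auto"`` to use
    20% of the mean read length, the recommended scaling for the
    alignment-overlap gate.
    """

    evalue: float = 10.0
    max_families: int = 3
    min_align_overlap: int | str = 20
    tau: float = 0.15
    mismatches: int = 2
    min_seq_overlap: int = 10
    tip_len: Optional[int] = None
    coverage_ratio: float = 2.0
    min_critical_supports: int = 0
    insert_mean: Optional[float] = None
    insert_sd: float = 0.0
    insert_tolerance_sd: float = 3.0
    max_model_gap_aa: int = 50
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Load a flat ``key = value`` or JSON config; unknown keys are errors."""
        with open(path) as fh:
            text = fh.read()
        if text.lstrip().startswith("{"):
            raw = json.loads(text)
        else:
            raw = {}
            for lineno, line in enumerate(text.splitlines(), start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                k, v = (s.strip() for s in line.split("=", 1))
                raw[k] = v
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if isinstance(v, str) and v != "auto":
                if v.lower() in ("none", ""):
                    v = None
                elif v.lower() in ("true", "false"):
                    v = v.lower() == "true"
                else:
                    try:
                        v = int(v)
                    except ValueError:
                        v = float(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def resolve_min_align_overlap(self, mean_read_len: float) -> int:
        if self.min_align_overlap == "auto":
            return max(1, int(round(0.2 * mean_read_len)))
        return int(self.min_align_overlap)


@dataclass
class FamilyResult:
    family_id: str
    contigs: list
    supers: list
    n_nodes_raw: int = 0
    n_edges_raw: int = 0
    n_nodes_merged: int = 0
    n_edges_merged: int = 0


def _overlap_params(config: PipelineConfig, mean_read_len: float) -> _og.OverlapParams:
    return _og.OverlapParams(
        min_align_overlap_bp=config.resolve_min_align_overlap(mean_read_len),
        tau=config.tau,
        max_mismatches=config.mismatches,
        min_seq_overlap_bp=config.min_seq_overlap,
    )


def assemble_family(
    bin_: _classify.FamilyBin,
    config: Optional[PipelineConfig] = None,
    mate_pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> FamilyResult:
    """Assemble one family bin into contigs and super contigs."""
    config = config or PipelineConfig()
    if not bin_.members:
        return FamilyResult(bin_.family_id, [], [])
    mean_rl = sum(len(r.sequence) for r, _h in bin_.members) / len(bin_.members)
    graph = _og.build_graph(bin_, _overlap_params(config, mean_rl))
    n_nodes_raw, n_edges_raw = graph.number_of_nodes(), graph.number_of_edges()
    if mate_pairs is None:
        by_id = {r.read_id: r for r, _h in bin_.members}
        mate_pairs = [
            (r.read_id, r.mate_id)
            for r, _h in bin_.members
            if r.mate_id and r.mate_id in by_id and r.read_id < r.mate_id
        ]
    merged, registry = _simplify.simplify(
        graph,
        _simplify.SimplifyParams(
            tip_len_bp=config.tip_len,
            insert_size_bp=int(config.insert_mean or 0),
        ),
        mate_pairs=mate_pairs,
    )
    params = _traversal.TraversalParams(
        coverage_ratio_max=config.coverage_ratio,
        min_critical_supports=config.min_critical_supports,
        pe_insert_mean=config.insert_mean,
        pe_insert_sd=config.insert_sd,
        insert_tolerance_sd=config.insert_tolerance_sd,
    )
    contigs = _traversal.traverse(merged, registry, params)
    supers = _scaffold.scaffold_contigs(
        contigs,
        registry,
        _scaffold.ScaffoldParams(
            max_model_gap_aa=config.max_model_gap_aa,
            pe_insert_mean=config.insert_mean,
            pe_insert_sd=config.insert_sd,
            insert_tolerance_sd=config.insert_tolerance_sd,
        ),
    )
    logger.info(
        "%s: %d/%d raw nodes/edges -> %d/%d merged -> %d contigs, %d supers",
        bin_.family_id,
        n_nodes_raw,
        n_edges_raw,
        merged.number_of_nodes(),
        merged.number_of_edges(),
        len(contigs),
        len(supers),
    )
    result = FamilyResult(
        family_id=bin_.family_id,
        contigs=contigs,
        supers=supers,
        n_nodes_raw=n_nodes_raw,
        n_edges_raw=n_edges_raw,
        n_nodes_merged=merged.number_of_nodes(),
        n_edges_merged=merged.number_of_edges(),
    )
    return result


def run_pipeline(
    reads: Sequence[ReadRecord],
    hits: Sequence[AlignmentHit],
    out_dir: str,
    config: Optional[PipelineConfig] = None,
) -> list[FamilyResult]:
    """Classify reads, assemble every family, and write all outputs.

    Writes per-family contig FASTAs, super-contig FASTA+TSV, and a
    MANIFEST recording per-stage counts (or the failing stage).
    """
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"config": {k: v for k, v in asdict(config).items()}, "families": {}}
    results: list[FamilyResult] = []
    stage = "classify"
    try:
        cparams = _classify.ClassifyParams(
            evalue_max=config.evalue, max_families_per_read=config.max_families
        )
        assignments = _classify.assign_families(hits, cparams)
        bins = _classify.bin_reads(reads, assignments, hits)
        if not bins:
            logger.warning("no reads classified into any family; nothing to assemble")
        stage = "assemble"
        for bin_ in bins:
            res = assemble_family(bin_, config)
            results.append(res)
            fam_safe = bin_.family_id.replace("/", "_")
            write_contigs(res.contigs, os.path.join(out_dir, f"{fam_safe}.contigs.fa"))
            write_supercontigs(
                res.supers,
                os.path.join(out_dir, f"{fam_safe}.supercontigs.fa"),
                os.path.join(out_dir, f"{fam_safe}.supercontigs.tsv"),
            )
            manifest["families"][bin_.family_id] = {
                "nodes_raw": res.n_nodes_raw,
                "edges_raw": res.n_edges_raw,
                "nodes_merged": res.n_nodes_merged,
                "edges_merged": res.n_edges_merged,
                "contigs": len(res.contigs),
                "super_contigs": len(res.supers),
            }
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(os.path.join(out_dir, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    with open(os.path.join(out_dir, "MANIFEST.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
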