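# Methods

## Problem setting and assumptions

`famasm` performs targeted (family-specific) gene assembly. Its premises:

* the genes of interest belong to protein/domain families well enough
  conserved that a profile-HMM search classifies most of their reads
  (sensitivity grows quickly with read length; ~85 bp reads are near-fully
  classifiable for moderately conserved domains);
* sequencing depth along a gene varies smoothly (library/PCR bias), so the
  coverage of consecutive graph nodes from one gene changes gradually —
  a sharp jump indicates a wrong join;
* reads carry substitution errors (no indel handling: frameshift-aware
  alignment correction is out of scope);
* paired-end inserts have a known mean and standard deviation.

The model coordinate system is the family profile HMM, in amino acids
(1-based inclusive externally); reads are DNA (0-based half-open internally).
All overlap quantities are expressed in bp; an aa overlap converts at 3 bp
per residue.

## Stage parameters

| parameter | default | units | meaning / why |
|---|---|---|---|
| `evalue` | 10 | — | search reporting threshold; the search tool's default |
| `max_families` | 3 | families | a read joins at most the 3 best-E families (families overlap in content) |
| `min_align_overlap` | 20 (`auto` = 20 % of read length) | bp | gate on alignment overlap; blocks small random overlaps |
| `tau` (τ) | 0.15 | — | cap on relative overlap difference d = \|Oa−Os\|/max(Oa,Os); empirically same-gene pairs sit near 0.07 and cross-gene pairs near 0.9, so 0.15 separates them with margin |
| `mismatches` (m) | 2 | bases | Hamming allowance inside the sequence overlap; **tune to the data's error rate** (0 for error-free/corrected reads) |
| `min_seq_overlap` | 10 | bp | floor on any sequence overlap; guards against 1–2 bp coincidences that the consistency rule alone would admit |
| `tip_len` | 2 × mean read length | bp | tip (dead-end chain) removal threshold, the usual topology-based rule |
| `coverage_ratio` | 2.0 | — | max ratio between consecutive non-chimeric node coverages still "similar"; a ratio is scale-free, matching the smooth-coverage assumption |
| `min_critical_supports` | 0 | supports | per-path emission threshold; 0 emits every generated path (raising it restricts output to well-supported paths in complex data; paths in branch-free components always pass) |
| `insert_mean` / `insert_sd` | none | bp | paired-end library; enables pe supports and the expectation stop |
| `insert_tolerance_sd` | 3.0 | sd | window for "implied distance consistent with the insert" |
| `max_model_gap_aa` | 50 | aa | scaffolding: max model-span gap joined without paired evidence |

## Edge creation

Candidate pairs are enumerated by a single sweep over hits sorted by model
start (ties: model end, then alignment offset within the read — a larger
offset means the read extends further left of the shared codon window and
therefore precedes — then read id). Only pairs passing the alignment-overlap
gate are compared at sequence level, so construction avoids all-against-all
comparison. `Os` is defined as the **longest** suffix–prefix match within m
mismatches; taking the longest (rather than the first consistent) match is
what makes the homolog counter-example fail the consistency test.

Duplicate reads (identical sequence after strand normalization) collapse into
one node; multiplicity feeds node coverage.

## Pruning

Order: inferior edges → transitive edges → tips → chain merging. The inferior
pass runs first so junk edges cannot mask legitimate transitive reductions.
Transitive detection is bounded to alternative paths of 2–3 hops — sufficient
for read-tiling geometry, where an alternative path between overlap-connected
reads is a short detour; removing only edges with alternatives provably
preserves reachability. Every removed transitive pair is recorded: it is
same-gene evidence ("a paired-end link with a tiny insert") used later by the
traversal. Chain splices resolve overlap mismatches by multiplicity-weighted
majority, ties keeping the earlier read's base.

## Traversal

Bounded DFS from each source node (then from any node still unreached, to
cover cycles and truncation fragments); successors are explored in ascending
node id, so output is deterministic. Decision order at each step:

1. at a branch, follow **all** successors with critical supports (a support
   is critical only where it disambiguates a branch);
2. otherwise follow the one non-chimeric successor (chimeric signature:
   in-degree ≥ 2 and out-degree ≥ 2) with the closest coverage ratio ≤ the
   bound (tie → higher coverage);
3. otherwise emit the path and enqueue each successor as a new start (each
   node may seed at most one new path, bounding output size linearly).

Paired-end supports count only when the implied along-path distance of the
mate pair matches the insert (± `insert_tolerance_sd` × sd). In paired mode an
additional **expectation stop** applies: if some visited node v (not
overlapping the candidate c) could geometrically host a mate pair reaching c
at the mean insert (with one insert-sd of slack) and neither a pe link nor a
transitive pair connects v and c, the path is emitted without c. This is what
truncates chimeric chains between isoforms that share an internal region but
have exclusive flanks on opposite sides (AS case B), where no branch exists
for supports to disambiguate.

Paired-end links between *adjacent* nodes are kept in the support registry:
at an isoform fork immediately after a shared node they are the only evidence
distinguishing the two splice branches. Transitive pairs, by contrast, are
dropped whenever a surviving direct edge joins the pair (the edge itself is
the evidence there).

## Scaffolding

Within a family, contigs are grouped by union-find over (a) insert-consistent
paired-end links and (b) disjoint model spans separated by ≤ `max_model_gap_aa`
residues; members are ordered by model-span start (never reversed), and the
gap estimate is 3 bp per missing residue (untranslated/intergenic content is
not modeled). Contigs with overlapping model spans and no paired link stay
separate: that signature usually means paralogs aligned to the same model
region, and joining them would manufacture chimeras. Emitted super-contig
sequences join members with N-runs of the gap estimate (minimum one N).

## Evaluation metrics

A *gene segment* is the part of a contig lying within one target gene; only
segments are scored. Gene coverage is the union (not sum) of segment
intervals over the gene length; contig coverage normalizes a segment by its
gene's length so long genes do not dominate; a segment is chimeric iff a read
from a different source gene overlaps its contig interval; a contig is
complete iff it covers strictly more than 90 % of one isoform. Metrics are
computed per family and averaged unweighted across families. In synthetic
mode segments derive from read-origin truth; for real data, precomputed
contig-to-gene alignments in tabular (blast6-like) layout can be ingested,
where chimera flags are not derivable and default to clean.

## Synthetic data generator

`synthetic.simulate_family` emulates: one ancestral coding gene (~1 kb);
paralogs at a target pairwise identity produced by **quasi-periodic**
substitution (inter-substitution gaps uniform in mean ± 2 bp) — mimicking
coding-sequence divergence, where synonymous-site changes recur every few
codons, and bounding the longest exact run shared by homologs (< 10 bp at
85 % identity); four alternative-splicing case groups (exon skipping; shared
internal region with exclusive opposite flanks; intron retention; mutually
exclusive exons); smooth sinusoidal depth modulation (amplitude 0.3 around a
20× mean); 100 bp reads, paired with a 300 ± 30 bp insert, mate 2
reverse-complemented; iid substitution errors (default 0.2 %); and alignment
hits synthesized from the true codon coordinates with optional ±aa jitter.

What it does **not** emulate — and hence what passing tests do not show about
real data: indels and frameshifts, quality-correlated error profiles,
homology-search false negatives in poorly conserved regions (every read gets
a hit), chimeric PCR artifacts, and model-to-gene misalignment beyond small
coordinate jitter. Graph-level fixtures (`shared_block_graph`,
`as_case_graph`) construct post-merge topologies directly with exactly placed
paired-end supports; they test traversal logic, not end-to-end robustness.

## Numerical and degenerate-input choices

* d ≤ τ is inclusive; d is exactly |Oa−Os|/max(Oa,Os) in [0, 1).
* Coverage-ratio comparisons use max/min ≥ 1 with a 1e-12 floor.
* Empty bins yield empty graphs; an empty contig list writes an empty FASTA;
  an empty segment list has chimera rate 0 by convention (with a warning).
* Cycles (possible only with inconsistent hit coordinates) are broken at the
  back-edge with a warning; a global path budget (4·|V|+16) guards against
  pathological branching.
* Contigs lacking a model span scaffold as singletons with a warning.

## Validation choices and problem sizes

The test suite pins worked examples (22 aa → 66 bp; 70 %/40 %/30 % and
zero-chimera values of the schematic segment example; the Oa=66/Os=25
homolog pair creating no edge), checks construction against brute-force
all-against-all oracles (100 random bins up to 200 reads), transitive
reduction against full reachability (100 random DAGs ≤ 50 nodes), and the
suffix–prefix primitive against an all-lengths scan (1000 pairs). The
simulation sweeps use 100 seeds each at the default study conditions
(999 bp genes, 20×, paired 300 ± 30): single-gene recovery must reach a
≥ 95 %-coverage contig in ≥ 95 seeds; the two-homolog stress (85 % identity,
error-free, m = 0 to match the error-free data) must yield zero chimeric
segments in every seed.

## Known limitations

* No indel/frameshift handling: a single indel inside an overlap breaks the
  Hamming comparison; such reads fragment contigs.
* Poorly conserved regions lose hits and therefore reads; coverage of such
  genes comes from scaffolding, not assembly.
* The consistency gate inherits the model's coordinate quality: large
  alignment-coordinate jitter (> ~2 aa on short overlaps) suppresses true
  edges before it admits false ones.
* The chimeric-node flag (in ≥ 2 and out ≥ 2) is a topological heuristic; a
  shared block at the very start or end of genes evades it (supports still
  guard those joins).
* Scaffold gap estimates assume the missing sequence is exactly the skipped
  model span; introns/UTRs make real gaps longer.
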