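"""Edge-creation criteria and graph construction vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famasm.classify import FamilyBin
from famasm.io_formats import AlignmentHit, ReadRecord
from famasm.overlap_graph import (
    OverlapParams,
    aa_overlap_to_bp,
    alignment_order_key,
    build_graph,
    collapse_duplicates,
    relative_overlap_difference,
    suffix_prefix_overlap,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_suffix_prefix(r1, r2, m, min_len):
    """All-lengths scan with numpy hamming; independent of the sweep code."""
    a = np.frombuffer(r1.encode(), dtype="S1")
    b = np.frombuffer(r2.encode(), dtype="S1")
    best = None
    for L in range(min_len, min(len(a), len(b)) + 1):
        d = int(np.count_nonzero(a[len(a) - L :] != b[:L]))
        if d <= m:
            best = (L, d)
    return best


def brute_edges(nodes, params):
    """All-against-all application of edge criteria i-iii."""
    order = {n.node_id: alignment_order_key(n) for n in nodes}
    edges = {}
    for n1 in nodes:
        for n2 in nodes:
            if n1.node_id == n2.node_id or order[n1.node_id] >= order[n2.node_id]:
                continue  # criterion i
            inter = min(n1.hit.model_end_aa, n2.hit.model_end_aa) - max(
                n1.hit.model_start_aa, n2.hit.model_start_aa) + 1
            oa = 3 * inter
            if oa < params.min_align_overlap_bp:
                continue  # criterion ii
            got = brute_suffix_prefix(
                n1.sequence, n2.sequence, params.max_mismatches,
                params.min_seq_overlap_bp)
            if got is None:
                continue
            os_, ham = got
            if abs(oa - os_) / max(oa, os_) > params.tau:
                continue  # criterion iii
            edges[(n1.node_id, n2.node_id)] = (os_, oa, ham)
    return edges


def tiled_bin(rng, n_reads=40, gene_len=600, read_len=76, family="f"):
    gene = "".join(rng.choice(list("ACGT"), size=gene_len))
    members = []
    starts = sorted(int(s) for s in rng.integers(0, gene_len - read_len, n_reads))
    for i, s in enumerate(starts):
        seq = gene[s : s + read_len]
        c0, c1 = -(-s // 3), (s + read_len) // 3
        members.append((
            ReadRecord(f"r{i:03d}", seq),
            AlignmentHit(f"r{i:03d}", family, 1e-9, c0 + 1, c1,
                         3 * c0 - s, 3 * c1 - s, "+", 0),
        ))
    return FamilyBin(family_id=family, members=members)


# ---------------------------------------------------------------------------
# unit behaviour
# ---------------------------------------------------------------------------


class TestUnitConversion:
    @pytest.mark.parametrize("aa,bp", [(22, 66), (0, 0), (7, 21)])
    def test_three_bases_per_residue(self, aa, bp):
        assert aa_overlap_to_bp(aa) == bp

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            aa_overlap_to_bp(-1)


class TestSuffixPrefixOverlap:
    def test_short_exact_overlap(self):
        assert suffix_prefix_overlap("ACGTACGT", "ACGTTTTT", 0, 2) == (4, 0)

    def test_identical_reads_full_length(self):
        s = "ACGT" * 19
        assert suffix_prefix_overlap(s, s, 0, 2) == (76, 0)

    def test_no_match_returns_none(self):
        assert suffix_prefix_overlap("AAAA", "CCCC", 0, 1) is None

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            suffix_prefix_overlap("", "ACGT", 0, 1)

    def test_mismatch_allowance_counts_hamming(self):
        # suffix ACGTA vs prefix ACCTA: one mismatch
        got = suffix_prefix_overlap("GGACGTA", "ACCTAGG", 1, 5)
        assert got == (5, 1)

    @given(st.integers(0, 10_000), st.integers(0, 2), st.integers(1, 6))
    @settings(max_examples=200)
    def test_matches_brute_force(self, seed, m, min_len):
        r = np.random.default_rng(seed)
        # correlated pairs so overlaps actually occur
        base = "".join(r.choice(list("ACGT"), size=60))
        lag = int(r.integers(0, 50))
        r1 = base[:40]
        r2 = base[40 - lag :][:40] if lag else base[:40]
        if len(r2) < min_len:
            r2 = base[:40]
        assert suffix_prefix_overlap(r1, r2, m, min_len) == brute_suffix_prefix(
            r1, r2, m, min_len)


class TestRelativeOverlapDifference:
    def test_equal_overlaps_zero(self):
        assert relative_overlap_difference(66, 66) == 0.0

    def test_homolog_counterexample_magnitude(self):
        assert relative_overlap_difference(66, 25) == pytest.approx(41 / 66)

    def test_small_consistent_pair_under_cutoff(self):
        assert relative_overlap_difference(20, 23) == pytest.approx(3 / 23)
        assert relative_overlap_difference(20, 23) <= 0.15

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relative_overlap_difference(0, 10)


def _two_read_bin(r1, r2, h1, h2):
    return FamilyBin(family_id="f", members=[
        (ReadRecord("a", r1), h1), (ReadRecord("b", r2), h2)])


class TestBuildGraph:
    def test_same_gene_tiled_pair_connected(self, make_dna):
        gene = make_dna(240, seed=5)
        r1, r2 = gene[0:76], gene[30:106]
        h1 = AlignmentHit("a", "f", 1e-9, 1, 25, 0, 75, "+", 0)
        h2 = AlignmentHit("b", "f", 1e-9, 11, 35, 0, 75, "+", 0)
        g = build_graph(_two_read_bin(r1, r2, h1, h2))
        assert list(g.edges()) == [("a", "b")]
        e = g.edges["a", "b"]
        assert e["os"] == 46 and abs(e["oa"] - 46) <= 6 and e["d"] <= 0.15

    def test_homolog_pair_with_inconsistent_overlaps_not_connected(self, make_dna):
        # alignment overlap 22 aa = 66 bp, sequence overlap only 25 bp
        left = make_dna(51, seed=11)
        shared = make_dna(25, seed=12)
        right = make_dna(51, seed=13)
        r1, r2 = left + shared, shared + right
        assert suffix_prefix_overlap(r1, r2, 2, 10) == (25, 0)
        h1 = AlignmentHit("a", "f", 1e-9, 1, 25, 0, 75, "+", 0)
        h2 = AlignmentHit("b", "f", 1e-9, 4, 28, 0, 75, "+", 0)  # 22 aa overlap
        g = build_graph(_two_read_bin(r1, r2, h1, h2))
        assert g.number_of_edges() == 0

    def test_alignment_overlap_below_gate_blocks_edge(self, make_dna):
        gene = make_dna(300, seed=6)
        r1, r2 = gene[0:76], gene[58:134]  # 18 bp sequence overlap
        h1 = AlignmentHit("a", "f", 1e-9, 1, 25, 0, 75, "+", 0)
        h2 = AlignmentHit("b", "f", 1e-9, 20, 44, 0, 75, "+", 0)  # Oa = 18
        g = build_graph(_two_read_bin(r1, r2, h1, h2))
        assert g.number_of_edges() == 0

    def test_small_consistent_overlap_allowed(self, make_dna):
        gene = make_dna(300, seed=7)
        r1, r2 = gene[0:75], gene[54:129]  # 21 bp overlap, codon aligned
        h1 = AlignmentHit("a", "f", 1e-9, 1, 25, 0, 75, "+", 0)
        h2 = AlignmentHit("b", "f", 1e-9, 19, 43, 0, 75, "+", 0)  # Oa = 21
        g = build_graph(_two_read_bin(r1, r2, h1, h2))
        e = g.edges["a", "b"]
        assert (e["oa"], e["os"]) == (21, 21)

    def test_duplicates_collapse_with_multiplicity(self, make_dna):
        seq = make_dna(76, seed=8)
        h = AlignmentHit("a", "f", 1e-9, 1, 25, 0, 75, "+", 0)
        bin_ = FamilyBin(family_id="f", members=[
            (ReadRecord("a", seq), h),
            (ReadRecord("b", seq),
             AlignmentHit("b", "f", 1e-9, 1, 25, 0, 75, "+", 0)),
        ])
        g = build_graph(bin_)
        assert g.number_of_nodes() == 1
        assert g.nodes["a"]["data"].multiplicity == 2

    def test_empty_bin_gives_empty_graph(self):
        g = build_graph(FamilyBin(family_id="f"))
        assert g.number_of_nodes() == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_sweep_equals_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bin_ = tiled_bin(rng, n_reads=int(rng.integers(15, 45)))
        params = OverlapParams()
        g = build_graph(bin_, params)
        nodes = collapse_duplicates(bin_)
        oracle = brute_edges(nodes, params)
        got = {(u, v): (d["os"], d["oa"], d["hamming"])
               for u, v, d in g.edges(data=True)}
        assert got == oracle

    def test_every_edge_satisfies_criteria(self):
        rng = np.random.default_rng(99)
        bin_ = tiled_bin(rng, n_reads=50)
        params = OverlapParams()
        g = build_graph(bin_, params)
        key = {n: alignment_order_key(g.nodes[n]["data"]) for n in g}
        for u, v, d in g.edges(data=True):
            assert key[u] < key[v]
            assert d["oa"] >= params.min_align_overlap_bp
            assert d["os"] >= params.min_seq_overlap_bp
            assert d["hamming"] <= params.max_mismatches
            assert d["d"] == abs(d["oa"] - d["os"]) / max(d["oa"], d["os"])
            assert d["d"] <= params.tau

    def test_single_gene_graph_is_dag(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        g = build_graph(tiled_bin(rng, n_reads=60))
        assert nx.is_directed_acyclic_graph(g)

    def test_two_homologs_without_shared_runs_never_cross_connect(self):
        """85% identity homologs; no cross-gene edge at the matched
        mismatch allowance (error-free reads -> m=0)."""
        from famasm.classify import assign_families, bin_reads
        from famasm.synthetic import SimConfig, simulate_family

        failures = 0
        for seed in range(10):
            sim = simulate_family(SimConfig(
                seed=seed, n_genes=2, identity=0.85, error_rate=0.0))
            bins = bin_reads(sim.reads, assign_families(sim.hits), sim.hits)
            g = build_graph(bins[0], OverlapParams(max_mismatches=0))
            cross = [
                (u, v) for u, v in g.edges()
                if sim.truth.reads[g.nodes[u]["data"].member_reads[0]][0]
                != sim.truth.reads[g.nodes[v]["data"].member_reads[0]][0]
            ]
            failures += bool(cross)
        assert failures == 0
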