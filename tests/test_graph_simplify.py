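"""Pruning passes: transitive reduction, inferior edges, tips, merging."""

import networkx as nx
import numpy as np
import pytest

from famasm.graph_simplify import (
    MergedNode,
    SimplifyParams,
    SupportRegistry,
    merge_chains,
    remove_inferior_edges,
    remove_tips,
    remove_transitive_edges,
    simplify,
)
from famasm.io_formats import AlignmentHit, ReadRecord
from famasm.overlap_graph import GraphNode


def _node(nid, seq="ACGTACGTACGT", ms=1, me=4, n_dup=1):
    hit = AlignmentHit(nid, "f", 1e-9, ms, me, 0, len(seq), "+", 0)
    return GraphNode(node_id=nid, sequence=seq, hit=hit,
                     member_reads=[nid] + [f"{nid}.d{i}" for i in range(n_dup - 1)])


def _graph(edges, nodes=None, os_=4, **node_kwargs):
    g = nx.DiGraph(family_id="f")
    ids = nodes or sorted({x for e in edges for x in e[:2]})
    for n in ids:
        g.add_node(n, data=_node(n, **node_kwargs))
    for e in edges:
        u, v = e[:2]
        attrs = e[2] if len(e) > 2 else {}
        g.add_edge(u, v, os=attrs.get("os", os_), oa=attrs.get("oa", os_),
                   hamming=attrs.get("hamming", 0), d=attrs.get("d", 0.0))
    return g


class TestTransitiveEdges:
    def test_triangle_shortcut_removed_and_recorded(self):
        g = _graph([("a", "b"), ("b", "c"), ("a", "c")])
        g, reg = remove_transitive_edges(g)
        assert set(g.edges()) == {("a", "b"), ("b", "c")}
        assert reg.transitive_pairs == {frozenset(("a", "c"))}

    def test_plain_chain_untouched(self):
        g = _graph([("a", "b"), ("b", "c")])
        g, reg = remove_transitive_edges(g)
        assert g.number_of_edges() == 2 and not reg.transitive_pairs

    def test_diamond_keeps_both_branches(self):
        g = _graph([("a", "b"), ("b", "d"), ("a", "c"), ("c", "d"), ("a", "d")])
        g, reg = remove_transitive_edges(g)
        assert set(g.edges()) == {("a", "b"), ("b", "d"), ("a", "c"), ("c", "d")}
        assert reg.transitive_pairs == {frozenset(("a", "d"))}

    @pytest.mark.parametrize("seed", range(20))
    def test_reachability_preserved_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        g = nx.DiGraph()
        for i in range(n):
            g.add_node(f"n{i:02d}", data=_node(f"n{i:02d}"))
        for i in range(n):
            for j in range(i + 1, min(n, i + 6)):
                if rng.random() < 0.4:
                    g.add_edge(f"n{i:02d}", f"n{j:02d}", os=4, oa=4, hamming=0, d=0.0)
        before = {u: nx.descendants(g, u) for u in g}
        g2, _reg = remove_transitive_edges(g.copy())
        after = {u: nx.descendants(g2, u) for u in g2}
        assert before == after

    def test_matches_networkx_reduction_on_tiling_dags(self):
        """On read-tiling geometry (edges span <= 3 hops) the bounded pass
        equals full transitive reduction."""
        rng = np.random.default_rng(77)
        g = nx.DiGraph()
        n = 30
        for i in range(n):
            g.add_node(i, data=_node(f"n{i}"))
        for i in range(n - 1):
            g.add_edge(i, i + 1, os=4, oa=4, hamming=0, d=0.0)
            for span in (2, 3):
                if i + span < n and rng.random() < 0.7:
                    g.add_edge(i, i + span, os=4, oa=4, hamming=0, d=0.0)
        expected = set(nx.transitive_reduction(g).edges())
        g2, _ = remove_transitive_edges(g.copy())
        assert set(g2.edges()) == expected


class TestInferiorEdges:
    def test_short_noisy_sibling_removed(self):
        g = _graph([
            ("t", "x", {"os": 15, "hamming": 2}),
            ("t", "y", {"os": 40, "hamming": 0}),
        ])
        remove_inferior_edges(g)
        assert set(g.edges()) == {("t", "y")}

    def test_both_criteria_required(self):
        g = _graph([
            ("t", "x", {"os": 15, "hamming": 0}),
            ("t", "y", {"os": 40, "hamming": 0}),
        ])
        remove_inferior_edges(g)
        assert g.number_of_edges() == 2

    def test_disjoint_edges_kept(self):
        g = _graph([
            ("a", "b", {"os": 15, "hamming": 2}),
            ("c", "d", {"os": 40, "hamming": 0}),
        ])
        remove_inferior_edges(g)
        assert g.number_of_edges() == 2

    def test_shared_head_also_compared(self):
        g = _graph([
            ("a", "x", {"os": 12, "hamming": 1}),
            ("b", "x", {"os": 50, "hamming": 0}),
        ])
        remove_inferior_edges(g)
        assert set(g.edges()) == {("b", "x")}


class TestTips:
    def _spur_graph(self, spur_len_bp=40):
        # main chain a-b-c-d-e with a spur off c
        g = _graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
                   seq="A" * 100, ms=1, me=30)
        g.add_node("spur", data=_node("spur", seq="A" * spur_len_bp))
        g.add_edge("c", "spur", os=10, oa=10, hamming=0, d=0.0)
        return g

    def test_short_spur_removed_main_chain_intact(self):
        g = self._spur_graph(40)
        remove_tips(g, tip_len_bp=152)
        assert "spur" not in g
        assert set(g.nodes()) == {"a", "b", "c", "d", "e"}

    def test_long_spur_kept(self):
        g = self._spur_graph(200)
        remove_tips(g, tip_len_bp=152)
        assert "spur" in g

    def test_isolated_linear_chain_never_removed(self):
        g = _graph([("a", "b"), ("b", "c")], seq="A" * 30)
        remove_tips(g, tip_len_bp=1000)
        assert set(g.nodes()) == {"a", "b", "c"}

    def test_head_side_spur_removed(self):
        g = _graph([("a", "b"), ("b", "c"), ("c", "d")], seq="A" * 100)
        g.add_node("spur", data=_node("spur", seq="A" * 30))
        g.add_edge("spur", "b", os=10, oa=10, hamming=0, d=0.0)
        remove_tips(g, tip_len_bp=100)
        assert "spur" not in g and "a" in g


class TestMergeChains:
    def _tiled_chain_graph(self, make_dna):
        gene = make_dna(136, seed=21)
        seqs = [gene[0:76], gene[30:106], gene[60:136]]
        g = nx.DiGraph(family_id="f")
        for i, s in enumerate(seqs):
            g.add_node(f"r{i}", data=_node(f"r{i}", seq=s, ms=1 + 10 * i,
                                           me=25 + 10 * i))
        g.add_edge("r0", "r1", os=46, oa=45, hamming=0, d=0.0)
        g.add_edge("r1", "r2", os=46, oa=45, hamming=0, d=0.0)
        return g, gene

    def test_chain_of_three_merges_to_136bp(self, make_dna):
        g, gene = self._tiled_chain_graph(make_dna)
        merged, _reg = merge_chains(g)
        assert merged.number_of_nodes() == 1
        node = merged.nodes["r0"]["data"]
        assert len(node.sequence) == 136
        assert node.sequence == gene
        assert node.member_reads == ["r0", "r1", "r2"]
        assert node.read_offsets == {"r0": 0, "r1": 30, "r2": 60}
        assert node.coverage == pytest.approx(3 * 76 / 136)

    def test_branch_node_never_merged_into_successor(self):
        g = _graph([("a", "b"), ("a", "c")], seq="A" * 20)
        merged, _ = merge_chains(g)
        assert merged.number_of_nodes() == 3

    def test_duplicate_multiplicity_gives_coverage_two(self):
        g = nx.DiGraph(family_id="f")
        g.add_node("a", data=_node("a", seq="A" * 100, n_dup=2))
        merged, _ = merge_chains(g)
        assert merged.nodes["a"]["data"].coverage == pytest.approx(2.0)

    def test_splice_mismatch_resolved_by_weight(self):
        g = nx.DiGraph(family_id="f")
        g.add_node("a", data=_node("a", seq="AAAATTTT", n_dup=1))
        g.add_node("b", data=_node("b", seq="TTTCGGGG", n_dup=3, ms=2, me=5))
        g.add_edge("a", "b", os=4, oa=4, hamming=1, d=0.0)
        merged, _ = merge_chains(g)
        seq = merged.nodes["a"]["data"].sequence
        # overlap TTTT vs TTTC: heavier (x3) later node wins the mismatch
        assert seq == "AAAATTTCGGGG"

    def test_inconsistent_splice_errors(self):
        g = nx.DiGraph(family_id="f")
        g.add_node("a", data=_node("a", seq="ACGT"))
        g.add_node("b", data=_node("b", seq="ACG"))
        g.add_edge("a", "b", os=5, oa=5, hamming=0, d=0.0)
        with pytest.raises(ValueError, match="inconsistent splice"):
            merge_chains(g)

    def test_registry_rekeyed_and_pe_populated(self, make_dna):
        g, _gene = self._tiled_chain_graph(make_dna)
        g.add_node("other", data=_node("other", seq=make_dna(76, seed=22),
                                       ms=60, me=80))
        reg = SupportRegistry()
        reg.add_transitive("r0", "r2")  # collapses inside the chain -> dropped
        reg.add_transitive("r1", "other")
        merged, reg2 = merge_chains(g, reg, mate_pairs=[("r2", "other")])
        assert reg2.transitive_pairs == {frozenset(("r0", "other"))}
        (pe,) = reg2.pe_pairs
        assert {pe.node_a, pe.node_b} == {"r0", "other"}
        assert pe.pos_a == 60  # r2 sits at offset 60 in the merged chain

    def test_merge_preserves_total_sequence_content(self, make_dna):
        g, _ = self._tiled_chain_graph(make_dna)
        total_before = sum(len(d.sequence) for _n, d in g.nodes(data="data")) - sum(
            d["os"] for _u, _v, d in g.edges(data=True))
        merged, _ = merge_chains(g)
        total_after = sum(len(d.sequence) for _n, d in merged.nodes(data="data"))
        assert total_before == total_after


class TestSimplifyPass:
    def test_idempotent(self, make_dna):
        from famasm.overlap_graph import build_graph
        from tests.test_overlap_graph import tiled_bin

        rng = np.random.default_rng(31)
        g = build_graph(tiled_bin(rng, n_reads=50))
        once, reg1 = simplify(g, SimplifyParams(tip_len_bp=152))
        twice, reg2 = simplify(once, SimplifyParams(tip_len_bp=152))
        assert set(once.nodes()) == set(twice.nodes())
        assert set(once.edges()) == set(twice.edges())
        assert {d.sequence for _n, d in once.nodes(data="data")} == {
            d.sequence for _n, d in twice.nodes(data="data")}
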