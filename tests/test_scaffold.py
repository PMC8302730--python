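"""Dovetail filtering, bi-directed graph construction, simplification,
and scaffold traversal."""

import itertools
import random

import pytest

from strainsep import scaffold as sg
from strainsep.assembly import StrainAwareContig
from strainsep.io import AlignmentRecord, revcomp
from strainsep.scaffold import PREFIX, SUFFIX
from strainsep.simulate import random_genome


def rec(query="r1", qlen=1000, qstart=0, qend=500, strand="+",
        target="c1", tlen=5000, tstart=4500, tend=5000, matches=480,
        block_len=505, mapq=60, primary=True, base_level=True):
    return AlignmentRecord(query, qlen, qstart, qend, strand, target, tlen,
                           tstart, tend, matches, block_len, mapq, primary,
                           base_level)


class TestFilterDovetails:
    def test_clean_suffix_prefix_dovetail_accepted(self):
        [d] = sg.filter_dovetails([rec()])
        assert (d.contig_end, d.read_end) == (SUFFIX, PREFIX)

    def test_mapq_boundary_strictly_greater(self):
        assert sg.filter_dovetails([rec(mapq=40)]) == []
        assert len(sg.filter_dovetails([rec(mapq=41)])) == 1

    def test_overhang_boundary_min_of_50_and_10pct(self):
        # match_len 300 -> threshold min(50, 30) = 30
        ok = rec(qstart=30, qend=330, matches=300, block_len=300,
                 tstart=4700, tend=5000)
        bad = rec(qstart=31, qend=331, matches=300, block_len=300,
                  tstart=4700, tend=5000)
        assert len(sg.filter_dovetails([ok])) == 1
        assert sg.filter_dovetails([bad]) == []

    def test_long_match_caps_overhang_at_50(self):
        # match_len 2000 -> threshold min(50, 200) = 50
        ok = rec(qlen=3000, qstart=50, qend=2050, matches=2000,
                 block_len=2000, tlen=9000, tstart=7000, tend=9000)
        bad = rec(qlen=3000, qstart=51, qend=2051, matches=2000,
                  block_len=2000, tlen=9000, tstart=7000, tend=9000)
        assert len(sg.filter_dovetails([ok])) == 1
        assert sg.filter_dovetails([bad]) == []

    def test_secondary_rejected(self):
        assert sg.filter_dovetails([rec(primary=False)]) == []

    def test_internal_alignment_not_dovetail(self):
        assert sg.filter_dovetails(
            [rec(qstart=300, qend=800, tstart=2000, tend=2500)]) == []

    def test_reverse_strand_pairing(self):
        # '-' strand: contig suffix faces the read's suffix
        [d] = sg.filter_dovetails(
            [rec(strand="-", qstart=500, qend=1000)])
        assert (d.contig_end, d.read_end) == (SUFFIX, SUFFIX)

    def test_missing_base_level_detail_is_error(self):
        with pytest.raises(ValueError):
            sg.filter_dovetails([rec(base_level=False)])


def contig(cid, origin="bb", interval=(0, 1000), kind="haplotype",
           hap="h1", seq_len=1000):
    return StrainAwareContig(cid, "A" * seq_len, origin, interval, kind,
                             hap if kind == "haplotype" else None)


def dt(read, cid, contig_end, read_end, qstart, qend, match_len=500):
    return sg.DovetailAlignment(read, cid, contig_end, read_end, "+",
                                match_len, 60, 0, qstart, qend)


class TestBuildGraph:
    def _contigs(self):
        # backbone of 10 kbp: hap pair on [1000,4000), unphased [4000,7000),
        # hap pair on [7000,9000)
        return [
            contig("A1", interval=(1000, 4000), hap="h1"),
            contig("A2", interval=(1000, 4000), hap="h2"),
            contig("U", interval=(4000, 7000), kind="unphased"),
            contig("B1", interval=(7000, 9000), hap="h1"),
            contig("B2", interval=(7000, 9000), hap="h2"),
        ]

    def test_bridging_reads_make_weighted_edge(self):
        dovetails = []
        for i in range(12):
            dovetails += [dt(f"r{i}", "A1", SUFFIX, PREFIX, 0, 500),
                          dt(f"r{i}", "U", PREFIX, SUFFIX, 600, 1000)]
        g = sg.build_graph(dovetails, self._contigs(), {"bb": 10_000})
        assert len(g.edges) == 1
        [e] = g.edges.values()
        assert e.weight == 12
        assert e.gaps == [100] * 12

    def test_same_read_end_twice_no_edge(self):
        dovetails = [dt("r", "A1", SUFFIX, PREFIX, 0, 500),
                     dt("r", "U", PREFIX, PREFIX, 0, 400)]
        g = sg.build_graph(dovetails, self._contigs(), {"bb": 10_000})
        assert g.edges == {}

    def test_adjacent_haplotype_contigs_linked_across_unphased_gap(self):
        # A and B are adjacent haplotype intervals (U in between is not a
        # phaseset), so rule (ii) admits the link
        dovetails = [dt("r", "A1", SUFFIX, PREFIX, 0, 500),
                     dt("r", "B1", PREFIX, SUFFIX, 700, 1200)]
        g = sg.build_graph(dovetails, self._contigs(), {"bb": 10_000})
        assert len(g.edges) == 1

    def test_cross_backbone_interior_contigs_not_linked(self):
        contigs = [contig("X", origin="bb1", interval=(5000, 8000)),
                   contig("Y", origin="bb2", interval=(5000, 8000))]
        dovetails = [dt("r", "X", SUFFIX, PREFIX, 0, 500),
                     dt("r", "Y", PREFIX, SUFFIX, 700, 1200)]
        g = sg.build_graph(dovetails, contigs,
                           {"bb1": 20_000, "bb2": 20_000})
        assert g.edges == {}

    def test_backbone_extremity_contigs_linked(self):
        contigs = [contig("X", origin="bb1", interval=(19_500, 20_000)),
                   contig("Y", origin="bb2", interval=(0, 600))]
        dovetails = [dt("r", "X", SUFFIX, PREFIX, 0, 500),
                     dt("r", "Y", PREFIX, SUFFIX, 700, 1200)]
        g = sg.build_graph(dovetails, contigs,
                           {"bb1": 20_000, "bb2": 20_000})
        assert len(g.edges) == 1

    def test_negative_gap_sample_for_overlapping_alignments(self):
        dovetails = [dt("r", "A1", SUFFIX, PREFIX, 0, 520),
                     dt("r", "U", PREFIX, SUFFIX, 500, 1000)]
        g = sg.build_graph(dovetails, self._contigs(), {"bb": 10_000})
        [e] = g.edges.values()
        assert e.gaps == [-20]

    def test_self_link_ignored(self):
        dovetails = [dt("r", "A1", SUFFIX, PREFIX, 0, 500),
                     dt("r", "A1", PREFIX, SUFFIX, 600, 1000)]
        g = sg.build_graph(dovetails, self._contigs(), {"bb": 10_000})
        assert g.edges == {}


def make_graph(n_vertices, edge_list):
    """edge_list: (u, us, v, vs, weight)."""
    g = sg.ScaffoldingGraph([f"v{i}" for i in range(n_vertices)])
    for u, us, v, vs, w in edge_list:
        e = sg.Edge(u, us, v, vs, w, [100] * w)
        g.edges[e.key] = e
    return g


def oracle_transitive_keys(edge_list):
    """Independent brute-force application of the transitive-edge rule."""
    edges = [sg.Edge(u, us, v, vs, w) for u, us, v, vs, w in edge_list]
    incident = []
    for e in edges:
        incident.append(((e.u, e.u_side), (e.v, e.v_side)))
    doomed = set()
    for i, e in enumerate(edges):
        for (a, b) in itertools.permutations([(e.u, e.u_side),
                                              (e.v, e.v_side)]):
            for j, e1 in enumerate(edges):
                if j == i:
                    continue
                ends1 = incident[j]
                if a not in ends1:
                    continue
                z, z_side = ends1[1 - ends1.index(a)]
                if z in (e.u, e.v):
                    continue
                z_exit = (z, PREFIX if z_side == SUFFIX else SUFFIX)
                for k, e2 in enumerate(edges):
                    if k in (i, j):
                        continue
                    ends2 = incident[k]
                    if z_exit in ends2 and b in ends2 \
                            and ends2.index(z_exit) != ends2.index(b):
                        doomed.add(e.key)
    return {e.key for e in edges} - doomed


class TestTransitiveReduction:
    def test_consistent_triangle_shortcut_removed(self):
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 5),
                           ("v1", SUFFIX, "v2", PREFIX, 5),
                           ("v0", SUFFIX, "v2", PREFIX, 5)])
        sg.remove_transitive_edges(g)
        keys = set(g.edges)
        assert sg.Edge("v0", SUFFIX, "v2", PREFIX).key not in keys
        assert len(keys) == 2

    def test_mismatched_arrow_keeps_edge(self):
        # direct edge leaves v0 via its prefix while the path leaves via
        # suffix: not a shortcut of the same traversal
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 5),
                           ("v1", SUFFIX, "v2", PREFIX, 5),
                           ("v0", PREFIX, "v2", PREFIX, 5)])
        sg.remove_transitive_edges(g)
        assert len(g.edges) == 3

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rnd = random.Random(seed)
        n = rnd.randint(3, 8)
        edge_list = []
        seen = set()
        for _ in range(rnd.randint(2, 12)):
            u, v = rnd.sample(range(n), 2)
            us = rnd.choice([PREFIX, SUFFIX])
            vs = rnd.choice([PREFIX, SUFFIX])
            e = sg.Edge(f"v{u}", us, f"v{v}", vs, 1)
            if e.key in seen:
                continue
            seen.add(e.key)
            edge_list.append((f"v{u}", us, f"v{v}", vs, rnd.randint(1, 30)))
        g = make_graph(n, edge_list)
        sg.remove_transitive_edges(g)
        assert set(g.edges) == oracle_transitive_keys(edge_list)

    def test_result_invariant_to_edge_order(self):
        edge_list = [("v0", SUFFIX, "v1", PREFIX, 5),
                     ("v1", SUFFIX, "v2", PREFIX, 5),
                     ("v0", SUFFIX, "v2", PREFIX, 5),
                     ("v2", SUFFIX, "v3", PREFIX, 5)]
        a = make_graph(4, edge_list)
        b = make_graph(4, list(reversed(edge_list)))
        sg.remove_transitive_edges(a)
        sg.remove_transitive_edges(b)
        assert set(a.edges) == set(b.edges)


class TestWeakEdges:
    def test_single_weight9_edge_removed(self):
        g = make_graph(2, [("v0", SUFFIX, "v1", PREFIX, 9)])
        sg.remove_weak_edges(g)
        assert g.edges == {}

    def test_dominated_side_keeps_strong_edge(self):
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 100),
                           ("v0", SUFFIX, "v2", PREFIX, 5)])
        sg.remove_weak_edges(g)
        assert len(g.edges) == 1
        [e] = g.edges.values()
        assert e.weight == 100  # 100 >= 0.9 * 105; 5 fails both rules

    def test_balanced_split_removes_both(self):
        # 100 and 12 from the same side: 100 < 0.9*112 and 12 < 0.9*112
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 100),
                           ("v0", SUFFIX, "v2", PREFIX, 12)])
        sg.remove_weak_edges(g)
        assert g.edges == {}

    def test_sides_pooled_independently(self):
        # opposite sides of v0 do not compete
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 100),
                           ("v0", PREFIX, "v2", SUFFIX, 12)])
        sg.remove_weak_edges(g)
        assert len(g.edges) == 2


class TestTraversal:
    def _seqs(self, n=3, ln=200):
        return {f"v{i}": random_genome(ln, seed=40 + i) for i in range(n)}

    def test_chain_yields_single_scaffold(self):
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 20),
                           ("v1", SUFFIX, "v2", PREFIX, 20)])
        [sc] = sg.traverse_paths(g)
        assert [c for c, _ in sc.parts] == ["v0", "v1", "v2"]
        assert all(o == "+" for _, o in sc.parts)

    def test_gap_is_lower_median_of_samples(self):
        g = make_graph(2, [("v0", SUFFIX, "v1", PREFIX, 3)])
        [e] = g.edges.values()
        e.gaps = [120, 140, 260]
        [sc] = sg.traverse_paths(g)
        assert sc.gaps == [140]
        seqs = self._seqs(2)
        assert "N" * 140 in sc.sequence(seqs)

    def test_negative_median_joins_directly(self):
        g = make_graph(2, [("v0", SUFFIX, "v1", PREFIX, 3)])
        [e] = g.edges.values()
        e.gaps = [-15, -20, -10]
        [sc] = sg.traverse_paths(g)
        assert sc.gaps == [0]
        seqs = self._seqs(2)
        assert "N" not in sc.sequence(seqs)

    def test_orientation_from_arrows(self):
        # v1 entered through its suffix -> reverse complemented
        g = make_graph(2, [("v0", SUFFIX, "v1", SUFFIX, 3)])
        [sc] = sg.traverse_paths(g)
        orient = dict(sc.parts)
        assert {orient["v0"], orient["v1"]} == {"+", "-"}
        seqs = self._seqs(2)
        joined = sc.sequence(seqs)
        assert (seqs["v0"] in joined and revcomp(seqs["v1"]) in joined) \
            or (revcomp(seqs["v0"]) in joined and seqs["v1"] in joined)

    def test_bifurcation_blocks_chaining(self):
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 20),
                           ("v0", SUFFIX, "v2", PREFIX, 20)])
        scaffolds = sg.traverse_paths(g)
        assert sorted(len(sc.parts) for sc in scaffolds) == [1, 1, 1]

    def test_conservation_every_contig_once(self):
        g = make_graph(6, [("v0", SUFFIX, "v1", PREFIX, 20),
                           ("v1", SUFFIX, "v2", PREFIX, 20),
                           ("v3", SUFFIX, "v4", PREFIX, 20)])
        scaffolds = sg.traverse_paths(g)
        used = [c for sc in scaffolds for c, _ in sc.parts]
        assert sorted(used) == [f"v{i}" for i in range(6)]
        seqs = self._seqs(6)
        total = sum(len(sc.sequence(seqs).replace("N", ""))
                    for sc in scaffolds)
        assert total == sum(len(s) for s in seqs.values())

    def test_cycle_broken_at_weakest_edge(self, caplog):
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 20),
                           ("v1", SUFFIX, "v2", PREFIX, 5),
                           ("v2", SUFFIX, "v0", PREFIX, 20)])
        with caplog.at_level("WARNING"):
            scaffolds = sg.traverse_paths(g)
        assert len(scaffolds) == 1
        assert len(scaffolds[0].parts) == 3
        assert any("cycle" in r.message for r in caplog.records)

    def test_reverse_complement_symmetry(self):
        seqs = self._seqs(3)
        g1 = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 20),
                            ("v1", SUFFIX, "v2", PREFIX, 20)])
        [s1] = sg.traverse_paths(g1)
        flip = {PREFIX: SUFFIX, SUFFIX: PREFIX}
        g2 = make_graph(3, [("v0", flip[SUFFIX], "v1", flip[PREFIX], 20),
                            ("v1", flip[SUFFIX], "v2", flip[PREFIX], 20)])
        [s2] = sg.traverse_paths(g2)
        rc_seqs = {k: revcomp(v) for k, v in seqs.items()}
        out1 = s1.sequence(seqs)
        out2 = s2.sequence(rc_seqs)
        assert out2 in (out1, revcomp(out1))


class TestOutputs:
    def test_agp_roundtrip_structure(self, tmp_path):
        g = make_graph(2, [("v0", SUFFIX, "v1", PREFIX, 3)])
        [e] = g.edges.values()
        e.gaps = [50]
        seqs = {"v0": "A" * 100, "v1": "C" * 80}
        scaffolds = sg.traverse_paths(g)
        path = tmp_path / "out.agp"
        sg.write_agp(scaffolds, seqs, path)
        lines = [l.split("\t") for l in path.read_text().splitlines()
                 if not l.startswith("#")]
        kinds = [l[4] for l in lines]
        assert kinds == ["W", "N", "W"]
        assert lines[1][5] == "50"

    def test_gfa_contains_all_vertices_and_links(self, tmp_path):
        g = make_graph(3, [("v0", SUFFIX, "v1", PREFIX, 3)])
        path = tmp_path / "out.gfa"
        sg.write_gfa(g, {f"v{i}": "A" * 10 for i in range(3)}, path)
        text = path.read_text()
        assert text.count("\nS\t") + text.startswith("S\t") == 3
        assert "L\tv0\t+\tv1\t+\t0M\tRC:i:3" in text
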