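"""Strain-aware scaffolding over a bi-directed graph.

Reads aligned to the strain-aware contigs contribute *dovetail* alignments
(suffix of a contig against the prefix of a read, or vice versa, with a
bounded unaligned overhang).  A read with one dovetail at its prefix and
one at its suffix witnesses adjacency between two contigs; such links form
a bi-directed weighted graph in which each edge carries an arrow at both
endpoints recording which contig end participates.  After transitive and
weak edges are removed, every maximal unambiguous path becomes a scaffold,
with gaps sized by the median read distance between the joined contigs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .assembly import StrainAwareContig
from .io import AlignmentRecord, revcomp

logger = logging.getLogger(__name__)

PREFIX = "p"
SUFFIX = "s"


@dataclass(frozen=True)
class DovetailAlignment:
    """A read-to-contig alignment joining a contig end to a read end."""

    read_id: str
    contig_id: str
    contig_end: str            # PREFIX | SUFFIX
    read_end: str              # PREFIX | SUFFIX (forward read orientation)
    strand: str
    match_len: int
    mapq: int
    read_offset: int           # unaligned bases at the involved read end
    qstart: int                # on the forward-oriented read
    qend: int


@dataclass
class Edge:
    """Bi-directed edge: arrows at each endpoint name the contig end."""

    u: str
    u_side: str
    v: str
    v_side: str
    weight: int = 0
    gaps: list[int] = field(default_factory=list)

    @property
    def key(self):
        a, b = (self.u, self.u_side), (self.v, self.v_side)
        return (a, b) if a <= b else (b, a)

    def side_at(self, vertex: str) -> str:
        return self.u_side if vertex == self.u else self.v_side

    def other(self, vertex: str) -> tuple[str, str]:
        if vertex == self.u:
            return self.v, self.v_side
        return self.u, self.u_side


class ScaffoldingGraph:
    """Vertices are strain-aware contig ids; edges are read-supported
    dovetail adjacencies with a weight and signed distance samples."""

    def __init__(self, vertices: list[str]):
        self.vertices = list(vertices)
        self.edges: dict[tuple, Edge] = {}

    def add_link(self, u: str, u_side: str, v: str, v_side: str, gap: int):
        if u == v:
            raise ValueError("self-loops are not allowed")
        e = Edge(u, u_side, v, v_side)
        e = self.edges.setdefault(e.key, e)
        e.weight += 1
        e.gaps.append(gap)

    def edges_at(self, vertex: str, side: str) -> list[Edge]:
        return [e for e in self.edges.values()
                if (e.u == vertex and e.u_side == side)
                or (e.v == vertex and e.v_side == side)]

    def remove(self, keys) -> None:
        for k in keys:
            self.edges.pop(k, None)

    def copy(self) -> "ScaffoldingGraph":
        g = ScaffoldingGraph(self.vertices)
        for k, e in self.edges.items():
            g.edges[k] = Edge(e.u, e.u_side, e.v, e.v_side, e.weight,
                              list(e.gaps))
        return g


@dataclass
class Scaffold:
    """An ordered, oriented contig chain with inter-contig gap sizes."""

    name: str
    parts: list[tuple[str, str]]       # (contig id, '+'|'-')
    gaps: list[int]                    # len(parts) - 1 entries, >= 0

    def __post_init__(self):
        if len(self.gaps) != len(self.parts) - 1:
            raise ValueError("gap count must be contig count - 1")

    def sequence(self, seqs: dict[str, str]) -> str:
        chunks = []
        for k, (cid, orient) in enumerate(self.parts):
            if k:
                chunks.append("N" * self.gaps[k - 1])
            s = seqs[cid]
            chunks.append(s if orient == "+" else revcomp(s))
        return "".join(chunks)


# ---------------------------------------------------------------------------
# Dovetail filtering

def filter_dovetails(records: list[AlignmentRecord], min_mapq: int = 40,
                     max_overhang_bp: int = 50,
                     max_overhang_frac: float = 0.10,
                     ) -> list[DovetailAlignment]:
    """Keep primary, high-confidence, dovetail-shaped alignments.

    Mapping quality must be strictly greater than ``min_mapq``; the
    unaligned extremities at the joined contig/read ends may not exceed
    ``min(max_overhang_bp, max_overhang_frac * match_len)``.
    """
    out = []
    for r in records:
        if not r.base_level:
            raise ValueError(
                f"{r.query} vs {r.target}: alignment lacks base-level "
                "detail; run the aligner with CIGAR output (-c / -a)")
        if not r.primary or r.mapq <= min_mapq:
            continue
        thr = min(max_overhang_bp, max_overhang_frac * r.matches)
        t_pre, t_suf = r.tstart, r.tlen - r.tend
        q_pre, q_suf = r.qstart, r.qlen - r.qend
        # which read end faces which contig end depends on strand
        if r.strand == "+":
            pairings = [(SUFFIX, PREFIX, t_suf, q_pre),
                        (PREFIX, SUFFIX, t_pre, q_suf)]
        else:
            pairings = [(SUFFIX, SUFFIX, t_suf, q_suf),
                        (PREFIX, PREFIX, t_pre, q_pre)]
        for contig_end, read_end, t_ov, q_ov in pairings:
            if t_ov <= thr and q_ov <= thr:
                out.append(DovetailAlignment(
                    read_id=r.query, contig_id=r.target,
                    contig_end=contig_end, read_end=read_end,
                    strand=r.strand, match_len=r.matches, mapq=r.mapq,
                    read_offset=q_ov, qstart=r.qstart, qend=r.qend))
    return out


# ---------------------------------------------------------------------------
# Graph construction

def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _ordered(a: tuple[int, int], b: tuple[int, int]):
    """Return (first, second) if intervals are disjoint and ordered."""
    if a[1] <= b[0]:
        return a, b
    if b[1] <= a[0]:
        return b, a
    return None


class _AdmissionRules:
    """The four link-admission rules over contig provenance metadata."""

    def __init__(self, contigs: list[StrainAwareContig],
                 backbone_lengths: dict[str, int],
                 extremity_window: int = 1000):
        self.by_id = {c.id: c for c in contigs}
        self.backbone_lengths = backbone_lengths
        self.window = extremity_window
        self.by_backbone: dict[str, list[StrainAwareContig]] = defaultdict(list)
        for c in contigs:
            self.by_backbone[c.origin_contig].append(c)
        self.hap_intervals: dict[str, set[tuple[int, int]]] = defaultdict(set)
        for c in contigs:
            if c.kind == "haplotype":
                self.hap_intervals[c.origin_contig].add(c.origin_interval)

    def consecutive(self, a: StrainAwareContig, b: StrainAwareContig) -> bool:
        if a.origin_contig != b.origin_contig:
            return False
        pair = _ordered(a.origin_interval, b.origin_interval)
        if pair is None:
            return False
        gap = (pair[0][1], pair[1][0])
        for c in self.by_backbone[a.origin_contig]:
            if c.id in (a.id, b.id):
                continue
            if _intervals_overlap(c.origin_interval, gap):
                return False
        return True

    def adjacent_haplotypes(self, a: StrainAwareContig,
                            b: StrainAwareContig) -> bool:
        if (a.kind != "haplotype" or b.kind != "haplotype"
                or a.origin_contig != b.origin_contig):
            return False
        pair = _ordered(a.origin_interval, b.origin_interval)
        if pair is None:
            return False
        gap = (pair[0][1], pair[1][0])
        for iv in self.hap_intervals[a.origin_contig]:
            if iv in (a.origin_interval, b.origin_interval):
                continue
            if _intervals_overlap(iv, gap):
                return False
        return True

    def unphased_hap_link(self, a: StrainAwareContig,
                          b: StrainAwareContig) -> bool:
        kinds = {a.kind, b.kind}
        return kinds == {"unphased", "haplotype"}

    def at_extremity(self, c: StrainAwareContig) -> bool:
        blen = self.backbone_lengths.get(c.origin_contig)
        if blen is None:
            return False
        s, e = c.origin_interval
        return s <= self.window or e >= blen - self.window

    def admitted(self, a: StrainAwareContig, b: StrainAwareContig) -> bool:
        return (self.consecutive(a, b)
                or self.adjacent_haplotypes(a, b)
                or self.unphased_hap_link(a, b)
                or (self.at_extremity(a) and self.at_extremity(b)))


def build_graph(dovetails: list[DovetailAlignment],
                contigs: list[StrainAwareContig],
                backbone_lengths: dict[str, int],
                extremity_window: int = 1000) -> ScaffoldingGraph:
    """Link contigs bridged by reads with prefix+suffix dovetails.

    An edge appears only when a read has one dovetail involving its prefix
    and one involving its suffix, on two different contigs, and the pair
    satisfies at least one admission rule: (i) consecutive contigs on a
    backbone, (ii) adjacent haplotype-assembled contigs, (iii) a
    read-linked unphased/haplotype pair, (iv) two contigs both mapping on
    a backbone extremity.
    """
    rules = _AdmissionRules(contigs, backbone_lengths, extremity_window)
    graph = ScaffoldingGraph([c.id for c in contigs])
    per_read: dict[str, dict[str, DovetailAlignment]] = defaultdict(dict)
    def rank(d: DovetailAlignment):
        return (-d.match_len, d.contig_id, d.contig_end)

    for d in dovetails:
        cur = per_read[d.read_id].get(d.read_end)
        # at most one dovetail per read end: keep the strongest match
        if cur is None or rank(d) < rank(cur):
            per_read[d.read_id][d.read_end] = d
    for read_id in sorted(per_read):
        ends = per_read[read_id]
        if PREFIX not in ends or SUFFIX not in ends:
            continue
        d1, d2 = ends[PREFIX], ends[SUFFIX]
        if d1.contig_id == d2.contig_id:
            continue
        a = rules.by_id.get(d1.contig_id)
        b = rules.by_id.get(d2.contig_id)
        if a is None or b is None or not rules.admitted(a, b):
            continue
        gap = d2.qstart - d1.qend   # read bases strictly between alignments
        graph.add_link(d1.contig_id, d1.contig_end,
                       d2.contig_id, d2.contig_end, gap)
    return graph


# ---------------------------------------------------------------------------
# Simplification

def remove_transitive_edges(graph: ScaffoldingGraph) -> ScaffoldingGraph:
    """Drop every edge shortcut by a valid two-edge path with matching
    arrows; evaluated against the original edge set (order-independent)."""
    edges = list(graph.edges.values())
    at: dict[tuple[str, str], list[Edge]] = defaultdict(list)
    for e in edges:
        at[(e.u, e.u_side)].append(e)
        at[(e.v, e.v_side)].append(e)
    doomed = []
    for e in edges:
        if _has_bypass(e, at):
            doomed.append(e.key)
    graph.remove(doomed)
    return graph


def _has_bypass(e: Edge, at) -> bool:
    for e1 in at[(e.u, e.u_side)]:
        if e1.key == e.key:
            continue
        z, z_in = e1.other(e.u)
        if z in (e.u, e.v):
            continue
        # traverse z: enter one contig end, exit through the other
        z_out = PREFIX if z_in == SUFFIX else SUFFIX
        for e2 in at[(z, z_out)]:
            if e2.key in (e.key, e1.key):
                continue
            w, w_side = e2.other(z)
            if w == e.v and w_side == e.v_side:
                return True
    return False


def remove_weak_edges(graph: ScaffoldingGraph, min_reads: int = 10,
                      frac: float = 0.9) -> ScaffoldingGraph:
    """Remove edges supported by fewer than ``min_reads`` reads or by less
    than ``frac`` of the total support of all edges exiting either of the
    two vertex sides they touch (sides pooled independently)."""
    totals: dict[tuple[str, str], int] = defaultdict(int)
    for e in graph.edges.values():
        totals[(e.u, e.u_side)] += e.weight
        totals[(e.v, e.v_side)] += e.weight
    doomed = []
    for e in graph.edges.values():
        if e.weight < min_reads:
            doomed.append(e.key)
        elif (e.weight < frac * totals[(e.u, e.u_side)]
                or e.weight < frac * totals[(e.v, e.v_side)]):
            doomed.append(e.key)
    graph.remove(doomed)
    return graph


# ---------------------------------------------------------------------------
# Traversal

def _lower_median(samples: list[int]) -> int:
    return sorted(samples)[(len(samples) - 1) // 2]


def traverse_paths(graph: ScaffoldingGraph) -> list[Scaffold]:
    """Emit one scaffold per maximal unambiguous path.

    An edge is traversable only when it is the unique edge at both of its
    endpoint sides; cycles are broken at their lowest-weight edge.  Every
    contig appears in exactly one scaffold (isolated ones as singletons).
    """
    degree: dict[tuple[str, str], int] = defaultdict(int)
    for e in graph.edges.values():
        degree[(e.u, e.u_side)] += 1
        degree[(e.v, e.v_side)] += 1
    chain: dict[tuple[str, str], Edge] = {}
    for e in graph.edges.values():
        if degree[(e.u, e.u_side)] == 1 and degree[(e.v, e.v_side)] == 1:
            chain[(e.u, e.u_side)] = e
            chain[(e.v, e.v_side)] = e

    # break cycles (components where every chain vertex has both sides used)
    visited_cycle: set[str] = set()
    for start in sorted({v for (v, _s) in chain}):
        if start in visited_cycle:
            continue
        comp_edges: list[Edge] = []
        comp_vertices = {start}
        stack = [start]
        open_end = False
        while stack:
            v = stack.pop()
            for side in (PREFIX, SUFFIX):
                e = chain.get((v, side))
                if e is None:
                    open_end = True
                    continue
                if e not in comp_edges:
                    comp_edges.append(e)
                    w, _ = e.other(v)
                    if w not in comp_vertices:
                        comp_vertices.add(w)
                        stack.append(w)
        visited_cycle |= comp_vertices
        if not open_end and comp_edges:
            weakest = min(comp_edges, key=lambda e: (e.weight, e.key))
            logger.warning("cycle through %d contigs broken at %s-%s",
                           len(comp_vertices), weakest.u, weakest.v)
            del chain[(weakest.u, weakest.u_side)]
            del chain[(weakest.v, weakest.v_side)]

    scaffolds: list[Scaffold] = []
    used: set[str] = set()
    for start in sorted(graph.vertices):
        if start in used:
            continue
        sides_with_edge = [s for s in (PREFIX, SUFFIX)
                           if (start, s) in chain]
        if len(sides_with_edge) == 2:
            continue  # interior vertex; reached from an endpoint
        exit_side = sides_with_edge[0] if sides_with_edge else SUFFIX
        parts = [(start, "+" if exit_side == SUFFIX else "-")]
        gaps: list[int] = []
        used.add(start)
        v, side = start, exit_side
        while (v, side) in chain:
            e = chain[(v, side)]
            w, w_in = e.other(v)
            if w in used:
                break
            med = _lower_median(e.gaps)
            gaps.append(med if med > 0 else 0)
            parts.append((w, "+" if w_in == PREFIX else "-"))
            used.add(w)
            v, side = w, (SUFFIX if w_in == PREFIX else PREFIX)
        parts, gaps = _canonical(parts, gaps)
        scaffolds.append(Scaffold(f"scaffold_{len(scaffolds)}", parts, gaps))
    # any vertex still unused can only come from a residual cycle
    for v in sorted(graph.vertices):
        if v not in used:
            used.add(v)
            scaffolds.append(Scaffold(f"scaffold_{len(scaffolds)}",
                                      [(v, "+")], []))
    return scaffolds


def _canonical(parts, gaps):
    flipped = [(c, "+" if o == "-" else "-") for c, o in reversed(parts)]
    if flipped < parts:
        return flipped, list(reversed(gaps))
    return parts, gaps


# ---------------------------------------------------------------------------
# Output formats

def write_agp(scaffolds: list[Scaffold], seqs: dict[str, str],
              path: str | Path) -> None:
    """AGP v2.1 description of scaffold composition."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for sc in scaffolds:
            pos = 1
            part = 1
            for k, (cid, orient) in enumerate(sc.parts):
                if k:
                    gap = sc.gaps[k - 1]
                    if gap > 0:
                        fh.write(f"{sc.name}\t{pos}\t{pos + gap - 1}\t{part}"
                                 f"\tN\t{gap}\tscaffold\tyes\tna\n")
                        pos += gap
                        part += 1
                ln = len(seqs[cid])
                fh.write(f"{sc.name}\t{pos}\t{pos + ln - 1}\t{part}\tW\t"
                         f"{cid}\t1\t{ln}\t{orient}\n")
                pos += ln
                part += 1


def write_gfa(graph: ScaffoldingGraph, seqs: dict[str, str],
              path: str | Path) -> None:
    """GFA 1.0 dump of the simplified graph for inspection."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for v in graph.vertices:
            ln = len(seqs.get(v, ""))
            fh.write(f"S\t{v}\t*\tLN:i:{ln}\n")
        for e in sorted(graph.edges.values(), key=lambda e: e.key):
            # suffix involvement = forward orientation leaving the contig
            ou = "+" if e.u_side == SUFFIX else "-"
            ov = "+" if e.v_side == PREFIX else "-"
            fh.write(f"L\t{e.u}\t{ou}\t{e.v}\t{ov}\t0M\tRC:i:{e.weight}\n")
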