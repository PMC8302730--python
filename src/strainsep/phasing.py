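"""SNV detection, diploid phasing, phasesets, and read separation.

Aligned long reads are piled up on each backbone contig to find biallelic
substitution sites (SNVs); reads are then bipartitioned into two haplotypes
per phase block by a greedy minimum-error-correction (MEC) heuristic, and
each block becomes a *phaseset*: the interval from its first to its last
phased SNV, annotated with the percentage of positions in that interval
that are SNVs (its density).  Reads overlapping a phaseset are separated by
minimum Hamming distance to the two haplotype allele vectors.

An external phaser (phased VCF + haplotag table) can be ingested in place
of the internal caller via :func:`load_external_phasing`.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class SNVSite:
    """A biallelic substitution site on a backbone contig (0-based)."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not 0 < self.alt_count < self.depth:
            raise ValueError("alt_count must be within (0, depth)")


class ReadSNVMatrix:
    """Per-read alleles at called SNV sites on one contig.

    Entries are 0 (ref), 1 (alt) or absent; a read has an entry only where
    its alignment spans the site and shows one of the two alleles.
    ``read_spans`` keeps each read's alignment interval for overlap tests.
    """

    def __init__(self, contig: str, sites: list[SNVSite]):
        self.contig = contig
        self.sites = sites
        self.positions = np.array([s.pos for s in sites], dtype=np.int64)
        self.entries: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.read_spans: dict[str, tuple[int, int]] = {}

    def add_read(self, read_id: str, span: tuple[int, int],
                 site_idx: np.ndarray, alleles: np.ndarray) -> None:
        self.read_spans[read_id] = span
        if len(site_idx):
            self.entries[read_id] = (site_idx.astype(np.int64),
                                     alleles.astype(np.int8))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def reads_overlapping(self, s: int, e: int) -> list[str]:
        """Reads whose alignment overlaps the inclusive interval [s, e]."""
        return [r for r, (a, b) in self.read_spans.items()
                if a <= e and b > s]


@dataclass
class Phaseset:
    """Interval (contig, s, e) from first to last phased SNV of a block.

    ``haplotypes`` holds the two allele vectors over ``snv_positions``
    (0 = ref, 1 = alt); by the diploid model they are complementary, i.e.
    they differ at every position.  ``dens`` is the percentage of positions
    in [s, e] that are phased SNVs.
    """

    contig: str
    s: int
    e: int
    snv_positions: np.ndarray
    haplotypes: tuple[np.ndarray, np.ndarray]
    dens: float = field(init=False)

    def __post_init__(self):
        if self.s > self.e:
            raise ValueError("phaseset requires s <= e")
        self.snv_positions = np.asarray(self.snv_positions, dtype=np.int64)
        if (self.snv_positions[0] != self.s
                or self.snv_positions[-1] != self.e):
            raise ValueError("s/e must be the first/last phased SNVs")
        h1, h2 = self.haplotypes
        if np.any(h1 == h2):
            raise ValueError("haplotype vectors must differ at every site")
        self.dens = self.density()

    def density(self) -> float:
        return 100.0 * len(self.snv_positions) / (self.e - self.s + 1)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_positions)


@dataclass
class HaplotypeBlock:
    """A phased block: global site indices, h1 alleles, per-read tags."""

    contig: str
    site_idx: np.ndarray            # indices into the matrix's site list
    positions: np.ndarray           # contig coordinates of those sites
    h1: np.ndarray                  # 0/1 alleles of haplotype 1
    tags: dict[str, str | None]     # read -> 'h1' | 'h2' | None


# ---------------------------------------------------------------------------
# SNV detection

def detect_snvs(bam: str | Path | pysam.AlignmentFile, contig: str,
                ref_seq: str, min_depth: int = 10, min_alt_frac: float = 0.2,
                min_per_allele: int = 5) -> list[SNVSite]:
    """Call biallelic SNVs on ``contig`` from a sorted, indexed alignment.

    A column is a SNV when depth >= ``min_depth``, the backbone base is one
    of the two most frequent bases (it becomes the ref allele), and the
    most frequent non-reference base reaches both ``min_per_allele`` reads
    and ``min_alt_frac`` of the depth.  Only substitutions are considered.
    """
    af = (bam if isinstance(bam, pysam.AlignmentFile)
          else pysam.AlignmentFile(str(bam)))
    if contig not in af.references:
        raise ValueError(f"contig {contig!r} absent from alignments")
    counts = np.array(af.count_coverage(contig, quality_threshold=0),
                      dtype=np.int64)  # 4 x L, rows A,C,G,T
    if not isinstance(bam, pysam.AlignmentFile):
        af.close()
    depth = counts.sum(axis=0)
    L = counts.shape[1]
    ref_idx = np.frombuffer(ref_seq[:L].upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        lut[ord(b)] = i
    ref_row = lut[ref_idx]
    valid = (depth >= min_depth) & (ref_row >= 0)
    cols = np.nonzero(valid)[0]
    if not len(cols):
        return []
    sub = counts[:, cols]
    ref_counts = sub[ref_row[cols], np.arange(len(cols))]
    masked = sub.copy()
    masked[ref_row[cols], np.arange(len(cols))] = -1
    alt_row = masked.argmax(axis=0)
    alt_counts = masked.max(axis=0)
    dep = depth[cols]
    keep = ((alt_counts >= min_per_allele)
            & (ref_counts >= min_per_allele)
            & (alt_counts >= min_alt_frac * dep)
            # backbone base must be one of the two most frequent bases
            & (ref_counts >= np.sort(sub, axis=0)[-2, :]))
    bases = "ACGT"
    sites = [SNVSite(contig, int(p), bases[ref_row[p]], bases[a],
                     int(d), int(c))
             for p, a, c, d in zip(cols[keep], alt_row[keep],
                                   alt_counts[keep], dep[keep])]
    return sites


def build_matrix(bam: str | Path | pysam.AlignmentFile, contig: str,
                 sites: list[SNVSite]) -> ReadSNVMatrix:
    """Collect per-read alleles at the called sites from primary alignments."""
    mat = ReadSNVMatrix(contig, sites)
    af = (bam if isinstance(bam, pysam.AlignmentFile)
          else pysam.AlignmentFile(str(bam)))
    positions = mat.positions
    ref_b = np.frombuffer("".join(s.ref_allele for s in sites).encode(),
                          dtype="S1") if sites else np.array([], dtype="S1")
    alt_b = np.frombuffer("".join(s.alt_allele for s in sites).encode(),
                          dtype="S1") if sites else np.array([], dtype="S1")
    for aln in af.fetch(contig):
        if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
            continue
        span = (aln.reference_start, aln.reference_end)
        if not len(positions):
            mat.add_read(aln.query_name, span, np.array([]), np.array([]))
            continue
        pairs = aln.get_aligned_pairs(matches_only=True)
        if not pairs:
            continue
        arr = np.asarray(pairs, dtype=np.int64)
        qpos, rpos = arr[:, 0], arr[:, 1]
        lo = np.searchsorted(rpos, positions, side="left")
        hit = (lo < len(rpos))
        lo_c = np.minimum(lo, len(rpos) - 1)
        hit &= rpos[lo_c] == positions
        idx = np.nonzero(hit)[0]
        if not len(idx):
            mat.add_read(aln.query_name, span, np.array([]), np.array([]))
            continue
        seq = np.frombuffer(aln.query_sequence.upper().encode(), dtype="S1")
        obs = seq[qpos[lo_c[idx]]]
        is_ref = obs == ref_b[idx]
        is_alt = obs == alt_b[idx]
        known = is_ref | is_alt
        mat.add_read(aln.query_name, span, idx[known],
                     is_alt[known].astype(np.int8))
    if not isinstance(bam, pysam.AlignmentFile):
        af.close()
    return mat


# ---------------------------------------------------------------------------
# Phasing

def _blocks_from_links(mat: ReadSNVMatrix) -> list[np.ndarray]:
    """Split sites into blocks; a block breaks where no read carries both
    of two consecutive SNVs."""
    n = mat.n_sites
    if n == 0:
        return []
    link = np.zeros(max(n - 1, 0), dtype=bool)
    for idx, _ in mat.entries.values():
        if len(idx) > 1:
            d = np.diff(idx)
            link[idx[:-1][d == 1]] = True
    blocks = []
    start = 0
    for k in range(n - 1):
        if not link[k]:
            blocks.append(np.arange(start, k + 1))
            start = k + 1
    blocks.append(np.arange(start, n))
    return blocks


def mec(entries: dict[str, tuple[np.ndarray, np.ndarray]],
        h1: np.ndarray, site_lookup: dict[int, int] | None = None) -> int:
    """Mismatch-error-correction cost of haplotype ``h1`` (h2 implied as its
    complement): sum over reads of the distance to the closer haplotype."""
    total = 0
    for idx, alleles in entries.values():
        if site_lookup is not None:
            keep = np.array([i in site_lookup for i in idx.tolist()])
            if not keep.any():
                continue
            local = np.array([site_lookup[i] for i in idx[keep].tolist()])
            a = alleles[keep]
        else:
            local, a = idx, alleles
        d1 = int(np.sum(a != h1[local]))
        total += min(d1, len(a) - d1)
    return total


def phase_diploid(mat: ReadSNVMatrix, seed: int = 0,
                  refine_sweeps: int = 2) -> list[HaplotypeBlock]:
    """Greedy seed-and-extend MEC phasing of the read/SNV matrix.

    Within each block the longest-spanning read seeds haplotype 1; the
    remaining reads are committed in order of decreasing overlap with the
    already-phased sites, each to the closer haplotype; two majority-vote
    refinement sweeps follow.  Ties (equal distance, or zero covered
    phased sites) leave a read untagged.  Fully deterministic: all ties
    break on lexicographic read id, ``seed`` is accepted for interface
    symmetry only.
    """
    blocks_idx = _blocks_from_links(mat)
    out: list[HaplotypeBlock] = []
    for bidx in blocks_idx:
        lookup = {int(g): k for k, g in enumerate(bidx)}
        lo, hi = int(bidx[0]), int(bidx[-1])
        # restrict entries to this block
        local: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for rid, (idx, alleles) in mat.entries.items():
            keep = (idx >= lo) & (idx <= hi)
            if keep.any():
                local[rid] = (idx[keep] - lo, alleles[keep])
        nb = len(bidx)
        if not local:
            continue
        votes = np.zeros(nb, dtype=np.int64)   # +1 per h1-alt/h2-ref vote
        nvotes = np.zeros(nb, dtype=np.int64)  # votes present per site
        tags: dict[str, str | None] = {rid: None for rid in local}
        # reads covering each site, for overlap updates on commit
        reads_at_site: list[list[str]] = [[] for _ in range(nb)]
        for rid, (idx, _) in local.items():
            for k in idx.tolist():
                reads_at_site[k].append(rid)
        overlap = {rid: 0 for rid in local}
        heap: list[tuple[int, str]] = []

        def commit(rid: str, hap: str):
            idx, alleles = local[rid]
            sign = 1 if hap == "h1" else -1
            votes[idx] += sign * (2 * alleles.astype(np.int64) - 1)
            tags[rid] = hap
            newly = idx[nvotes[idx] == 0]
            nvotes[idx] += 1
            # overlap of pending reads grew: re-push with exact keys
            for k in newly.tolist():
                for other in reads_at_site[k]:
                    if tags.get(other) is None:
                        overlap[other] += 1
                        heapq.heappush(heap, (-overlap[other], other))

        seed_read = min(local, key=lambda r: (-len(local[r][0]), r))
        commit(seed_read, "h1")
        while heap:
            negov, rid = heapq.heappop(heap)
            # stale entry: a fresher, higher-overlap one is in the heap
            if tags.get(rid) is not None or -negov != overlap[rid]:
                continue
            idx, alleles = local[rid]
            h1_here = (votes[idx] > 0).astype(np.int8)
            covered = nvotes[idx] > 0
            d1 = int(np.sum(alleles[covered] != h1_here[covered]))
            d2 = int(covered.sum()) - d1
            if d1 == d2:
                continue  # ambiguous now; revisited if its overlap grows
            commit(rid, "h1" if d1 < d2 else "h2")

        h1 = (votes > 0).astype(np.int8)
        for _ in range(refine_sweeps):
            # recompute haplotype as weighted majority of tagged reads
            votes[:] = 0
            for rid, hap in tags.items():
                if hap is None:
                    continue
                idx, alleles = local[rid]
                sign = 1 if hap == "h1" else -1
                votes[idx] += sign * (2 * alleles.astype(np.int64) - 1)
            h1 = (votes > 0).astype(np.int8)
            for rid in sorted(local):
                idx, alleles = local[rid]
                d1 = int(np.sum(alleles != h1[idx]))
                d2 = len(alleles) - d1
                tags[rid] = ("h1" if d1 < d2 else "h2") if d1 != d2 else None

        out.append(HaplotypeBlock(
            contig=mat.contig, site_idx=bidx,
            positions=mat.positions[bidx], h1=h1, tags=tags))
    return out


# ---------------------------------------------------------------------------
# Phasesets and separation

def extract_phasesets(blocks: list[HaplotypeBlock],
                      min_dens: float = 0.1) -> list[Phaseset]:
    """One phaseset per block spanning [first SNV, last SNV].

    Blocks with fewer than two SNVs carry no phase information and are
    skipped; phasesets with density strictly below ``min_dens`` percent
    are discarded (high-identity regions are left unseparated).
    """
    out = []
    for blk in blocks:
        if len(blk.positions) < 2:
            continue
        ps = Phaseset(contig=blk.contig, s=int(blk.positions[0]),
                      e=int(blk.positions[-1]), snv_positions=blk.positions,
                      haplotypes=(blk.h1, (1 - blk.h1).astype(np.int8)))
        if ps.dens < min_dens:
            continue
        out.append(ps)
    out.sort(key=lambda p: p.s)
    return out


def separate_reads(ps: Phaseset, mat: ReadSNVMatrix,
                   ) -> tuple[set[str], set[str], set[str]]:
    """Partition reads overlapping [s, e] by Hamming distance to the two
    haplotype vectors; ties and SNV-free reads are untagged."""
    pos_to_local = {int(p): k for k, p in enumerate(ps.snv_positions)}
    site_local = np.array(
        [pos_to_local.get(int(p), -1) for p in mat.positions],
        dtype=np.int64)
    h1 = ps.haplotypes[0]
    h1_set: set[str] = set()
    h2_set: set[str] = set()
    untagged: set[str] = set()
    for rid in mat.reads_overlapping(ps.s, ps.e):
        ent = mat.entries.get(rid)
        if ent is None:
            untagged.add(rid)
            continue
        idx, alleles = ent
        loc = site_local[idx]
        m = loc >= 0
        if not m.any():
            untagged.add(rid)
            continue
        d1 = int(np.sum(alleles[m] != h1[loc[m]]))
        d2 = int(m.sum()) - d1
        if d1 < d2:
            h1_set.add(rid)
        elif d2 < d1:
            h2_set.add(rid)
        else:
            untagged.add(rid)
    return h1_set, h2_set, untagged


# ---------------------------------------------------------------------------
# VCF / haplotag I/O

def write_phased_vcf(phasesets: list[Phaseset],
                     sites_by_contig: dict[str, list[SNVSite]],
                     path: str | Path) -> None:
    """Emit phased genotypes (VCF 4.2, 1-based, PS = phaseset start)."""
    site_lookup = {(c, s.pos): s for c, ss in sites_by_contig.items()
                   for s in ss}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 "\tSAMPLE\n")
        for ps in phasesets:
            ps_id = ps.s + 1
            for k, p in enumerate(ps.snv_positions.tolist()):
                site = site_lookup.get((ps.contig, p))
                if site is None:
                    continue
                a1 = int(ps.haplotypes[0][k])
                fh.write(f"{ps.contig}\t{p + 1}\t.\t{site.ref_allele}\t"
                         f"{site.alt_allele}\t.\tPASS\t.\tGT:PS\t"
                         f"{a1}|{1 - a1}:{ps_id}\n")


def load_external_phasing(vcf_path: str | Path, haplotag_path: str | Path,
                          contig: str) -> tuple[list[Phaseset], dict[str, str]]:
    """Hook: ingest an externally produced phased VCF plus a haplotag table
    (``read_id<TAB>h1|h2``) in place of the internal caller/phaser."""
    groups: dict[int, list[tuple[int, int]]] = {}
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] != contig or len(f) < 10:
                continue
            fmt = f[8].split(":")
            vals = dict(zip(fmt, f[9].split(":")))
            gt = vals.get("GT", "")
            if "|" not in gt:
                continue
            ps_id = int(vals.get("PS", 0))
            a1 = int(gt.split("|")[0])
            groups.setdefault(ps_id, []).append((int(f[1]) - 1, a1))
    phasesets = []
    for ps_id in sorted(groups):
        rows = sorted(groups[ps_id])
        if len(rows) < 2:
            continue
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        h1 = np.array([r[1] for r in rows], dtype=np.int8)
        phasesets.append(Phaseset(contig=contig, s=int(pos[0]), e=int(pos[-1]),
                                  snv_positions=pos,
                                  haplotypes=(h1, (1 - h1).astype(np.int8))))
    tags = {}
    with open(haplotag_path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                fields = line.split()
                # 2-column (read, tag) or wider tables with the tag last
                tags[fields[0]] = fields[-1]
    return phasesets, tags
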