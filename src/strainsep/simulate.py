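"""Synthetic strain communities with planted truth.

Generates mixtures of conspecific strain genomes (2-5 strains, pairwise
divergence in the 0.1-3% range), PacBio-like long reads (mean length about
6 kbp, 85-97% identity), and truth alignments against a "backbone" genome,
so every downstream stage of the pipeline can be exercised without an
external aligner or downloads.

The backbone is the first strain's genome: it stands in for a
strain-oblivious assembly in which conspecific strains have been collapsed
onto one consensus contig.  Every other strain carries an explicit edit
script against the backbone, and every read carries an explicit edit script
against its source strain; composing the two yields exact truth CIGARs.

The read error model injects substitutions, insertions and deletions at
60/20/20 of the total error rate (1 - identity): a deliberate simplification
of PacBio error profiles -- downstream behavior depends on SNV density and
read span, not on the exact error process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .io import revcomp, write_fasta, write_fastq

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")

# CIGAR op codes as used throughout: "M" consumes query+reference (matches
# and substitutions alike), "I" consumes query only, "D" reference only.
Cigar = list[tuple[str, int]]


@dataclass
class StrainTruth:
    """A strain genome with its planted differences to the backbone.

    ``variants`` lists substitutions as ``(backbone_pos, ref, alt)`` with
    strictly increasing 0-based positions; ``backbone_cigar`` aligns the
    strain genome (query) to the backbone (reference) and is a single
    ``[("M", len)]`` run when ``indel_rate`` was zero.
    """

    strain_id: str
    genome: str
    variants: list[tuple[int, str, str]]
    coverage: float
    backbone_cigar: Cigar = field(default_factory=list)

    def __post_init__(self):
        if not self.backbone_cigar:
            self.backbone_cigar = [("M", len(self.genome))]


@dataclass
class SimulatedRead:
    """A read with truth provenance.

    ``true_start``/``true_end`` are 0-based half-open *backbone*
    coordinates of the genomic segment the read was drawn from; ``strand``
    records whether ``sequence`` is the reverse complement of that segment
    (after error injection).  ``cigar`` aligns the forward-oriented read to
    its source strain segment ``[src_start, src_end)``.
    """

    read_id: str
    sequence: str
    source_strain: str
    true_start: int
    true_end: int
    strand: str
    src_start: int = 0
    src_end: int = 0
    cigar: Cigar = field(default_factory=list)

    @property
    def forward_sequence(self) -> str:
        return self.sequence if self.strand == "+" else revcomp(self.sequence)


# ---------------------------------------------------------------------------
# Genome mutation

def random_genome(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(BASES, size=length).tobytes().decode()


def mutate_genome(base_genome: str, divergence: float, indel_rate: float = 0.0,
                  seed: int = 0, strain_id: str = "strain", coverage: float = 50.0,
                  ) -> StrainTruth:
    """Derive a strain genome from the backbone by uniform random edits.

    Substitutions are placed uniformly at an expected rate of ``divergence``
    per base; 1-bp insertions/deletions at ``indel_rate`` (default 0, which
    keeps strain and backbone coordinates identical).  Deterministic for a
    fixed seed.
    """
    if not base_genome:
        raise ValueError("base genome must be non-empty")
    if not 0.0 <= divergence <= 0.05:
        raise ValueError(f"divergence {divergence} outside [0, 0.05]")
    if not 0.0 <= indel_rate <= 0.01:
        raise ValueError(f"indel_rate {indel_rate} outside [0, 0.01]")
    rng = np.random.default_rng(seed)
    n = len(base_genome)
    n_sub = rng.binomial(n, divergence)
    n_ind = rng.binomial(n, indel_rate)
    pos = rng.choice(n, size=min(n, n_sub + n_ind), replace=False)
    sub_pos = np.sort(pos[:n_sub])
    ind_pos = set(pos[n_sub:].tolist())

    base = np.frombuffer(base_genome.encode(), dtype="S1")
    genome = base.copy()
    variants: list[tuple[int, str, str]] = []
    # substitutions: pick uniformly among the three non-reference bases
    for p in sub_pos.tolist():
        ref = base_genome[p]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        genome[p] = alt.encode()
        variants.append((p, ref, alt))

    if not ind_pos:
        return StrainTruth(strain_id, genome.tobytes().decode(), variants,
                           coverage, [("M", n)])

    # rebuild with indels; cigar aligns strain (query) to backbone (ref)
    out: list[str] = []
    cigar: Cigar = []

    def emit(op: str, ln: int):
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    prev = 0
    seq = genome.tobytes().decode()
    for p in sorted(ind_pos):
        out.append(seq[prev:p])
        emit("M", p - prev)
        if rng.random() < 0.5:  # insertion before backbone base p
            ins = rng.choice(BASES).decode()
            out.append(ins)
            emit("I", 1)
            prev = p
        else:  # deletion of backbone base p
            emit("D", 1)
            prev = p + 1
    out.append(seq[prev:])
    emit("M", n - prev)
    return StrainTruth(strain_id, "".join(out), variants, coverage, cigar)


# ---------------------------------------------------------------------------
# Read simulation

def _merge(cigar: Cigar) -> Cigar:
    merged: Cigar = []
    for op, ln in cigar:
        if ln == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


def _inject_errors(segment: str, error_rate: float, rng: np.random.Generator,
                   ) -> tuple[str, Cigar]:
    """Plant substitutions/insertions/deletions at 60/20/20 of error_rate.

    Returns the erroneous sequence and its CIGAR against ``segment``.
    """
    n = len(segment)
    if error_rate <= 0:
        return segment, [("M", n)]
    k = rng.binomial(n, error_rate)
    if k == 0:
        return segment, [("M", n)]
    pos = np.sort(rng.choice(n, size=min(n, k), replace=False))
    kinds = rng.choice(3, size=len(pos), p=[0.6, 0.2, 0.2])  # sub/ins/del
    out: list[str] = []
    cigar: Cigar = []
    prev = 0
    for p, kind in zip(pos.tolist(), kinds.tolist()):
        out.append(segment[prev:p])
        cigar.append(("M", p - prev))
        if kind == 0:
            alt = rng.choice([b for b in "ACGT" if b != segment[p]])
            out.append(alt)
            cigar.append(("M", 1))
            prev = p + 1
        elif kind == 1:  # insertion before position p
            out.append(rng.choice(BASES).decode())
            cigar.append(("I", 1))
            prev = p
        else:  # deletion of position p
            cigar.append(("D", 1))
            prev = p + 1
    out.append(segment[prev:])
    cigar.append(("M", n - prev))
    return "".join(out), _merge(cigar)


def simulate_reads(strains: list[StrainTruth], mean_len: int = 6000,
                   sd_len: int = 3700, mean_identity: float = 0.90,
                   sd_identity: float = 0.03, max_identity: float = 0.97,
                   min_len: int = 500, seed: int = 0) -> list[SimulatedRead]:
    """Simulate long reads from each strain at its stated fold-coverage.

    Read lengths follow a gamma distribution matched to ``mean_len``/
    ``sd_len`` (truncated at ``min_len`` and the genome length); per-read
    identity is normal around ``mean_identity`` truncated at
    ``max_identity``.  Each read is reverse-complemented with probability
    0.5.  Per-strain total bases land within 10% of the requested coverage.
    """
    if not strains:
        raise ValueError("strain list is empty")
    for st in strains:
        if st.coverage <= 0:
            raise ValueError(f"{st.strain_id}: coverage must be > 0")
        if mean_len >= len(st.genome):
            raise ValueError(f"{st.strain_id}: mean_len >= genome length")
    rng = np.random.default_rng(seed)
    shape = (mean_len / sd_len) ** 2
    scale = sd_len**2 / mean_len
    reads: list[SimulatedRead] = []
    for st in strains:
        glen = len(st.genome)
        target = st.coverage * glen
        total = 0
        idx = 0
        while total < target:
            ln = int(rng.gamma(shape, scale))
            ln = max(min_len, min(ln, glen))
            start = int(rng.integers(0, glen - ln + 1))
            segment = st.genome[start : start + ln]
            identity = min(float(rng.normal(mean_identity, sd_identity)),
                           max_identity)
            identity = max(identity, 0.75)
            seq, cigar = _inject_errors(segment, 1.0 - identity, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            bstart, bend = _project_interval(st, start, start + ln)
            reads.append(SimulatedRead(
                read_id=f"{st.strain_id}_r{idx:06d}",
                sequence=seq if strand == "+" else revcomp(seq),
                source_strain=st.strain_id,
                true_start=bstart, true_end=bend, strand=strand,
                src_start=start, src_end=start + ln, cigar=cigar,
            ))
            total += len(seq)
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# Truth alignments

def _project_interval(strain: StrainTruth, a: int, b: int) -> tuple[int, int]:
    """Map strain-genome interval [a, b) to backbone coordinates."""
    q = r = 0
    bstart = bend = None
    for op, ln in strain.backbone_cigar:
        if op == "M":
            if bstart is None and a < q + ln:
                bstart = r + max(0, a - q)
            if b <= q + ln:
                bend = r + (b - q)
                break
            q += ln
            r += ln
        elif op == "I":
            if bstart is None and a < q + ln:
                bstart = r
            if b <= q + ln:
                bend = r
                break
            q += ln
        else:  # D
            r += ln
    if bstart is None:
        bstart = r
    if bend is None:
        bend = r
    return bstart, bend


def _clip_cigar(cigar: Cigar, a: int, b: int) -> tuple[int, Cigar]:
    """Restrict a query-to-reference cigar to query interval [a, b).

    Returns the reference offset of the clipped alignment start and the
    clipped cigar.
    """
    q = r = 0
    out: Cigar = []
    rstart = None
    for op, ln in cigar:
        cq = ln if op in ("M", "I") else 0
        cr = ln if op in ("M", "D") else 0
        if cq:
            lo, hi = max(q, a), min(q + cq, b)
            if lo < hi:
                if rstart is None:
                    rstart = r + (lo - q if op == "M" else 0)
                out.append((op, hi - lo))
        else:  # D: keep only if inside the clipped span
            if rstart is not None and q < b:
                out.append((op, ln))
        q += cq
        r += cr
        if q >= b:
            break
    while out and out[-1][0] == "D":
        out.pop()
    return (rstart if rstart is not None else r), _merge(out)


def compose_cigars(a: Cigar, b: Cigar) -> Cigar:
    """Compose read->strain (``a``) with strain->backbone (``b``).

    ``b`` must cover exactly the strain interval that ``a`` aligns to.
    """
    out: Cigar = []
    bi = 0
    bop, bln = (b[0] if b else ("M", 0))

    def take_b(need_strain: int):
        nonlocal bi, bop, bln
        taken: Cigar = []
        while need_strain > 0:
            while bln == 0:
                bi += 1
                bop, bln = b[bi]
            if bop == "D":  # consumes backbone only; emit as-is
                taken.append(("D", bln))
                bln = 0
                continue
            t = min(bln, need_strain)
            taken.append((bop, t))
            bln -= t
            need_strain -= t
        return taken

    for op, ln in a:
        if op == "I":
            out.append(("I", ln))
            continue
        for bop2, bln2 in take_b(ln):
            if bop2 == "D":
                out.append(("D", bln2))
            elif bop2 == "I":
                # strain-inserted bases: read aligns to them, absent from
                # backbone -> insertion in read-vs-backbone
                out.append(("I" if op == "M" else "P", bln2))
            else:  # M
                out.append(("D" if op == "D" else "M", bln2))
    # leading/trailing D on backbone handled by _clip_cigar; "P" marks read
    # deletions against strain insertions: they consume nothing -> drop
    return _merge([(o, l) for o, l in out if o != "P"])


def truth_cigar(read: SimulatedRead, strain: StrainTruth) -> tuple[int, Cigar]:
    """Exact read-vs-backbone alignment (position, CIGAR) for a truth read."""
    if read.cigar is None or not read.cigar:
        raise ValueError(f"{read.read_id}: read carries no truth coordinates")
    rstart, b_clip = _clip_cigar(strain.backbone_cigar, read.src_start,
                                 read.src_end)
    return rstart, compose_cigars(read.cigar, b_clip)


def emit_truth_alignments(reads: list[SimulatedRead],
                          strains: list[StrainTruth],
                          backbone_name: str, backbone_len: int,
                          bam_path: str | Path) -> Path:
    """Write a position-sorted, indexed truth BAM against the backbone.

    One primary record per read; CIGAR composed from the planted read
    errors and the strain-vs-backbone edit script.
    """
    by_id = {st.strain_id: st for st in strains}
    recs = []
    for read in reads:
        strain = by_id[read.source_strain]
        pos, cigar = truth_cigar(read, strain)
        recs.append((pos, read, cigar))
    recs.sort(key=lambda t: (t[0], t[1].read_id))

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": backbone_name, "LN": backbone_len}]}
    bam_path = Path(bam_path)
    op_code = {"M": 0, "I": 1, "D": 2}
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
        for pos, read, cigar in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.query_sequence = read.forward_sequence
            a.flag = 16 if read.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [(op_code[o], l) for o, l in cigar]
            out.write(a)
    pysam.index(str(bam_path))
    return bam_path


# ---------------------------------------------------------------------------
# Community bundle

@dataclass
class Community:
    """A generated strain mixture plus all on-disk artifacts."""

    backbone_id: str
    strains: list[StrainTruth]
    reads: list[SimulatedRead]
    outdir: Path

    @property
    def backbone(self) -> StrainTruth:
        return self.strains[0]

    @property
    def assembly_fasta(self) -> Path:
        return self.outdir / "backbone.fasta"

    @property
    def bam(self) -> Path:
        return self.outdir / "truth.bam"

    @property
    def reads_fastq(self) -> Path:
        return self.outdir / "reads.fastq"

    @property
    def references_fasta(self) -> Path:
        return self.outdir / "strains.fasta"


def make_community(outdir: str | Path, genome_len: int = 1_000_000,
                   n_strains: int = 2, divergence: float = 0.01,
                   coverage: float | list[float] = 50.0,
                   mean_len: int = 6000, sd_len: int = 3700,
                   mean_identity: float = 0.90, indel_rate: float = 0.0,
                   seed: int = 0) -> Community:
    """Generate a community and write all standard artifacts.

    Strain 1 is the backbone itself (the collapsed consensus stand-in);
    strains 2..n each diverge from it by ``divergence`` substitutions per
    base, so the pairwise divergence between two mutated strains is about
    twice that.  Emits backbone FASTA, strain references FASTA, reads
    FASTQ, truth BAM (sorted + indexed) and TSV truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covs = ([coverage] * n_strains if isinstance(coverage, (int, float))
            else list(coverage))
    if len(covs) != n_strains:
        raise ValueError("one coverage per strain required")
    base = random_genome(genome_len, seed)
    strains = [StrainTruth("strain1", base, [], covs[0])]
    for k in range(2, n_strains + 1):
        strains.append(mutate_genome(base, divergence, indel_rate,
                                     seed=seed + k, strain_id=f"strain{k}",
                                     coverage=covs[k - 1]))
    reads = simulate_reads(strains, mean_len=mean_len, sd_len=sd_len,
                           mean_identity=mean_identity, seed=seed + 101)

    com = Community("backbone", strains, reads, outdir)
    write_fasta({"backbone": base}, com.assembly_fasta)
    write_fasta({st.strain_id: st.genome for st in strains},
                com.references_fasta)
    write_fastq([(r.read_id, r.sequence) for r in reads], com.reads_fastq)
    emit_truth_alignments(reads, strains, "backbone", genome_len, com.bam)
    with open(outdir / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\tstrain\tstart\tend\tstrand\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.source_strain}\t{r.true_start}\t"
                     f"{r.true_end}\t{r.strand}\n")
    with open(outdir / "truth_variants.tsv", "w") as fh:
        fh.write("strain\tpos\tref\talt\n")
        for st in strains[1:]:
            for p, ref, alt in st.variants:
                fh.write(f"{st.strain_id}\t{p}\t{ref}\t{alt}\n")
    return com
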