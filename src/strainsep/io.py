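"""File formats and small sequence utilities.

FASTA round-trips through :func:`read_fasta`/:func:`write_fasta`,
read-to-assembly alignments through pysam (sorted + indexed SAM/BAM), and
read-to-contig alignments for scaffolding through either PAF (minimap2
``-c``) or SAM/BAM, normalized into :class:`AlignmentRecord`.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict.

    Duplicate ids raise ``ValueError``; an empty file returns an empty dict
    with a warning.  Case is preserved.
    """
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate FASTA id: {name!r}")
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    if not seqs:
        logger.warning("%s: empty FASTA", path)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` records as FASTQ with constant quality."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Sorted/indexed BAM plumbing

def open_alignments(path: str | Path) -> pysam.AlignmentFile:
    """Open a position-sorted, indexed SAM/BAM file.

    A missing index is an error that names the fix rather than a silent
    degradation, since random access underpins every downstream stage.
    """
    af = pysam.AlignmentFile(str(path))
    try:
        af.check_index()
    except (ValueError, AttributeError) as exc:
        raise FileNotFoundError(
            f"{path} has no index; position-sort and index it first "
            f"(samtools sort {path} | samtools index -)"
        ) from exc
    return af


def read_alignments(path: str | Path, contig: str | None = None,
                    start: int | None = None, end: int | None = None):
    """Iterate primary/secondary alignment records over an optional region."""
    with open_alignments(path) as af:
        yield from af.fetch(contig=contig, start=start, end=end)


def sort_and_index(sam_path: str | Path, bam_path: str | Path) -> Path:
    """Position-sort a SAM/BAM and index the result."""
    bam_path = Path(bam_path)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


# ---------------------------------------------------------------------------
# Generic alignment record for scaffolding / evaluation

@dataclass(frozen=True)
class AlignmentRecord:
    """A base-level local alignment between a query and a target sequence.

    Coordinates are 0-based half-open and always refer to the *forward*
    strand of both sequences; ``strand`` is '-' when the reverse complement
    of the query aligns.  ``matches`` counts identical bases, ``block_len``
    the total alignment columns (including indels).
    """

    query: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    target: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    mapq: int
    primary: bool = True
    base_level: bool = True

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file (minimap2 ``-c`` output) into alignment records."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tags = dict(t.split(":", 2)[::2] for t in f[12:])
            records.append(AlignmentRecord(
                query=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
                strand=f[4],
                target=f[5], tlen=int(f[6]), tstart=int(f[7]), tend=int(f[8]),
                matches=int(f[9]), block_len=int(f[10]), mapq=int(f[11]),
                primary=tags.get("tp", "P") == "P",
                base_level="cg" in tags,
            ))
    return records


def read_sam_records(path: str | Path) -> list[AlignmentRecord]:
    """Normalize SAM/BAM records into :class:`AlignmentRecord` objects."""
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        tlens = dict(zip(af.references, af.lengths))
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            qlen = aln.infer_read_length() or aln.query_length
            # query_alignment_start/end refer to SEQ as stored; map back to
            # the original read orientation for reverse-strand records.
            qs, qe = aln.query_alignment_start, aln.query_alignment_end
            # account for hard clips
            cig = aln.cigartuples or []
            if cig and cig[0][0] == 5:
                qs += cig[0][1]
                qe += cig[0][1]
            if aln.is_reverse:
                qs, qe = qlen - qe, qlen - qs
            matches = sum(n for op, n in cig if op in (0, 7, 8))
            block = sum(n for op, n in cig if op in (0, 1, 2, 7, 8))
            records.append(AlignmentRecord(
                query=aln.query_name, qlen=qlen, qstart=qs, qend=qe,
                strand="-" if aln.is_reverse else "+",
                target=aln.reference_name, tlen=tlens[aln.reference_name],
                tstart=aln.reference_start, tend=aln.reference_end,
                matches=matches, block_len=block,
                mapq=aln.mapping_quality,
                primary=not (aln.is_secondary or aln.is_supplementary),
                base_level=aln.cigartuples is not None,
            ))
    return records


# ---------------------------------------------------------------------------
# minimap2 wrapper (external aligner; internals out of scope)

def run_minimap2(target_fa: str | Path, query_fx: str | Path,
                 out_path: str | Path, *, preset: str = "map-pb",
                 sam: bool = False, threads: int = 1) -> Path:
    """Align queries to a target with minimap2.

    Emits PAF with CIGAR (``-c``) by default, or SAM with ``sam=True``.
    Secondary alignments are suppressed: scaffolding and evaluation only
    ever use unique/primary alignments.
    """
    out_path = Path(out_path)
    cmd = ["minimap2", "-x", preset, "-t", str(threads), "--secondary=no"]
    cmd.append("-a" if sam else "-c")
    cmd += [str(target_fa), str(query_fx)]
    with open(out_path, "w") as out:
        subprocess.run(cmd, stdout=out, stderr=subprocess.DEVNULL, check=True)
    return out_path


def align_to_bam(target_fa: str | Path, query_fx: str | Path,
                 bam_path: str | Path, *, preset: str = "map-pb",
                 threads: int = 1) -> Path:
    """minimap2 + sort + index, yielding a ready-to-use BAM."""
    with tempfile.TemporaryDirectory() as tmp:
        sam = Path(tmp) / "aln.sam"
        run_minimap2(target_fa, query_fx, sam, preset=preset, sam=True,
                     threads=threads)
        return sort_and_index(sam, bam_path)
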