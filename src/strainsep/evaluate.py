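"""Assembly evaluation against known reference genomes.

Each contig/scaffold is assigned to the reference for which it aligns over
at least half of its length with the highest ``alignedBases x
averageIdentity`` score; per-reference summary metrics follow: reference
coverage (union of aligned intervals), ANI (alignment-length-weighted mean
identity, mirroring dnadiff's AvgIdentity), NG50 against the reference
length, and the duplication ratio (aligned assembly bases over distinct
covered reference bases -- about k when k strains are resolved against one
reference).

Alignments come from minimap2 (``-cx asm20``) or from ingested PAF files;
all metrics are pure functions of the normalized alignment records.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import AlignmentRecord, read_fasta, read_paf, run_minimap2

logger = logging.getLogger(__name__)


@dataclass
class ReferenceAssignment:
    contig_id: str
    reference_id: str | None
    aligned_bases: int
    average_identity: float

    @property
    def score(self) -> float:
        return self.aligned_bases * self.average_identity


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    end = None
    for s, e in sorted(intervals):
        if end is None or s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


# ---------------------------------------------------------------------------
# Assignment

def assign_to_reference(alignments: list[AlignmentRecord],
                        contig_lengths: dict[str, int],
                        min_aligned_frac: float = 0.5,
                        ) -> list[ReferenceAssignment]:
    """Assign each contig to its closest reference.

    A contig is assignable to a reference only if the union of all its
    alignment blocks against that reference covers at least
    ``min_aligned_frac`` of the contig; among those, the reference with
    the highest ``alignedBases x averageIdentity`` wins, ties broken by
    lexicographically smaller reference id.
    """
    per_pair: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for r in alignments:
        if r.primary:
            per_pair.setdefault((r.query, r.target), []).append(r)
    out = []
    for contig in sorted(contig_lengths):
        best: ReferenceAssignment | None = None
        for (q, ref), recs in per_pair.items():
            if q != contig:
                continue
            aligned = union_length([(r.qstart, r.qend) for r in recs])
            if aligned < min_aligned_frac * contig_lengths[contig]:
                continue
            blocks = sum(r.block_len for r in recs)
            ident = (sum(r.matches for r in recs) / blocks) if blocks else 0.0
            cand = ReferenceAssignment(contig, ref, aligned, ident)
            if (best is None or cand.score > best.score
                    or (cand.score == best.score
                        and ref < best.reference_id)):
                best = cand
        out.append(best if best is not None
                   else ReferenceAssignment(contig, None, 0, 0.0))
    return out


# ---------------------------------------------------------------------------
# Summary metrics

def ng50(contig_lengths: list[int], genome_size: int) -> int:
    """Largest L such that contigs of length >= L cover half the genome."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    total = 0
    for ln in sorted(contig_lengths, reverse=True):
        total += ln
        if 2 * total >= genome_size:
            return ln
    logger.warning("assembly covers less than half the genome; NG50 = 0")
    return 0


def duplication_ratio(alignments: list[AlignmentRecord]) -> float | None:
    """Aligned assembly bases (with multiplicity) over distinct covered
    reference bases; ``None`` when nothing aligns."""
    numer = sum(r.qend - r.qstart for r in alignments)
    denom = union_length([(r.tstart, r.tend) for r in alignments])
    if denom == 0:
        logger.warning("duplication ratio undefined: no reference covered")
        return None
    return numer / denom


def reference_metrics(assignments: list[ReferenceAssignment],
                      alignments: list[AlignmentRecord],
                      reference_lengths: dict[str, int],
                      contig_lengths: dict[str, int]) -> pd.DataFrame:
    """Per-reference evaluation table.

    Only alignments between a contig and the reference it was *assigned*
    to contribute.  Columns: coverage %, ANI %, duplication ratio, NG50,
    assigned contig count, and the fraction of total assembly bases that
    did not align anywhere.
    """
    assigned_ref = {a.contig_id: a.reference_id for a in assignments}
    per_ref: dict[str, list[AlignmentRecord]] = {r: [] for r in reference_lengths}
    for rec in alignments:
        if rec.primary and assigned_ref.get(rec.query) == rec.target:
            per_ref[rec.target].append(rec)

    total_bases = sum(contig_lengths.values())
    aligned_q = {}
    for rec in alignments:
        if rec.primary:
            aligned_q.setdefault(rec.query, []).append((rec.qstart, rec.qend))
    unaligned_frac = (1.0 - sum(union_length(iv) for iv in aligned_q.values())
                      / total_bases) if total_bases else 0.0

    rows = []
    for ref in sorted(reference_lengths):
        recs = per_ref[ref]
        rlen = reference_lengths[ref]
        cov = union_length([(r.tstart, r.tend) for r in recs]) / rlen * 100.0
        blocks = sum(r.block_len for r in recs)
        ani = (sum(r.matches for r in recs) / blocks * 100.0) if blocks else 0.0
        contigs = sorted({a.contig_id for a in assignments
                          if a.reference_id == ref})
        lens = [contig_lengths[c] for c in contigs]
        rows.append({
            "reference": ref,
            "coverage_pct": cov,
            "ani_pct": ani,
            "duplication_ratio": duplication_ratio(recs),
            "ng50": ng50(lens, rlen) if lens else 0,
            "assigned_contigs": len(contigs),
            "unaligned_assembly_frac": unaligned_frac,
        })
    return pd.DataFrame(rows).set_index("reference")


# ---------------------------------------------------------------------------
# Driver

def evaluate_assembly(assembly_fasta: str | Path, references_fasta: str | Path,
                      paf: str | Path | None = None,
                      preset: str = "asm20") -> pd.DataFrame:
    """Align an assembly to references (or ingest a PAF) and summarize."""
    contigs = read_fasta(assembly_fasta)
    refs = read_fasta(references_fasta)
    contig_lengths = {k: len(v) for k, v in contigs.items()}
    ref_lengths = {k: len(v) for k, v in refs.items()}
    if not refs:
        logger.warning("no references: all contigs unassigned")
        return pd.DataFrame()
    if paf is None:
        with tempfile.TemporaryDirectory() as tmp:
            out = Path(tmp) / "eval.paf"
            run_minimap2(references_fasta, assembly_fasta, out, preset=preset)
            alignments = read_paf(out)
    else:
        alignments = read_paf(paf)
    assignments = assign_to_reference(alignments, contig_lengths)
    return reference_metrics(assignments, alignments, ref_lengths,
                             contig_lengths)
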