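"""Iterative separation: the outer loop of the pipeline.

Each round phases the current assembly, separates reads, assembles both
haplotypes of every retained phaseset, and scaffolds the result; reads are
then re-aligned to the scaffolds and a tentative re-phasing yields the
mean *Hamming rate* (per read: mismatching shared SNV positions over total
shared positions, minimum over the two haplotypes, counted only for reads
overlapping a phased region by >= 3 kbp).  Another round runs only while
that global mean improves by at least 1% relative to the previous round,
it is applied only to sequences whose local mean improves by the same
rule, and at most ``max_strains - 1`` rounds ever run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import assembly as asm
from . import phasing as ph
from . import scaffold as sg
from .config import PipelineConfig
from .io import (align_to_bam, open_alignments, read_fasta, read_paf,
                 run_minimap2, write_fasta)

logger = logging.getLogger(__name__)


@dataclass
class HammingRecord:
    """Hamming rate of one read against one phaseset's haplotypes."""

    read_id: str
    sequence_id: str
    shared_sites: int
    mismatches: tuple[int, int]      # vs h1, vs h2

    @property
    def rate(self) -> float:
        return min(self.mismatches) / self.shared_sites


@dataclass
class IterationState:
    iteration_index: int = 0
    max_strains: int = 5
    previous_global_rate: float | None = None
    per_sequence_rates: dict[str, float | None] = field(default_factory=dict)


def hamming_rate(alleles: np.ndarray, local_idx: np.ndarray,
                 haplotypes: tuple[np.ndarray, np.ndarray], overlap_bp: int,
                 read_id: str = "", sequence_id: str = "",
                 min_overlap: int = 3000) -> HammingRecord | None:
    """Hamming record for one read, or ``None`` when excluded.

    Excluded when the read overlaps the phased region by less than
    ``min_overlap`` bp or shares no SNV position with the haplotypes.
    """
    if overlap_bp < min_overlap or len(local_idx) == 0:
        return None
    h1, h2 = haplotypes
    d1 = int(np.sum(alleles != h1[local_idx]))
    d2 = int(np.sum(alleles != h2[local_idx]))
    return HammingRecord(read_id, sequence_id, len(local_idx), (d1, d2))


def phasing_hamming_records(mat: ph.ReadSNVMatrix,
                            phasesets: list[ph.Phaseset],
                            min_overlap: int = 3000) -> list[HammingRecord]:
    """All included (read, phaseset) Hamming records on one sequence."""
    out = []
    for ps in phasesets:
        pos_to_local = {int(p): k for k, p in enumerate(ps.snv_positions)}
        site_local = np.array(
            [pos_to_local.get(int(p), -1) for p in mat.positions])
        for rid in mat.reads_overlapping(ps.s, ps.e):
            a, b = mat.read_spans[rid]
            overlap = min(b, ps.e + 1) - max(a, ps.s)
            ent = mat.entries.get(rid)
            if ent is None:
                continue
            idx, alleles = ent
            loc = site_local[idx]
            m = loc >= 0
            rec = hamming_rate(alleles[m], loc[m], ps.haplotypes, overlap,
                               read_id=rid, sequence_id=mat.contig,
                               min_overlap=min_overlap)
            if rec is not None:
                out.append(rec)
    return out


def should_iterate(previous: float | None, current: float,
                   improvement_frac: float = 0.01) -> bool:
    """True on the first round, or when the mean Hamming rate improved by
    at least ``improvement_frac`` relative to the previous round."""
    if previous is None:
        return True
    return current <= previous * (1.0 - improvement_frac)


def select_sequences(previous: dict[str, float | None],
                     current: dict[str, float],
                     improvement_frac: float = 0.01) -> set[str]:
    """Sequences whose local mean Hamming rate improved by >= 1% relative;
    sequences without a previous rate (newly created) are eligible."""
    return {sid for sid, rate in current.items()
            if should_iterate(previous.get(sid), rate, improvement_frac)}


# ---------------------------------------------------------------------------
# Pipeline driver

@dataclass
class PipelineResult:
    final_fasta: Path
    iterations_run: int
    global_rates: list[float]
    outdir: Path


def _extract_reads_fastq(bam: Path, fastq: Path) -> int:
    """Pull primary read sequences out of a BAM for re-alignment."""
    n = 0
    with pysam.AlignmentFile(str(bam)) as af, open(fastq, "w") as out:
        for aln in af.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence
            if not seq:
                continue
            out.write(f"@{aln.query_name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def _phase_assembly(seqs: dict[str, str], bam: Path, cfg: PipelineConfig):
    """Tentative phasing of every sequence of the current assembly.

    Returns per-sequence (matrix, phasesets, hamming records).
    """
    result = {}
    with pysam.AlignmentFile(str(bam)) as af:
        present = set(af.references)
        for sid in sorted(seqs):
            if sid not in present:
                result[sid] = (None, [], [])
                continue
            sites = ph.detect_snvs(af, sid, seqs[sid],
                                   min_depth=cfg.min_snv_depth,
                                   min_alt_frac=cfg.min_alt_frac,
                                   min_per_allele=cfg.min_per_allele)
            mat = ph.build_matrix(af, sid, sites)
            blocks = ph.phase_diploid(mat, seed=cfg.seed)
            phasesets = ph.extract_phasesets(blocks, min_dens=cfg.min_dens)
            records = phasing_hamming_records(
                mat, phasesets, min_overlap=cfg.hamming_min_overlap)
            result[sid] = (mat, phasesets, records)
    return result


def _mean_rate(records: list[HammingRecord]) -> float | None:
    return (sum(r.rate for r in records) / len(records)) if records else None


def _separate_and_scaffold(seqs: dict[str, str], bam: Path,
                           phased: dict, selected: set[str],
                           reads_fastq: Path, itdir: Path,
                           cfg: PipelineConfig):
    """One separation round: haplotype assembly + strain-aware scaffolding.

    Returns (scaffold sequences, provenance: scaffold -> origin sequence
    ids).
    """
    backbones = []
    hap_contigs: dict[str, list[asm.StrainAwareContig]] = {}
    tag_rows: list[tuple[str, str, int, str]] = []
    with pysam.AlignmentFile(str(bam)) as af:
        for sid in sorted(seqs):
            mat, phasesets, _ = phased[sid]
            use = phasesets if sid in selected else []
            bb = asm.BackboneContig(sid, seqs[sid], use)
            backbones.append(bb)
            if not use:
                continue
            separations = {k: ph.separate_reads(psx, mat)
                           for k, psx in enumerate(bb.phasesets)}
            for k, psx in enumerate(bb.phasesets):
                h1_reads, h2_reads, _ = separations[k]
                tag_rows += [(r, sid, psx.s, "h1") for r in sorted(h1_reads)]
                tag_rows += [(r, sid, psx.s, "h2") for r in sorted(h2_reads)]
            hap_contigs[sid] = asm.assemble_backbone(bb, separations, af, cfg)
    ph.write_phased_vcf(
        [psx for sid in sorted(seqs)
         for psx in (phased[sid][1] if sid in selected else [])],
        {sid: phased[sid][0].sites for sid in seqs
         if phased[sid][0] is not None},
        itdir / "phased.vcf")
    with open(itdir / "haplotags.tsv", "w") as fh:
        fh.write("#read_id\tsequence\tphaseset_start\thaplotype\n")
        for row in tag_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    contigs = asm.build_contig_set(backbones, hap_contigs,
                                   min_unphased_len=cfg.min_unphased_len)
    contig_seqs = {c.id: c.sequence for c in contigs}
    contigs_fa = itdir / "contigs.fasta"
    write_fasta(contig_seqs, contigs_fa)

    # read-to-contig dovetails via the external aligner
    paf = itdir / "reads_vs_contigs.paf"
    run_minimap2(contigs_fa, reads_fastq, paf, preset=cfg.aligner_preset,
                 threads=cfg.threads)
    dovetails = sg.filter_dovetails(
        read_paf(paf), min_mapq=cfg.min_mapq,
        max_overhang_bp=cfg.max_overhang_bp,
        max_overhang_frac=cfg.max_overhang_frac)
    backbone_lengths = {sid: len(s) for sid, s in seqs.items()}
    graph = sg.build_graph(dovetails, contigs, backbone_lengths,
                           extremity_window=cfg.extremity_window)
    sg.remove_transitive_edges(graph)
    sg.remove_weak_edges(graph, min_reads=cfg.weak_edge_min_reads,
                         frac=cfg.weak_edge_frac)
    scaffolds = sg.traverse_paths(graph)
    sg.write_gfa(graph, contig_seqs, itdir / "graph.gfa")
    sg.write_agp(scaffolds, contig_seqs, itdir / "scaffolds.agp")

    by_id = {c.id: c for c in contigs}
    scaffold_seqs = {}
    provenance = {}
    for sc in scaffolds:
        scaffold_seqs[sc.name] = sc.sequence(contig_seqs)
        provenance[sc.name] = {by_id[cid].origin_contig
                               for cid, _ in sc.parts}
    write_fasta(scaffold_seqs, itdir / "scaffolds.fasta")
    return scaffold_seqs, provenance


def run_pipeline(assembly_fasta: str | Path, bam: str | Path,
                 outdir: str | Path,
                 cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run up to ``max_strains - 1`` separation rounds and emit the final
    strain-aware assembly, per-iteration artifacts, and a summary TSV."""
    cfg = cfg or PipelineConfig()
    if cfg.max_strains < 2:
        raise ValueError("max_strains must be >= 2")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.write(outdir / "config.txt")
    log_path = outdir / "strainsep.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("strainsep")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(Path(assembly_fasta), Path(bam), outdir, cfg)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(assembly_fasta: Path, bam: Path, outdir: Path,
         cfg: PipelineConfig) -> PipelineResult:
    open_alignments(bam).close()   # fail fast on unsorted/unindexed input
    seqs = read_fasta(assembly_fasta)
    reads_fastq = outdir / "reads.fastq"
    n_reads = _extract_reads_fastq(bam, reads_fastq)
    logger.info("input: %d sequences, %d reads", len(seqs), n_reads)

    state = IterationState(max_strains=cfg.max_strains)
    cur_seqs, cur_bam = seqs, bam
    provenance = {sid: {sid} for sid in seqs}
    final_fasta = outdir / "assembly.strainsep.fasta"
    global_rates: list[float] = []
    rows = []

    while state.iteration_index < cfg.max_strains - 1:
        it = state.iteration_index + 1
        phased = _phase_assembly(cur_seqs, cur_bam, cfg)
        all_records = [r for _, _, recs in phased.values() for r in recs]
        cur_global = _mean_rate(all_records)
        cur_local = {sid: _mean_rate(recs)
                     for sid, (_, _, recs) in phased.items()}
        logger.info("iteration %d: mean Hamming rate %s", it,
                    f"{cur_global:.4f}" if cur_global is not None else "n/a")

        n_phasesets = sum(len(p) for _, p, _ in phased.values())
        if n_phasesets == 0:
            logger.info("no retained phasesets; output equals input")
            break
        if state.iteration_index > 0 and not should_iterate(
                state.previous_global_rate, cur_global or 0.0,
                cfg.improvement_frac):
            logger.info("global Hamming rate no longer improves; stopping")
            break
        if state.iteration_index == 0:
            selected = {sid for sid, (_, p, _) in phased.items() if p}
        else:
            selected = select_sequences(
                state.per_sequence_rates,
                {sid: r for sid, r in cur_local.items() if r is not None},
                cfg.improvement_frac)
            selected &= {sid for sid, (_, p, _) in phased.items() if p}
        if not selected:
            logger.info("no sequence improves locally; stopping")
            break

        itdir = outdir / f"iteration_{it}"
        itdir.mkdir(exist_ok=True)
        new_seqs, new_prov = _separate_and_scaffold(
            cur_seqs, cur_bam, phased, selected, reads_fastq, itdir, cfg)
        rows.append({"iteration": it, "sequences": len(new_seqs),
                     "separated": len(selected),
                     "mean_hamming_rate": cur_global,
                     "total_bases": sum(len(s) for s in new_seqs.values())})

        # inherit previous per-sequence rates through provenance
        inherited: dict[str, float | None] = {}
        for sid, origins in new_prov.items():
            vals = [cur_local[o] for o in origins
                    if cur_local.get(o) is not None]
            inherited[sid] = (sum(vals) / len(vals)) if vals else None
        state.per_sequence_rates = inherited
        state.previous_global_rate = cur_global
        if cur_global is not None:
            global_rates.append(cur_global)
        state.iteration_index += 1

        cur_seqs = new_seqs
        provenance = {sid: set().union(*(provenance[o] for o in origins))
                      for sid, origins in new_prov.items()}
        if state.iteration_index < cfg.max_strains - 1:
            cur_bam = align_to_bam(itdir / "scaffolds.fasta", reads_fastq,
                                   itdir / "reads_vs_scaffolds.bam",
                                   preset=cfg.aligner_preset,
                                   threads=cfg.threads)

    write_fasta(cur_seqs, final_fasta)
    pd.DataFrame(rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    logger.info("done: %d iteration(s), final assembly %s",
                state.iteration_index, final_fasta)
    return PipelineResult(final_fasta, state.iteration_index, global_rates,
                          outdir)
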