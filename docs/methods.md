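# Methods

This note documents the models, parameters, and numerical choices behind
`strainsep`, and what the synthetic tests do and do not establish.

## Problem setting and model

A "strain" is treated as a bacterial haplotype: a contiguous nucleotide
sequence jointly observed by sequencing reads. The input is a
strain-oblivious assembly — conspecific strains collapsed onto consensus
contigs — plus position-sorted long-read alignments. Since long-read
variant callers handle ploidy 2 far better than higher ploidy, separation
is performed as an *iterated diploid* split: each round bipartitions reads
into two haplotypes per region; `n` strains require up to `n − 1` rounds.

## SNV detection

A pileup column is called a biallelic SNV when:

| parameter | default | role |
|---|---|---|
| `min_snv_depth` | 10 | minimum column depth |
| `min_alt_frac` | 0.2 | alternate allele fraction of depth |
| `min_per_allele` | 5 | absolute read support for *each* allele |

The backbone base must be one of the two most frequent bases and becomes
the REF allele; the most frequent other base becomes ALT. The per-allele
floor of 5 guards against error pileups: at ~10% read error, each wrong
base appears in ~2–3% of reads, so low-count alternates are noise. Only
substitutions are considered; indel variants are ignored. These thresholds
are stand-ins for a long-read caller's internal defaults and are exposed
in `PipelineConfig` (including per-iteration override by re-running with a
different config).

## Phasing

Phase blocks split wherever no single read carries both of two consecutive
SNVs. Within a block the two haplotypes are complementary allele vectors
(the diploid assumption), and the objective is the MEC count: the minimal
number of allele flips making every read consistent with one haplotype.

The heuristic is greedy seed-and-extend: the read covering the most sites
seeds haplotype 1; remaining reads are committed strictly in order of
decreasing overlap with already-phased sites (a priority queue re-keyed on
every commit — processing a read whose overlap is stale caused long-range
switch errors in an earlier design), each to the closer haplotype by
Hamming distance, updating per-site weighted votes. Two majority-vote
refinement sweeps follow. Ties (equal distance, or no covered phased site)
leave a read untagged. The procedure is fully deterministic — all ties
break on lexicographic read id — so the `seed` argument exists only for
interface symmetry.

Blocks with a single SNV are not emitted as phasesets: one site cannot
anchor an interval, and the phaseset formalism (`[s, e]` spanning first to
last phased SNV) presumes at least two. Phasesets with `dens < 0.1%` are
discarded, which deliberately leaves strains of > 99.9% identity
unseparated and suppresses false-positive-driven splits.

## Haplotype assembly

Separated reads are assembled by a coordinate-anchored column-wise
consensus over their existing backbone alignments, restricted to the
phaseset interval: per column the majority base wins; a deletion wins when
> 50% of covering reads delete; an insertion (the most frequent inserted
sequence) is emitted when > 50% of reads covering the junction carry one.
The consensus splits wherever fewer than `min_consensus_depth = 3`
separated reads cover a column — below 3, majority vote is meaningless.
Because the consensus is anchored to `[s, e]`, the assemble-then-trim
sequence of the external-assembler path collapses into one step
internally. An external assembler can be substituted via a command
template (for wtdbg2, flags suited to short, low-coverage phasesets are
`-e 5 -l 1000 -L 3000 -S 1 -R`); its contigs are trimmed back to `[s, e]` by aligning them to
the backbone window `[s − 10 kbp, e + 10 kbp]` (contigs originate locally,
so a genome-wide search is unnecessary) and keeping the collinear chain
projecting inside the interval; contigs aligning for < 50% of their length
are dropped. Unphased backbone stretches are retained only when strictly
longer than 500 bp.

## Scaffolding

The scaffolding graph is bi-directed: each edge endpoint records which
contig end (prefix/suffix) participates, constraining traversal (enter
through one end, leave through the other). Edges require a read with one
dovetail at its prefix and one at its suffix, on different contigs, and
one of four admission rules: consecutive contigs on a backbone; adjacent
haplotype contigs; a read-linked unphased/haplotype pair; or two contigs
both mapping within `extremity_window = 1 kbp` of a backbone end (no
canonical window size exists for "at the extremity"; 1 kbp is a
configurable choice on the scale of read lengths).

Numerical and semantic choices:

- The 90% weak-edge rule compares an edge's support against the total of
  *all* edges exiting a vertex side, including itself; prefix- and
  suffix-side pools are independent. This removes both edges of a 55/45
  split — the literal reading of the rule.
- Gap length is the *lower* median of the per-read distance samples
  (read bases strictly between the two dovetail alignments; negative when
  they overlap on the read); gaps are integer base counts, so no
  interpolation. Non-positive medians give a direct join.
- Cycles have no linear traversal; they are broken at the
  minimum-weight edge (conservative: preserves the strongest links).
- Transitive-edge removal is evaluated against the original edge set, so
  it is independent of edge iteration order.
- Scaffold orientation is canonicalized (lexicographically smallest
  part list of the two traversal directions) for byte-reproducibility.

## Iteration control

After scaffolding, reads are re-aligned to the scaffolds (minimap2, one
thread; alignment is always delegated, never reimplemented)
and tentatively re-phased. For every read overlapping a phaseset by
≥ 3 kbp, the Hamming rate is the mismatch fraction over shared SNV sites,
minimized over the two haplotypes. Another round runs only if the global
mean rate improves by ≥ 1% *relative* to the previous round's value
(current ≤ 0.99 × previous; an absolute reading would make the rule
scale-dependent), and only on sequences improving locally by the same
rule; new sequences without a predecessor are eligible by convention.
The round-1 baseline is the tentative phasing of the input assembly.
Previous-rate inheritance across rounds follows scaffold provenance (mean
of origin-sequence rates). Default `max_strains = 5`, a practical
ceiling for iterated diploid splitting.

## Synthetic communities

The generator emulates simulated conspecific mock communities: 2–5
conspecific strains, pairwise divergence 0.1–3%, per-strain coverage
5–80×, PacBio-like reads with gamma-distributed lengths (mean 6 kbp, SD
3.7 kbp, minimum 500 bp) and per-read identity ~ Normal(90%, 3%) truncated
at 97% — the same length/identity profile as a Badread simulation with
`--identity 90,97,3 --length 6100,3700`. Errors are injected at 60/20/20
substitution/insertion/deletion, a deliberate simplification: downstream
behaviour depends on SNV density and read span, not the exact error
process. Indel-skewed (Nanopore-like) profiles can be explored via the
error-split parameters rather than guessed defaults.

The backbone handed to the pipeline is strain 1's exact genome — the
ideal collapsed consensus. Strain genomes carry explicit edit scripts
against it and reads carry edit scripts against their strain, so truth
alignments have exact, composed CIGARs. **Consequently a green synthetic
test establishes the separation machinery works given a faithful
backbone; it says nothing about errors inherited from a real
strain-oblivious assembler**, which is precisely where low-coverage
degradation appears in practice (see the acceptance suite: at 10× per
strain this pipeline recovers ~98% of each strain because the backbone is
perfect, whereas a full real-data stack also inherits assembler
degradation at 10×). Chimeric
reads, base-quality models, and recombination simulation are out of
scope; recombination ladders can be run on user-supplied genome pairs.

Acceptance scenarios run at 200–300 kbp genomes instead of 1 Mbp to fit a
single-CPU runtime budget; divergence, coverage, and read parameters are
unchanged.

## Known limitations

- Exactly two haplotypes per round: regions with ≥ 3 equally abundant
  strains need multiple rounds and may fragment at round boundaries.
- The internal consensus assembler cannot reconstruct sequence absent
  from the backbone (large strain-specific insertions); the external
  assembler hook exists for that case.
- Uneven strain abundance below the SNV-calling thresholds (alt fraction
  < 0.2 or < 5 reads) leaves the minor strain unseparated.
- Evaluation identity is minimap2-based; numbers can differ in the last
  decimal from MUMmer/dnadiff-derived values. A PAF ingestion path allows
  reproducing externally computed alignments exactly.
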