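"""Pipeline configuration.

All tunable thresholds of the pipeline live here with their defaults.  A
resolved config is serialized (flat ``key=value``) into every output
directory so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    """Tunable parameters of the strain-separation pipeline.

    Attributes
    ----------
    min_snv_depth:
        Minimum read depth for a pileup column to be considered for SNV
        calling.
    min_alt_frac:
        Minimum fraction of reads carrying the alternate allele.
    min_per_allele:
        Minimum absolute read count required for *each* of the two alleles;
        guards against long-read error pileups.
    min_dens:
        Phasesets whose SNV density (percent of positions in ``[s, e]`` that
        are phased SNVs) is strictly below this value are discarded.
    min_unphased_len:
        Unphased backbone subsequences are retained only if strictly longer
        than this many bp.
    min_consensus_depth:
        Haplotype consensus is split wherever fewer than this many separated
        reads cover a column.
    min_mapq:
        Dovetail candidates must have mapping quality strictly greater than
        this.
    max_overhang_bp, max_overhang_frac:
        A dovetail may leave at most ``min(max_overhang_bp,
        max_overhang_frac * match_len)`` unaligned bases at the joined
        extremities.
    weak_edge_min_reads:
        Scaffolding edges supported by fewer reads are removed.
    weak_edge_frac:
        An edge is also removed when its support is below this fraction of
        the total support of all edges exiting the same vertex side.
    extremity_window:
        A contig counts as mapping "on the extremity" of a backbone contig
        when its origin interval starts/ends within this many bp of the
        backbone's ends (scaffolding admission rule for inter-backbone
        joins).
    hamming_min_overlap:
        Reads must overlap a phased region by at least this many bp to enter
        the Hamming-rate average.
    improvement_frac:
        Another separation round runs only if the global mean Hamming rate
        improved by at least this relative fraction.
    max_strains:
        Maximal number of conspecific strains to resolve; the pipeline
        performs ``max_strains - 1`` separation rounds at most.
    """

    min_snv_depth: int = 10
    min_alt_frac: float = 0.2
    min_per_allele: int = 5
    min_dens: float = 0.1
    min_unphased_len: int = 500
    min_consensus_depth: int = 3
    min_mapq: int = 40
    max_overhang_bp: int = 50
    max_overhang_frac: float = 0.10
    weak_edge_min_reads: int = 10
    weak_edge_frac: float = 0.9
    extremity_window: int = 1000
    hamming_min_overlap: int = 3000
    improvement_frac: float = 0.01
    max_strains: int = 5
    seed: int = 0
    threads: int = 1
    aligner: str = "minimap2"
    aligner_preset: str = "map-pb"
    external_phaser: str | None = None
    external_assembler: str | None = None

    def write(self, path: str | Path) -> None:
        """Serialize as flat ``key=value`` lines."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}={'' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key=value`` file written by :meth:`write`."""
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key!r}")
            default = types[key].default
            if raw == "":
                kwargs[key] = None
            elif isinstance(default, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(raw)
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
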