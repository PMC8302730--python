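"""Shared fixtures: tiny synthetic communities and in-memory BAM builders."""

from pathlib import Path

import pysam
import pytest

from strainsep.simulate import make_community


def write_bam(path: Path, references: dict[str, str],
              alignments: list[dict]) -> Path:
    """Build a small position-sorted, indexed BAM from plain dicts.

    Each alignment dict: name, ref, pos, seq, cigar (string), and optional
    flag / mapq.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": k, "LN": len(v)} for k, v in references.items()],
    }
    ref_ids = {k: i for i, k in enumerate(references)}
    sam = Path(str(path) + ".unsorted.bam")
    with pysam.AlignmentFile(str(sam), "wb", header=header) as out:
        for rec in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["name"]
            a.reference_id = ref_ids[rec["ref"]]
            a.reference_start = rec["pos"]
            a.query_sequence = rec["seq"]
            a.cigarstring = rec.get("cigar", f"{len(rec['seq'])}M")
            a.mapping_quality = rec.get("mapq", 60)
            a.flag = rec.get("flag", 0)
            out.write(a)
    pysam.sort("-o", str(path), str(sam))
    pysam.index(str(path))
    sam.unlink()
    return Path(path)


@pytest.fixture(scope="session")
def small_community(tmp_path_factory):
    """50 kbp two-strain community at 1% divergence, 40x per strain."""
    outdir = tmp_path_factory.mktemp("com_small")
    return make_community(outdir, genome_len=50_000, n_strains=2,
                          divergence=0.01, coverage=40.0, seed=11)


@pytest.fixture()
def bam_builder(tmp_path):
    def _build(references, alignments, name="test.bam"):
        return write_bam(tmp_path / name, references, alignments)
    return _build
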