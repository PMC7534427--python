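from pathlib import Path

import pysam
import pytest

from splicetime.design import Sample, SampleSheet


def write_bam(path, reads, chrom="chr1", chrom_len=100_000):
    """Write a coordinate-sorted, indexed BAM from (name, pos, cigar, mapq)
    tuples; an optional 5th element is the SAM flag."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": chrom_len}],
        }
    )
    segs = []
    for read in reads:
        name, pos, cigar, mapq = read[:4]
        flag = read[4] if len(read) > 4 else 0
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.reference_id = 0
        seg.reference_start = pos
        seg.cigarstring = cigar
        seg.mapping_quality = mapq
        seg.flag = flag
        seg.query_sequence = "A" * sum(
            ln for op, ln in seg.cigartuples if op in (0, 1, 4, 7, 8)
        )
        segs.append(seg)
    segs.sort(key=lambda s: s.reference_start)
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for seg in segs:
            bam.write(seg)
    pysam.index(str(path))
    return path


@pytest.fixture
def bam_factory(tmp_path):
    counter = {"n": 0}

    def factory(reads, **kwargs):
        counter["n"] += 1
        return write_bam(tmp_path / f"fixture{counter['n']}.bam", reads, **kwargs)

    return factory


def two_by_two_sheet():
    """Two timepoints (one per phase extreme), two replicates each."""
    return SampleSheet(
        [
            Sample("TP2R1", 2.0, "1", "LightG1"),
            Sample("TP2R2", 2.0, "2", "LightG1"),
            Sample("TP20R1", 20.0, "1", "DarkG1"),
            Sample("TP20R2", 20.0, "2", "DarkG1"),
        ]
    )


@pytest.fixture
def sheet22():
    return two_by_two_sheet()
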