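"""Naive per-read brute-force classifiers used as independent oracles.

These re-derive every evidence count by explicit position arithmetic over
the CIGAR string, independently of the package's counting code.
"""

from __future__ import annotations

import pysam


def read_segments_and_gaps(read: pysam.AlignedSegment):
    """Explicit enumeration: list of per-segment reference position lists
    (M/=/X runs, insertions ignored, D and N break segments) and the list of
    N-gap intervals."""
    segments: list[list[int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    current: list[int] = []
    for op, ln in read.cigartuples or []:
        if op in (0, 7, 8):
            current.extend(range(pos, pos + ln))
            pos += ln
        elif op == 3:
            if current:
                segments.append(current)
                current = []
            gaps.append((pos, pos + ln))
            pos += ln
        elif op == 2:
            if current:
                segments.append(current)
                current = []
            pos += ln
    if current:
        segments.append(current)
    return segments, gaps


def naive_intron_counts(bam_path, intron, min_mapq=10, min_anchor=10):
    """Classify every read by brute force against one intron."""
    sj = ie5 = ie3 = intron_reads = 0
    depth = 0
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.mapping_quality < min_mapq
            ):
                continue
            segments, gaps = read_segments_and_gaps(read)
            if (intron.start, intron.end) in gaps:
                sj += 1
            for boundary, bump in ((intron.donor_site, "ie5"), (intron.acceptor_site, "ie3")):
                wanted = set(range(boundary - min_anchor, boundary + min_anchor))
                if any(wanted <= set(seg) for seg in segments):
                    if bump == "ie5":
                        ie5 += 1
                    else:
                        ie3 += 1
            inside = sum(
                1
                for seg in segments
                for p in seg
                if intron.start <= p < intron.end
            )
            if inside:
                intron_reads += 1
                depth += inside
    cov = depth / (intron.end - intron.start)
    return {
        "sj": sj,
        "ie5": ie5,
        "ie3": ie3,
        "intron_reads": intron_reads,
        "intron_cov": cov,
    }


def naive_junction_counts(
    bam_path, min_overhang=8, min_mapq=0, min_len=10, max_len=3000
):
    """Per-read gap enumerator with explicit flanking-segment arithmetic."""
    counts: dict[tuple[str, int, int], int] = {}
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.mapping_quality < min_mapq
            ):
                continue
            segments, gaps = read_segments_and_gaps(read)
            for gs, ge in gaps:
                if not (min_len <= ge - gs <= max_len):
                    continue
                left = [seg for seg in segments if seg and seg[-1] == gs - 1]
                right = [seg for seg in segments if seg and seg[0] == ge]
                if not left or not right:
                    continue
                if len(left[0]) >= min_overhang and len(right[0]) >= min_overhang:
                    key = (read.reference_name, gs, ge)
                    counts[key] = counts.get(key, 0) + 1
    return counts
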