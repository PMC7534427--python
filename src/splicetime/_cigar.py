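"""CIGAR walking shared by the intron-retention and junction extraction code.

Aligned blocks are maximal runs of reference-consuming match operations
(M/=/X); insertions do not interrupt a block, while deletions (D) and skips
(N) both end it. Gaps are the reference intervals skipped by N operations —
the spliced-out introns of a gapped alignment.
"""

from __future__ import annotations

import pysam

# CIGAR op codes
_MATCH_OPS = {0, 7, 8}  # M, =, X
_REF_SKIP = 3  # N
_DELETION = 2  # D
_REF_CONSUMING = {0, 2, 3, 7, 8}


def aligned_blocks_and_gaps(
    read: pysam.AlignedSegment,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Return (blocks, gaps) for one alignment in reference coordinates.

    blocks: 0-based half-open intervals of reference positions covered by
    match operations, with insertions absorbed.
    gaps: intervals skipped by N operations (one per splice junction).
    """
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    block_start: int | None = None
    for op, length in read.cigartuples or []:
        if op in _MATCH_OPS:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == _REF_SKIP:
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            gaps.append((pos, pos + length))
            pos += length
        elif op == _DELETION:
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
        # I/S/H/P consume no reference
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks, gaps


def passes_alignment_filters(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    """Primary, mapped, MAPQ-passing records only."""
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.mapping_quality < min_mapq
    )
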