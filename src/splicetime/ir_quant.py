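"""Intron retention quantification via the Percent Intron Retention (PIR) metric.

For each constitutive intron and sample, five pieces of read evidence are
counted from the alignments:

- #SJ   — reads whose alignment gap exactly excises the intron (spliced reads)
- #IE5  — ungapped reads crossing the exon-intron boundary at the 5' splice
          site with >= min_anchor aligned reference positions on both sides
- #IE3  — the same at the 3' splice site
- #I    — reads with at least one aligned position inside the intron
- Introncov — mean per-base aligned depth over the intron

Counts are averaged across replicates of a timepoint, a filter cascade
selects quantifiable introns, and

    PIR = (#IE5 + #IE3) / (#IE5 + #IE3 + #SJ)

is computed per intron per timepoint. An intron with enough spliced reads but
zero boundary evidence is fully spliced (PIR = 0.0); an intron with too few
spliced reads (#SJ < min_sj) cannot be quantified and is missing by default
(``insufficient_as_zero=True`` reports 0.0 instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._cigar import aligned_blocks_and_gaps, passes_alignment_filters
from .annotation import Intron
from .design import SampleSheet, format_timepoint
from .matrix import SplicingMatrix

QUANTIFIED = "quantified"
SPLICED_ONLY = "spliced_only"
INSUFFICIENT = "insufficient"


@dataclass
class IntronCounts:
    """Per-intron read evidence for one sample (or replicate-averaged)."""

    intron_id: str
    sample: str
    sj: float = 0.0
    ie5: float = 0.0
    ie3: float = 0.0
    intron_reads: float = 0.0
    intron_cov: float = 0.0

    def validate(self) -> None:
        for name in ("sj", "ie5", "ie3", "intron_reads", "intron_cov"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name} for {self.intron_id}")


@dataclass
class IntronQuant:
    intron_id: str
    timepoint: float
    counts: IntronCounts
    pir: float | None
    status: str


def _block_contains(blocks: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(bs <= start and end <= be for bs, be in blocks)


def count_intron_evidence(
    alignments: pysam.AlignmentFile,
    intron: Intron,
    min_mapq: int = 10,
    min_anchor: int = 10,
    sample: str = "",
) -> IntronCounts:
    """Classify every MAPQ-passing primary alignment near one intron.

    A read can contribute to several evidence classes (e.g. a long boundary
    read covers both an IE site and intron body positions) but a read spliced
    at this intron cannot also be boundary evidence there, because a gap at
    the boundary disqualifies the anchor check.
    """
    if intron.chrom not in alignments.references:
        raise ValueError(f"chromosome {intron.chrom!r} absent from alignment header")
    counts = IntronCounts(intron_id=intron.intron_id, sample=sample)
    depth = 0.0
    fetch_start = max(0, intron.start - 1)
    ilen = intron.length
    for read in alignments.fetch(intron.chrom, fetch_start, intron.end + 1):
        if not passes_alignment_filters(read, min_mapq):
            continue
        blocks, gaps = aligned_blocks_and_gaps(read)
        if (intron.start, intron.end) in gaps:
            counts.sj += 1
        # boundary evidence: one gapless block spanning min_anchor on each side
        d = intron.donor_site
        a = intron.acceptor_site
        if _block_contains(blocks, d - min_anchor, d + min_anchor):
            counts.ie5 += 1
        if _block_contains(blocks, a - min_anchor, a + min_anchor):
            counts.ie3 += 1
        overlap = sum(
            max(0, min(be, intron.end) - max(bs, intron.start)) for bs, be in blocks
        )
        if overlap > 0:
            counts.intron_reads += 1
            depth += overlap
    counts.intron_cov = depth / ilen if ilen else 0.0
    return counts


def count_sample(
    bam_path,
    introns: list[Intron],
    min_mapq: int = 10,
    min_anchor: int = 10,
    sample: str | None = None,
) -> dict[str, IntronCounts]:
    """Evidence counts for all introns in one coordinate-sorted, indexed BAM."""
    bam_path = Path(bam_path)
    name = sample if sample is not None else bam_path.stem
    with pysam.AlignmentFile(str(bam_path)) as af:
        if not af.has_index():
            raise ValueError(f"{bam_path} has no index")
        return {
            i.intron_id: count_intron_evidence(af, i, min_mapq, min_anchor, name)
            for i in introns
        }


def average_replicates(
    counts_by_sample: dict[str, dict[str, IntronCounts]],
    sheet: SampleSheet,
) -> dict[float, dict[str, IntronCounts]]:
    """Arithmetic mean of every count field across replicates of a timepoint."""
    out: dict[float, dict[str, IntronCounts]] = {}
    for tp in sheet.timepoints:
        reps = [s.sample_id for s in sheet.samples_at(tp)]
        missing = [r for r in reps if r not in counts_by_sample]
        if missing:
            raise ValueError(f"timepoint {tp}: no counts for sample(s) {missing}")
        label = format_timepoint(tp)
        per_intron: dict[str, IntronCounts] = {}
        intron_ids = counts_by_sample[reps[0]].keys()
        for iid in intron_ids:
            fields = {}
            for f in ("sj", "ie5", "ie3", "intron_reads", "intron_cov"):
                fields[f] = float(
                    np.mean([getattr(counts_by_sample[r][iid], f) for r in reps])
                )
            per_intron[iid] = IntronCounts(intron_id=iid, sample=label, **fields)
        out[tp] = per_intron
    return out


def compute_pir(
    counts: IntronCounts,
    timepoint: float = float("nan"),
    min_sj: float = 5,
    min_ie: float = 2,
    min_cov: float = 1.0,
    min_intron_reads: float = 5,
    insufficient_as_zero: bool = False,
) -> IntronQuant:
    """Apply the filter cascade to replicate-averaged counts and compute PIR."""
    counts.validate()
    boundary = counts.ie5 + counts.ie3
    if (
        counts.sj >= min_sj
        and counts.ie5 >= min_ie
        and counts.ie3 >= min_ie
        and counts.intron_cov >= min_cov
        and counts.intron_reads >= min_intron_reads
    ):
        pir = boundary / (boundary + counts.sj)
        return IntronQuant(counts.intron_id, timepoint, counts, pir, QUANTIFIED)
    if counts.sj >= min_sj and boundary == 0:
        return IntronQuant(counts.intron_id, timepoint, counts, 0.0, SPLICED_ONLY)
    pir = 0.0 if insufficient_as_zero else None
    return IntronQuant(counts.intron_id, timepoint, counts, pir, INSUFFICIENT)


def quantify(
    averaged: dict[float, dict[str, IntronCounts]],
    min_sj: float = 5,
    min_ie: float = 2,
    min_cov: float = 1.0,
    min_intron_reads: float = 5,
    insufficient_as_zero: bool = False,
) -> list[IntronQuant]:
    return [
        compute_pir(
            c,
            timepoint=tp,
            min_sj=min_sj,
            min_ie=min_ie,
            min_cov=min_cov,
            min_intron_reads=min_intron_reads,
            insufficient_as_zero=insufficient_as_zero,
        )
        for tp, per_intron in averaged.items()
        for c in per_intron.values()
    ]


def build_pir_matrix(
    quants: list[IntronQuant],
    sheet: SampleSheet,
    min_pir: float = 0.05,
    pseudo: float = 0.001,
) -> SplicingMatrix:
    """Introns-by-timepoints PIR matrix.

    Rows are kept only if PIR >= min_pir at one or more timepoints. Cells from
    insufficient-coverage introns stay missing (NA); the pseudo-count is
    added to every remaining value.
    """
    labels = sheet.timepoint_labels
    cells: dict[str, dict[str, float]] = {}
    for q in quants:
        cells.setdefault(q.intron_id, {})[format_timepoint(q.timepoint)] = (
            math.nan if q.pir is None else q.pir
        )
    rows = {}
    for iid, by_tp in cells.items():
        vals = [by_tp.get(lbl, math.nan) for lbl in labels]
        finite = [v for v in vals if not math.isnan(v)]
        if finite and max(finite) >= min_pir:
            rows[iid] = [v if math.isnan(v) else v + pseudo for v in vals]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels, dtype=float)
    df = df.sort_index()
    return SplicingMatrix(values=df, metric="PIR", pseudo=pseudo)


def counts_to_frame(counts_by_sample: dict[str, dict[str, IntronCounts]]) -> pd.DataFrame:
    rows = [
        {
            "intron_id": c.intron_id,
            "sample": c.sample,
            "sj": c.sj,
            "ie5": c.ie5,
            "ie3": c.ie3,
            "intron_reads": c.intron_reads,
            "intron_cov": c.intron_cov,
        }
        for per_intron in counts_by_sample.values()
        for c in per_intron.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["intron_id", "sample", "sj", "ie5", "ie3", "intron_reads", "intron_cov"],
    )
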