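"""Splice-junction extraction, local event grouping and PSI quantification.

A junction is the reference interval skipped by the N operation of a spliced
alignment. Junctions observed across samples are noise-filtered (replicate
concordance, minimum read support, repeat exclusion), then grouped into local
splicing events: junctions of one gene sharing a start coordinate form one
event, junctions sharing an end coordinate form another, mirroring local
splicing variations anchored at a common exon boundary. Within an event the
Percent Spliced In of junction j in a sample is the read proportion

    PSI_j = n_j / sum_k n_k

over the event's junctions. The junction with the highest mean PSI across
samples is the canonical form; all others are alternates and become rows of
the PSI matrix.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._cigar import aligned_blocks_and_gaps, passes_alignment_filters
from .annotation import GeneModel, RepeatIntervals
from .design import SampleSheet, format_timepoint
from .matrix import SplicingMatrix

logger = logging.getLogger(__name__)

JunctionKey = tuple[str, int, int]  # (chrom, start, end), 0-based half-open


@dataclass
class Junction:
    chrom: str
    start: int
    end: int
    strand: str | None = None
    counts: dict[str, int] = field(default_factory=dict)  # sample -> reads

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def max_count(self) -> int:
        return max(self.counts.values(), default=0)


@dataclass
class SplicingEvent:
    """Junctions sharing one boundary, with per-sample counts and PSI."""

    event_id: str
    gene_id: str
    strand: str
    anchor: int
    anchor_side: str  # "start" | "end": which genomic coordinate is shared
    junctions: list[JunctionKey]
    counts: dict[JunctionKey, dict[str, int]]
    psi: dict[str, dict[JunctionKey, float]] = field(default_factory=dict)
    canonical: JunctionKey | None = None

    @property
    def alternates(self) -> list[JunctionKey]:
        return [j for j in self.junctions if j != self.canonical]

    def mean_psi(self, junction: JunctionKey) -> float:
        vals = [by_j[junction] for by_j in self.psi.values() if junction in by_j]
        return float(np.mean(vals)) if vals else math.nan

    def max_psi(self, junction: JunctionKey) -> float:
        vals = [by_j[junction] for by_j in self.psi.values() if junction in by_j]
        return max(vals, default=math.nan)

    def max_count(self, junction: JunctionKey) -> int:
        return max(self.counts[junction].values(), default=0)


def extract_junctions(
    bam_path,
    min_overhang: int = 8,
    min_mapq: int = 0,
    min_intron_len: int = 10,
    max_intron_len: int = 3000,
) -> Counter[JunctionKey]:
    """Count gap-supported junctions in one alignment file.

    A gap contributes one count when both flanking aligned blocks span at
    least ``min_overhang`` reference positions and the gap length lies within
    the allowed intron-length range.
    """
    counts: Counter[JunctionKey] = Counter()
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af.fetch(until_eof=True):
            if not passes_alignment_filters(read, min_mapq):
                continue
            blocks, gaps = aligned_blocks_and_gaps(read)
            for gap in gaps:
                glen = gap[1] - gap[0]
                if not (min_intron_len <= glen <= max_intron_len):
                    continue
                left = next((b for b in blocks if b[1] == gap[0]), None)
                right = next((b for b in blocks if b[0] == gap[1]), None)
                if left is None or right is None:
                    continue  # gap adjacent to a deletion, not anchored
                if left[1] - left[0] >= min_overhang and right[1] - right[0] >= min_overhang:
                    counts[(read.reference_name, gap[0], gap[1])] += 1
    return counts


def collect_junctions(
    bam_by_sample: dict[str, object], **extract_kwargs
) -> dict[JunctionKey, Junction]:
    """Extract junction counts per sample and merge into Junction records."""
    junctions: dict[JunctionKey, Junction] = {}
    for sample, path in bam_by_sample.items():
        for key, n in extract_junctions(path, **extract_kwargs).items():
            j = junctions.setdefault(key, Junction(*key))
            j.counts[sample] = n
    return junctions


def filter_junctions(
    junctions: dict[JunctionKey, Junction],
    sheet: SampleSheet,
    repeats: RepeatIntervals | None = None,
    min_reads: int = 2,
) -> dict[JunctionKey, Junction]:
    """Noise filters: replicate concordance, read support, repeat exclusion.

    A junction survives iff (a) every replicate of at least one timepoint
    observed it, (b) some sample supports it with >= min_reads reads, and
    (c) neither terminal intronic base lies inside a repeat interval.
    """
    kept: dict[JunctionKey, Junction] = {}
    for key, j in junctions.items():
        concordant = any(
            all(j.counts.get(s.sample_id, 0) >= 1 for s in sheet.samples_at(tp))
            for tp in sheet.timepoints
        )
        if not concordant:
            continue
        if j.max_count() < min_reads:
            continue
        if repeats is not None and (
            repeats.contains_point(j.chrom, j.start)
            or repeats.contains_point(j.chrom, j.end - 1)
        ):
            continue
        kept[key] = j
    return kept


def _gene_for(junction: Junction, genes: list[GeneModel]) -> GeneModel | None:
    # smallest containing gene wins when genes overlap
    hits = [
        g
        for g in genes
        if g.chrom == junction.chrom and g.start <= junction.start and junction.end <= g.end
    ]
    if not hits:
        return None
    return min(hits, key=lambda g: g.end - g.start)


def group_events(
    junctions: dict[JunctionKey, Junction], genes: list[GeneModel]
) -> list[SplicingEvent]:
    """Group a gene's junctions sharing a start or an end coordinate.

    A junction can belong to two events (one per shared end); single-junction
    groups are not events. Junctions contained in no gene are dropped.
    """
    by_gene: dict[str, list[Junction]] = {}
    gene_of: dict[str, GeneModel] = {}
    dropped = 0
    for j in junctions.values():
        g = _gene_for(j, genes)
        if g is None:
            dropped += 1
            continue
        by_gene.setdefault(g.gene_id, []).append(j)
        gene_of[g.gene_id] = g
    if dropped:
        logger.info("%d junction(s) not assignable to any gene were dropped", dropped)

    events: list[SplicingEvent] = []
    for gene_id, js in sorted(by_gene.items()):
        g = gene_of[gene_id]
        for side, coord_of in (("start", lambda j: j.start), ("end", lambda j: j.end)):
            groups: dict[int, list[Junction]] = {}
            for j in js:
                groups.setdefault(coord_of(j), []).append(j)
            for anchor, members in sorted(groups.items()):
                if len(members) < 2:
                    continue
                members = sorted(members, key=lambda j: (j.start, j.end))
                tag = "S" if side == "start" else "E"
                events.append(
                    SplicingEvent(
                        event_id=f"{gene_id}:{tag}{anchor}",
                        gene_id=gene_id,
                        strand=g.strand,
                        anchor=anchor,
                        anchor_side=side,
                        junctions=[j.key for j in members],
                        counts={j.key: dict(j.counts) for j in members},
                    )
                )
    return events


def compute_psi(event: SplicingEvent, sample: str) -> dict[JunctionKey, float] | None:
    """Read-proportion PSI per junction for one sample; None when no reads."""
    totals = {j: event.counts[j].get(sample, 0) for j in event.junctions}
    total = sum(totals.values())
    if total == 0:
        return None
    return {j: n / total for j, n in totals.items()}


def compute_all_psi(event: SplicingEvent, samples: list[str]) -> SplicingEvent:
    event.psi = {}
    for s in samples:
        psi = compute_psi(event, s)
        if psi is not None:
            event.psi[s] = psi
    return event


def annotate_roles(event: SplicingEvent) -> SplicingEvent:
    """Canonical = highest mean PSI; ties go to the lower start coordinate."""
    if not event.psi:
        raise ValueError(f"event {event.event_id} has no PSI values")
    event.canonical = min(
        event.junctions, key=lambda j: (-event.mean_psi(j), j[1], j[2])
    )
    return event


def filter_events(
    events: list[SplicingEvent],
    min_alt_psi: float = 0.05,
    min_alt_reads: int = 2,
) -> list[SplicingEvent]:
    """Keep events whose alternates carry real signal.

    Some alternate junction must reach PSI > min_alt_psi in a sample, and
    some alternate junction must be supported by >= min_alt_reads reads in a
    sample.
    """
    kept = []
    for ev in events:
        alts = ev.alternates
        if not alts:
            continue
        psi_ok = any(
            not math.isnan(ev.max_psi(a)) and ev.max_psi(a) > min_alt_psi for a in alts
        )
        reads_ok = any(ev.max_count(a) >= min_alt_reads for a in alts)
        if psi_ok and reads_ok:
            kept.append(ev)
    return kept


def junction_row_label(event: SplicingEvent, junction: JunctionKey) -> str:
    chrom, s, e = junction
    return f"{event.event_id}|{chrom}:{s}-{e}"


def build_psi_matrix(
    events: list[SplicingEvent],
    sheet: SampleSheet,
    pseudo: float = 0.0001,
) -> SplicingMatrix:
    """Alternate junctions x timepoints; a cell is the mean PSI over the
    timepoint's replicates with data, and missing cells become the
    pseudo-count."""
    labels = sheet.timepoint_labels
    rows: dict[str, list[float]] = {}
    for ev in events:
        for alt in ev.alternates:
            vals = []
            for tp in sheet.timepoints:
                reps = [
                    ev.psi[s.sample_id][alt]
                    for s in sheet.samples_at(tp)
                    if s.sample_id in ev.psi
                ]
                vals.append(float(np.mean(reps)) if reps else pseudo)
            rows[junction_row_label(ev, alt)] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels, dtype=float)
    df = df.sort_index()
    return SplicingMatrix(values=df, metric="PSI", pseudo=pseudo)


def junctions_to_frame(junctions: dict[JunctionKey, Junction]) -> pd.DataFrame:
    rows = [
        {"chrom": j.chrom, "start": j.start, "end": j.end, "sample": s, "count": n}
        for j in junctions.values()
        for s, n in sorted(j.counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "count"])


def events_to_frame(events: list[SplicingEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        for j in ev.junctions:
            rows.append(
                {
                    "event_id": ev.event_id,
                    "gene_id": ev.gene_id,
                    "anchor_side": ev.anchor_side,
                    "chrom": j[0],
                    "start": j[1],
                    "end": j[2],
                    "role": "canonical" if j == ev.canonical else "alternate",
                    "mean_psi": ev.mean_psi(j),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "anchor_side",
            "chrom",
            "start",
            "end",
            "role",
            "mean_psi",
        ],
    )
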