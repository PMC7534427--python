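"""Synthetic diurnal time-course fixtures: genome, annotation and alignments.

The generator emulates a synchronized diurnal RNA-seq experiment: a panel of
timepoints spanning the Light G1 / S-M / Dark G1 phases (including the
half-hour points around the S-M transition), two biological replicates per
timepoint, and genes whose splicing follows a known trajectory:

- ``ir`` genes: two exons and one constitutive intron; a fraction r(t) of
  fragments at timepoint t derive from the intron-retaining pre-mRNA, the
  rest from the spliced mRNA.
- ``es`` genes: three exons; the alternate isoform skips the middle exon,
  creating a shared-donor event of two junctions with canonical usage p(t).
- ``alt`` genes: three exons; the alternate isoform uses an acceptor shifted
  ``alt_shift`` nt into the middle exon (frame-preserving when the shift is
  a multiple of 3).

Reads are single-end, placed uniformly along the chosen isoform, with gaps
exactly at intron boundaries; a configurable fraction of decoy reads carries
MAPQ 0 to exercise the mapping-quality filter. Truth tables record both the
design trajectory and the analytic expectation of the observed PIR/PSI under
uniform read placement, so estimates can be checked against closed-form
values rather than against the raw trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .design import Sample, SampleSheet, default_phase, format_timepoint

# the 28-point diurnal sampling grid: hourly through G1, half-hourly around
# the S-M transition
DIURNAL_TIMEPOINTS: tuple[float, ...] = tuple(
    [float(t) for t in range(1, 12)]
    + [11.5, 12.0, 12.5, 13.0, 13.5, 14.0, 14.5, 15.0]
    + [float(t) for t in range(16, 25)]
)

_BASES = np.array(list("ACGT"))
# cyclic codon with no stop in any frame of either strand
_STOP_FREE_UNIT = "GCT"


@dataclass
class SimDesign:
    """Parameters of one synthetic experiment; defaults mirror the studied
    diurnal design (28 timepoints, 2 replicates, 100 nt reads)."""

    n_genes: int = 10
    gene_kinds: tuple[str, ...] = ("ir", "es", "ir", "alt")  # cycled over genes
    exon_len: tuple[int, int] = (300, 500)
    intron_len: tuple[int, int] = (80, 300)
    timepoints: tuple[float, ...] = DIURNAL_TIMEPOINTS
    replicates: int = 2
    read_length: int = 100
    reads_per_gene: int = 200
    decoy_low_mapq_fraction: float = 0.1
    alt_shifts: tuple[int, ...] = (45, 44)  # cycled over alt genes
    n_repeats: int = 2
    repeat_on_first_junction: bool = False
    stop_free_skipped_exon: bool = False
    trajectory_overrides: dict[int, dict[float, float]] = field(default_factory=dict)
    seed: int = 42

    def validate(self) -> None:
        if self.exon_len[0] < self.read_length:
            raise ValueError("minimum exon length must be >= read length")
        if not (10 <= self.intron_len[0] <= self.intron_len[1] <= 3000):
            raise ValueError("intron length range must lie within [10, 3000]")
        if self.replicates < 1 or self.reads_per_gene < 1:
            raise ValueError("replicates and depth must be >= 1")
        for kind in self.gene_kinds:
            if kind not in ("ir", "es", "alt"):
                raise ValueError(f"unknown gene kind {kind!r}")

    def sample_sheet(self) -> SampleSheet:
        samples = [
            Sample(
                sample_id=f"{format_timepoint(tp)}R{rep}",
                timepoint=tp,
                replicate=str(rep),
                phase=default_phase(tp),
            )
            for tp in self.timepoints
            for rep in range(1, self.replicates + 1)
        ]
        return SampleSheet(samples)


@dataclass
class SimGene:
    gene_id: str
    kind: str  # ir | es | alt
    strand: str
    archetype: str
    exons: list[tuple[int, int]]
    alt_shift: int | None
    trajectory: dict[float, float]  # tp -> r(t) for ir, canonical p(t) otherwise

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    # isoform block lists in genomic order -------------------------------
    def canonical_blocks(self) -> list[tuple[int, int]]:
        return list(self.exons)

    def alternate_blocks(self) -> list[tuple[int, int]]:
        if self.kind == "ir":
            return [self.span]  # unspliced pre-mRNA
        if self.kind == "es":
            return [self.exons[0], self.exons[2]]
        s2, e2 = self.exons[1]
        return [self.exons[0], (s2 + self.alt_shift, e2), self.exons[2]]

    def event_junctions(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(canonical, alternate) junction intervals of the tracked event."""
        j1 = self.introns[0]
        if self.kind == "ir":
            return j1, j1
        if self.kind == "es":
            return j1, (self.exons[0][1], self.exons[2][0])
        return j1, (self.exons[0][1], self.exons[1][0] + self.alt_shift)


@dataclass
class SimGenome:
    chrom: str
    sequence: str
    genes: list[SimGene]
    repeats: list[tuple[int, int]]
    fasta: Path
    gff3: Path
    bed: Path
    design_tsv: Path


# ---------------------------------------------------------------------------
# analytic expectations under uniform read placement


def expected_pir(
    r: float,
    retained_len: int,
    spliced_len: int,
    read_len: int,
    anchor: int = 10,
) -> float:
    """Expected observed PIR for retention fraction r.

    Boundary reads require >= anchor aligned bases on each side of a splice
    site (read_len - 2*anchor + 1 eligible starts per boundary on the
    retained isoform); spliced-junction reads need >= 1 base on each side
    (read_len - 1 starts on the spliced isoform).
    """
    ie = r * max(0, read_len - 2 * anchor + 1) / (retained_len - read_len + 1)
    sj = (1 - r) * (read_len - 1) / (spliced_len - read_len + 1)
    if 2 * ie + sj == 0:
        return 1.0 if r > 0 else 0.0
    return 2 * ie / (2 * ie + sj)


def expected_psi(
    p: float,
    canonical_iso_len: int,
    alternate_iso_len: int,
    read_len: int,
    overhang: int = 8,
) -> float:
    """Expected observed PSI of the canonical junction for canonical usage p."""
    starts = max(0, read_len - 2 * overhang + 1)
    c = p * starts / (canonical_iso_len - read_len + 1)
    a = (1 - p) * starts / (alternate_iso_len - read_len + 1)
    if c + a == 0:
        return float("nan")
    return c / (c + a)


def _blocks_len(blocks: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in blocks)


# ---------------------------------------------------------------------------
# trajectories

_IR_ARCHETYPES = ("dark_high", "flat")
_PSI_ARCHETYPES = ("light_high", "flat")


def _archetype_value(kind: str, archetype: str, tp: float) -> float:
    dark = default_phase(tp) == "DarkG1"
    if kind == "ir":
        if archetype == "dark_high":
            return 0.7 if dark else 0.1
        return 0.3
    # canonical-junction usage for es/alt genes
    if archetype == "light_high":
        return 0.3 if dark else 0.9
    return 0.6


# ---------------------------------------------------------------------------
# genome generation


def plan_genes(design: SimDesign) -> tuple[list[SimGene], int]:
    """Lay out gene structures deterministically from the design seed."""
    design.validate()
    rng = np.random.default_rng([design.seed, 1])
    genes: list[SimGene] = []
    pos = 100  # leading margin
    ir_i = psi_i = alt_i = 0
    for g in range(design.n_genes):
        kind = design.gene_kinds[g % len(design.gene_kinds)]
        n_exons = 2 if kind == "ir" else 3
        exons = []
        for e in range(n_exons):
            elen = int(rng.integers(design.exon_len[0], design.exon_len[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if e < n_exons - 1:
                ilen = int(rng.integers(design.intron_len[0], design.intron_len[1] + 1))
                pos += ilen
        if kind == "ir":
            archetype = _IR_ARCHETYPES[ir_i % 2]
            ir_i += 1
        else:
            archetype = _PSI_ARCHETYPES[psi_i % 2]
            psi_i += 1
        shift = None
        if kind == "alt":
            shift = design.alt_shifts[alt_i % len(design.alt_shifts)]
            alt_i += 1
        traj = design.trajectory_overrides.get(
            g, {tp: _archetype_value(kind, archetype, tp) for tp in design.timepoints}
        )
        genes.append(
            SimGene(
                gene_id=f"gene{g + 1}",
                kind=kind,
                strand="+" if g % 2 == 0 else "-",
                archetype=archetype,
                exons=exons,
                alt_shift=shift,
                trajectory=dict(traj),
            )
        )
        pos += 200  # intergenic gap
    return genes, pos + 100


def make_genome(design: SimDesign, out_dir) -> SimGenome:
    """Write FASTA, GFF3, repeat BED and the sample sheet for one design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes, chrom_len = plan_genes(design)
    rng = np.random.default_rng([design.seed, 2])
    seq = rng.choice(_BASES, size=chrom_len)
    if design.stop_free_skipped_exon:
        for g in genes:
            if g.kind in ("es", "alt"):
                s, e = g.exons[1]
                unit = _STOP_FREE_UNIT * ((e - s) // 3 + 1)
                seq[s:e] = list(unit[: e - s])
    sequence = "".join(seq)
    chrom = "chr1"

    fasta = out_dir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, chrom_len, 60):
            fh.write(sequence[i : i + 60] + "\n")
    pysam.faidx(str(fasta))

    gff3 = out_dir / "genes.gff3"
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{chrom}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{chrom}\tsim\tmRNA\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{k};Parent={mrna}\n"
                )

    # repeats in intergenic gaps (or deliberately on a junction boundary)
    repeats: list[tuple[int, int]] = []
    for i in range(min(design.n_repeats, len(genes) - 1)):
        gap_start = genes[i].span[1]
        gap_end = genes[i + 1].span[0]
        mid = (gap_start + gap_end) // 2
        repeats.append((mid - 20, mid + 20))
    if design.repeat_on_first_junction and genes:
        j = genes[0].introns[0]
        repeats.append((j[0] - 5, j[0] + 5))
    bed = out_dir / "repeats.bed"
    with open(bed, "w") as fh:
        for s, e in repeats:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    design_tsv = out_dir / "samples.tsv"
    design.sample_sheet().to_tsv(design_tsv)

    return SimGenome(
        chrom=chrom,
        sequence=sequence,
        genes=genes,
        repeats=repeats,
        fasta=fasta,
        gff3=gff3,
        bed=bed,
        design_tsv=design_tsv,
    )


# ---------------------------------------------------------------------------
# read simulation


def _read_blocks(
    isoform: list[tuple[int, int]], start: int, read_len: int
) -> list[tuple[int, int]]:
    """Genomic blocks covered by a read at transcript offset ``start``."""
    out: list[tuple[int, int]] = []
    remaining, offset = read_len, start
    for bs, be in isoform:
        blen = be - bs
        if offset >= blen:
            offset -= blen
            continue
        take = min(blen - offset, remaining)
        out.append((bs + offset, bs + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past isoform end")
    return out


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    blocks: list[tuple[int, int]],
    sequence: str,
    mapq: int,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_id = 0
    seg.reference_start = blocks[0][0]
    seg.mapping_quality = mapq
    seg.flag = 0
    cigar = []
    for i, (s, e) in enumerate(blocks):
        if i:
            cigar.append((3, s - blocks[i - 1][1]))  # N
        cigar.append((0, e - s))  # M
    seg.cigartuples = cigar
    seg.query_sequence = "".join(sequence[s:e] for s, e in blocks)
    return seg


def simulate_reads(
    design: SimDesign, genome: SimGenome, out_dir
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write one coordinate-sorted, indexed BAM per sample plus truth tables.

    Returns (sample_id -> BAM path, truth DataFrame). The truth table holds,
    per gene and timepoint, the design trajectory value and the analytic
    expectation of the observed metric under uniform placement.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = design.sample_sheet()
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": genome.chrom, "LN": len(genome.sequence)}],
        }
    )
    R = design.read_length
    bam_paths: dict[str, Path] = {}
    truth_rows = []
    for si, sample in enumerate(sheet.samples):
        rng = np.random.default_rng([design.seed, 3, si])
        segs: list[pysam.AlignedSegment] = []
        for g in genome.genes:
            value = g.trajectory[sample.timepoint]
            canonical = g.canonical_blocks()
            alternate = g.alternate_blocks()
            # for ir genes the trajectory is retention (alternate-isoform)
            # probability; for es/alt genes it is canonical usage
            p_canonical = (1 - value) if g.kind == "ir" else value
            n = design.reads_per_gene
            n_decoy = int(round(design.decoy_low_mapq_fraction * n))
            for i in range(n + n_decoy):
                iso = canonical if rng.random() < p_canonical else alternate
                iso_len = _blocks_len(iso)
                s = int(rng.integers(0, iso_len - R + 1))
                blocks = _read_blocks(iso, s, R)
                mapq = 0 if i >= n else 60
                segs.append(
                    _make_segment(
                        header,
                        f"{g.gene_id}:{sample.sample_id}:{i}",
                        blocks,
                        genome.sequence,
                        mapq,
                    )
                )
        segs.sort(key=lambda seg: seg.reference_start)
        path = out_dir / f"{sample.sample_id}.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for seg in segs:
                bam.write(seg)
        pysam.index(str(path))
        bam_paths[sample.sample_id] = path

    for g in genome.genes:
        can_len = _blocks_len(g.canonical_blocks())
        alt_len = _blocks_len(g.alternate_blocks())
        for tp in design.timepoints:
            value = g.trajectory[tp]
            if g.kind == "ir":
                expected = expected_pir(value, alt_len, can_len, R)
                metric = "PIR"
            else:
                expected = expected_psi(value, can_len, alt_len, R)
                metric = "PSI"
            truth_rows.append(
                {
                    "gene_id": g.gene_id,
                    "kind": g.kind,
                    "metric": metric,
                    "timepoint": tp,
                    "truth": value,
                    "expected_observed": expected,
                    "reads_per_sample": design.reads_per_gene,
                }
            )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return bam_paths, truth


def simulate(design: SimDesign, out_dir) -> tuple[SimGenome, dict[str, Path], pd.DataFrame]:
    """Full fixture: genome + annotation + repeats + per-sample alignments."""
    genome = make_genome(design, out_dir)
    bams, truth = simulate_reads(design, genome, out_dir)
    return genome, bams, truth
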