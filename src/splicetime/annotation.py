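"""Gene models from GFF3: merged exons, constitutive introns, repeat intervals.

Constitutive introns are the gaps between a gene's merged exons — regions that
are intronic in every annotated transcript of the gene (as opposed to
exitrons, which lie inside annotated exons and are out of scope here). Exons
from all transcripts of a gene are pooled and merged before the gaps are
derived, so a region exonic in any isoform is never called an intron.

Internal coordinates are 0-based half-open throughout. GFF3 input is 1-based
inclusive and converted at load time; BED input is already 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Intron:
    """One constitutive intron with strand-aware splice-site boundaries.

    ``index`` numbers introns 1..n in transcription order (reversed genomic
    order on the minus strand). The donor (5') site is the lower boundary on
    '+' genes and the upper boundary on '-' genes.
    """

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    index: int
    overlaps_other_exon: bool = False

    @property
    def donor_site(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_site(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    merged_exons: list[tuple[int, int]]
    constitutive_introns: list[Intron] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.merged_exons[0][0]

    @property
    def end(self) -> int:
        return self.merged_exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def merge_exons(exon_intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping (and touching) intervals into a sorted disjoint set.

    Touching intervals are merged so that no zero-length intron can arise.
    """
    if not exon_intervals:
        raise AnnotationError("cannot merge an empty exon list")
    for s, e in exon_intervals:
        if s >= e:
            raise AnnotationError(f"degenerate exon interval ({s}, {e})")
    merged: list[list[int]] = []
    for s, e in sorted(exon_intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def derive_introns(gene: GeneModel) -> list[Intron]:
    """Gaps between consecutive merged exons, numbered in transcription order."""
    gaps = [
        (left[1], right[0])
        for left, right in zip(gene.merged_exons, gene.merged_exons[1:])
    ]
    order = range(len(gaps), 0, -1) if gene.strand == "-" else range(1, len(gaps) + 1)
    return [
        Intron(
            intron_id=f"{gene.gene_id}:{idx}",
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            start=s,
            end=e,
            strand=gene.strand,
            index=idx,
        )
        for (s, e), idx in zip(gaps, order)
    ]


def _flag_overlapping_introns(genes: list[GeneModel]) -> None:
    # introns of one gene may overlap another (overlapping) gene's exons;
    # such introns are kept but flagged so downstream users can exclude them
    exon_trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = exon_trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.merged_exons:
            tree.addi(s, e, g.gene_id)
    for g in genes:
        tree = exon_trees.get(g.chrom)
        if tree is None:
            continue
        flagged = []
        for intron in g.constitutive_introns:
            hit = any(
                iv.data != g.gene_id for iv in tree.overlap(intron.start, intron.end)
            )
            flagged.append(replace(intron, overlaps_other_exon=hit) if hit else intron)
        g.constitutive_introns = flagged


def load_annotation(gff3_path) -> list[GeneModel]:
    """Parse a GFF3 file into one GeneModel per gene carrying >= 1 exon.

    Exons from all transcripts of a gene are pooled before merging. Exons
    whose parentage cannot be traced to a gene feature are skipped with a
    logged count.
    """
    # gffutils is permissive; enforce the 9-column contract up front so a
    # malformed line fails loudly with its line number
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise AnnotationError(
                    f"malformed GFF3 line {lineno}: expected 9 tab-separated fields"
                )
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    claimed_exons = 0
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exon_ivs = [
            (ex.start - 1, ex.end)  # GFF3 1-based inclusive -> half-open
            for ex in db.children(gene.id, featuretype="exon")
        ]
        if not exon_ivs:
            continue
        claimed_exons += len(exon_ivs)
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            merged_exons=merge_exons(exon_ivs),
        )
        model.constitutive_introns = derive_introns(model)
        genes.append(model)

    total_exons = db.count_features_of_type("exon")
    orphans = total_exons - claimed_exons
    if orphans > 0:
        logger.warning(
            "%d exon feature(s) without a resolvable gene parent were skipped", orphans
        )
    _flag_overlapping_introns(genes)
    return genes


def all_introns(genes: list[GeneModel]) -> list[Intron]:
    return [i for g in genes for i in g.constitutive_introns]


def write_intron_table(genes: list[GeneModel], path) -> None:
    rows = [
        {
            "intron_id": i.intron_id,
            "chrom": i.chrom,
            "start": i.start,
            "end": i.end,
            "strand": i.strand,
            "gene_id": i.gene_id,
            "overlaps_other_exon": i.overlaps_other_exon,
        }
        for i in all_introns(genes)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "intron_id",
            "chrom",
            "start",
            "end",
            "strand",
            "gene_id",
            "overlaps_other_exon",
        ],
    ).to_csv(path, sep="\t", index=False)


class RepeatIntervals:
    """Per-chromosome interval set for repeat-region exclusion queries."""

    def __init__(self, intervals_by_chrom: dict[str, list[tuple[int, int]]] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in (intervals_by_chrom or {}).items():
            self._trees[chrom] = IntervalTree.from_tuples(
                (s, e) for s, e in ivs if s < e
            )

    @classmethod
    def from_bed(cls, bed_path) -> "RepeatIntervals":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        with open(bed_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise AnnotationError(
                        f"malformed BED line {lineno}: fewer than 3 fields"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise AnnotationError(
                        f"malformed BED line {lineno}: non-integer coordinates"
                    ) from exc
                by_chrom.setdefault(fields[0], []).append((start, end))
        return cls(by_chrom)

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def load_repeats(bed_path) -> RepeatIntervals:
    return RepeatIntervals.from_bed(bed_path)
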