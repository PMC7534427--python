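# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open. GFF3 is read as 1-based
inclusive and converted once at load time; BED is read as 0-based half-open
unchanged. This keeps every interval computation (merging, gap derivation,
block containment) free of ±1 adjustments.

## Gene models and constitutive introns

Exons from **all** transcripts of a gene are pooled and merged before
introns are derived, so a region exonic in any isoform never becomes an
intron; UTR-only exons are included deliberately, since a read retained in a
UTR intron is retention evidence like any other. Touching exons (end ==
next start) merge, so zero-length introns cannot arise. Introns are numbered
in transcription order — genomically reversed on the minus strand — and the
donor (5′) splice site is the higher genomic boundary on minus-strand genes.
When genes overlap, each gene's introns are derived independently; an intron
overlapping another gene's exon is kept but flagged
(`overlaps_other_exon`), letting downstream users exclude ambiguous loci
without losing information.

## Intron-retention quantification

Per intron and alignment file, only primary, mapped records with
MAPQ ≥ `min_mapq` (default 10) are considered. A record's CIGAR is walked
into aligned blocks (M/=/X runs; insertions absorbed, deletions and skips
break blocks) and skip gaps:

- `#SJ` requires a gap *exactly* matching the intron; near-miss gaps are
  ignored here (they are alternative-splice-site evidence, not retention
  evidence). A read with several gaps scores once per intron it excises.
- `#IE5`/`#IE3` require one gapless block containing ≥ `min_anchor`
  (default 10) reference positions on both sides of the respective splice
  site. A read spliced at the intron can never double as boundary evidence
  there, because its gap ends the block at the boundary.
- `#I` counts reads with ≥ 1 aligned position inside the intron;
  `Introncov` sums aligned overlap over all passing records (including
  boundary reads' intra-intron portions) divided by intron length.
  Paired-end mates overlapping the same base would count twice; depth is per
  aligned record, and duplicates are not removed.

Counts are averaged across replicates of a timepoint **before** filtering
(so averaged counts may be non-integer), then the cascade
`#SJ ≥ 5`, `#IE5 ≥ 2 ∧ #IE3 ≥ 2`, `Introncov ≥ 1.0 ∧ #I ≥ 5` gates
quantification, and `PIR = (#IE5+#IE3)/(#IE5+#IE3+#SJ)`. Three outcomes:

- *quantified* — all filters pass, 0 < PIR ≤ 1;
- *spliced_only* — `#SJ ≥ 5` with zero boundary reads: PIR exactly 0.0;
- *insufficient* — `#SJ < 5`, or boundary/coverage evidence present but
  below threshold: PIR is missing (`NA`). A compatibility mode
  (`insufficient_as_zero`) reports 0.0 instead; NA is the default because
  missing cells are what the clustering stage must drop.

The PIR matrix keeps introns with PIR ≥ 0.05 at ≥ 1 timepoint, leaves
insufficient cells `NA`, and adds a pseudo-count of 0.001 to every retained
value.

## Junction-level PSI

Junctions are gaps of primary alignments whose flanking aligned blocks each
span ≥ 8 reference positions (`min_overhang`), with gap length restricted to
[10, 3000] nt; MAPQ is not filtered here by default (retention counting is
the stage that needs it). Noise filters: observed in every replicate of at
least one timepoint; ≥ 2 reads in some sample; neither terminal intronic
base (start, end−1) inside a repeat interval.

Events are a deliberate simplification of graph-based local splicing
variations: within a gene, junctions sharing a start coordinate form one
event and junctions sharing an end coordinate another, so one junction can
appear in two events; single-junction groups are not events. A junction is
assigned to the smallest gene whose span contains it. PSI is the plain read
proportion within the event — not a posterior estimate — because the metric
is defined as a proportion and the matrices feed clustering, not
differential testing. The canonical junction has the highest mean PSI across
samples with data; ties break to the lower genomic start (then end) for
determinism. Event noise filters: an alternate with PSI > 0.05 in some
sample, and an alternate with ≥ 2 reads in some sample. Matrix cells are the
mean PSI over the timepoint's replicates with data; cells with no data
become the pseudo-count 0.0001 exactly.

## Event consequences

With more than one significant alternate (max PSI > 0.05) an event is
*complex* and excluded from frame analysis. Otherwise the alternate is
compared with the canonical junction: if it spans ≥ 1 whole annotated exon
the canonical does not span, the event is exon skipping (ES) and `delta_nt`
is the total skipped-exon length; otherwise `delta_nt` is the absolute
coordinate difference at the varying end, typed Alt 5′ or Alt 3′ by which
splice site varies given the strand. `delta_nt % 3 == 0` is
frame-preserving. The "inserted interval" is the genomic region present in
the shorter junction form but excised by the longer one; its sequence
(fetched from the indexed FASTA) is scanned for TAA/TAG/TGA in the three
forward and three reverse-complement frames — codons containing N never
count. A stop in all six frames flags the event as PTC-introducing
regardless of the transcript's actual frame, which is why the scan is
strand-agnostic. No NMD rule (e.g. the 50-nt rule) is applied.

Phase occurrence uses the standard partition — timepoints ≤ 10 Light G1,
11–15 S-M, ≥ 16 Dark G1 — and an event occurs in a phase iff its matrix
value strictly exceeds the pseudo-count at ≥ 1 timepoint of the phase
(pseudo-filled cells denote absence).

Frame classes are compared on mean PSI per alternate junction with a
two-sided Wilcoxon rank-sum test; the exact permutation null is used when
either group has ≤ 25 values (the tie-driven fallback to the normal
approximation is otherwise triggered even where enumeration is cheap), the
asymptotic form otherwise. Bonferroni correction multiplies by the number of
tests in the batch; significance is corrected p < 0.01.

## Time-course clustering

Rows with any missing cell are removed before k-means (the insufficient-PIR
cells make this the default path; a pseudo-fill mode exists for matrices
where missingness already became pseudo-counts). k-means is Lloyd's
algorithm, Euclidean distance, best of 25 random restarts by within-cluster
sum of squares, deterministic for a fixed seed (default 42). k is chosen by
the user; the elbow curve (WSS for k = 1..20 by default) is a diagnostic
only. Timepoints are then clustered from the k centroids by agglomerative
clustering (complete linkage, Euclidean — neither is canonical, these are
the package's defaults), giving the heatmap column order. Per-cluster
summaries report mean, sample SD (ddof = 1; 0 for singleton clusters),
SE = SD/√n and a normal-approximation CI (default 95%). Expression context
is the fold change of each gene's RPKM against its own across-timepoint
mean; all-zero genes are undefined and returned missing.

## The simulator

`simdata` emulates the diurnal design: default 28 timepoints (hourly, plus
half-hour points 11.5–15 around the S-M transition), two replicates, 100 nt
single-end reads, uniform fragment placement on the chosen isoform, gaps
exactly at intron boundaries, and 10% decoy reads at MAPQ 0. Gene
archetypes give IR genes either a dark-high (r = 0.1 light / 0.7 dark) or
flat (r = 0.3) retention trajectory and PSI genes a light-high
(p = 0.9/0.3) or flat (p = 0.6) canonical-usage trajectory; individual
trajectories can be overridden per gene. Exon lengths default to 300–500 nt
(≥ read length, so every junction read is anchored in single exons) and
introns to 80–300 nt.

Uniform placement yields closed-form expectations: on an isoform of length
L, a read of length R has L−R+1 equally likely starts, of which R−1 span a
junction (≥ 1 base each side), and R−2a+1 satisfy an a-base anchor on both
sides of a boundary. The truth table therefore records, besides the design
trajectory, the expected *observed* PIR/PSI (ratio of expected evidence
counts), which is what estimates converge to — observed PIR is not r itself,
because boundary and junction reads have different placement probabilities.

What the simulator does not model: sequencing errors, quality strings,
mismapping (decoys are flagged by MAPQ, not misplaced), paired-end
fragments, library-size variation between replicates, and expression
differences between genes. Passing tests therefore demonstrate the
correctness of counting, filtering and estimation logic under ideal
alignment, not robustness to aligner artifacts on real data.

## Problem sizes and numerical choices

Tests run on desk-scale fixtures: oracle-equivalence sweeps use ~500-read
alignment files; trajectory-recovery simulations use depths giving ≥ 2000
informative (junction- or boundary-spanning) reads per timepoint so the
3-standard-error band is tight; the end-to-end pipeline check uses 10 genes
× 6 timepoints × 2 replicates. These sizes are the package's validation
scale — headline counts from a full multi-million-read experiment are
functions of its data and are not asserted here.

Tie-breaks and degenerate inputs are deterministic throughout: canonical
role ties go to the lower coordinate; empty exon lists, k > rows, matrices
with missing cells, negative counts and non-nucleotide characters raise
errors rather than guessing; zero-read events yield missing PSI, never 0/0.
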