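"""Event-level consequences: type, reading frame, premature stops, phases.

Each splicing event is typed as alternative 5' splice site (Alt5),
alternative 3' splice site (Alt3), putative exon skipping (ES) or complex
(more than one significant alternate). For non-complex events the length
difference between the alternate and canonical forms (delta_nt; the skipped
exon length for ES) decides the reading-frame consequence: divisible by 3 is
frame-preserving, otherwise frame-disrupting. Sequence inserted by the
shorter junction form is scanned for stop codons in all six reading frames;
an insertion carrying a stop in every frame necessarily truncates the
protein regardless of the transcript's frame, flagging a premature
termination codon (PTC) candidate for nonsense-mediated decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .design import PHASES
from .matrix import SplicingMatrix
from .sj_quant import SplicingEvent

ALT5 = "Alt5"
ALT3 = "Alt3"
ES = "ES"
COMPLEX = "complex"
UNCLASSIFIED = "unclassified"

PRESERVING = "preserving"
DISRUPTING = "disrupting"
COMPLEX_EXCLUDED = "complex_excluded"

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class EventConsequence:
    event_id: str
    event_type: str
    delta_nt: int | None
    frame_class: str | None
    inserted_interval: tuple[str, int, int] | None
    ptc_all_six: bool | None = None


def _significant_alternates(event: SplicingEvent, min_psi: float) -> list:
    return [
        a
        for a in event.alternates
        if not math.isnan(event.max_psi(a)) and event.max_psi(a) > min_psi
    ]


def _skipped_exons(
    gene: GeneModel, alt: tuple, canon: tuple
) -> list[tuple[int, int]]:
    """Merged exons fully inside the alternate gap but not the canonical one."""
    return [
        (s, e)
        for s, e in gene.merged_exons
        if alt[1] <= s and e <= alt[2] and not (canon[1] <= s and e <= canon[2])
    ]


def classify_event(
    event: SplicingEvent,
    gene: GeneModel | None,
    min_alt_psi: float = 0.05,
) -> EventConsequence:
    """Type one event and derive its frame consequence inputs.

    delta_nt is the absolute coordinate difference at the varying end
    (total skipped-exon length for ES). The inserted interval is the genomic
    region present in the shorter junction form but excised by the longer
    one — the sequence an alternative splice-site choice adds back to the
    transcript.
    """
    if gene is None:
        return EventConsequence(event.event_id, UNCLASSIFIED, None, None, None)
    if event.canonical is None:
        raise ValueError(f"event {event.event_id} has no canonical junction")

    sig = _significant_alternates(event, min_alt_psi)
    if len(sig) > 1:
        return EventConsequence(
            event.event_id, COMPLEX, None, COMPLEX_EXCLUDED, None
        )
    alt = sig[0] if sig else max(event.alternates, key=event.mean_psi)
    canon = event.canonical

    skipped = _skipped_exons(gene, alt, canon)
    if skipped:
        delta = sum(e - s for s, e in skipped)
        interval = (gene.chrom, skipped[0][0], skipped[-1][1])
        return EventConsequence(
            event.event_id, ES, delta, frame_class(delta), interval
        )

    if event.anchor_side == "start":
        c_var, a_var = canon[2], alt[2]
        event_type = ALT3 if event.strand == "+" else ALT5
    else:
        c_var, a_var = canon[1], alt[1]
        event_type = ALT5 if event.strand == "+" else ALT3
    delta = abs(a_var - c_var)
    lo, hi = sorted((a_var, c_var))
    interval = (event.junctions[0][0], lo, hi) if delta > 0 else None
    return EventConsequence(
        event.event_id, event_type, delta, frame_class(delta), interval
    )


def classify_event_type(
    event: SplicingEvent, genes: list[GeneModel], min_alt_psi: float = 0.05
) -> str:
    by_id = {g.gene_id: g for g in genes}
    return classify_event(event, by_id.get(event.gene_id), min_alt_psi).event_type


def frame_class(delta_nt: int) -> str:
    """Frame-preserving iff the length difference is a multiple of 3."""
    return PRESERVING if delta_nt % 3 == 0 else DISRUPTING


def scan_ptc(inserted_seq: str) -> dict[str, bool]:
    """Stop-codon flags for the three forward and three reverse frames.

    Returns keys F0,F1,F2,R0,R1,R2 plus 'all_six'. Codons containing N are
    never counted as stops.
    """
    seq = inserted_seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide character(s) in sequence: {sorted(bad)}")
    rc = seq.translate(_COMPLEMENT)[::-1]
    flags: dict[str, bool] = {}
    for prefix, s in (("F", seq), ("R", rc)):
        for frame in range(3):
            flags[f"{prefix}{frame}"] = any(
                s[i : i + 3] in STOP_CODONS for i in range(frame, len(s) - 2, 3)
            )
    flags["all_six"] = all(flags[k] for k in ("F0", "F1", "F2", "R0", "R1", "R2"))
    return flags


def fetch_inserted_sequence(fasta, consequence: EventConsequence) -> str | None:
    """Genomic sequence of the inserted interval from an indexed FASTA
    (a pyfaidx.Fasta or anything with the same slicing interface)."""
    if consequence.inserted_interval is None:
        return None
    chrom, start, end = consequence.inserted_interval
    return str(fasta[chrom][start:end])


def annotate_ptc(fasta, consequence: EventConsequence) -> EventConsequence:
    seq = fetch_inserted_sequence(fasta, consequence)
    consequence.ptc_all_six = None if seq is None else scan_ptc(seq)["all_six"]
    return consequence


def phase_occurrence(
    row: pd.Series,
    phase_of_label: dict[str, str],
    presence_threshold: float,
) -> set[str]:
    """Phases in which an event occurs: value > threshold at >= 1 timepoint.

    The threshold defaults (at call sites) to the matrix pseudo-count, so
    pseudo-filled cells denote absence.
    """
    present = set()
    for label, value in row.items():
        if pd.notna(value) and value > presence_threshold:
            present.add(phase_of_label[str(label)])
    return present


def phase_occurrence_table(
    matrix: SplicingMatrix,
    phase_of_label: dict[str, str],
    presence_threshold: float | None = None,
) -> pd.DataFrame:
    """Count events per phase-combination (upset-style tabulation)."""
    thr = matrix.pseudo if presence_threshold is None else presence_threshold
    combos: dict[frozenset, int] = {}
    for _, row in matrix.values.iterrows():
        occ = frozenset(phase_occurrence(row, phase_of_label, thr))
        combos[occ] = combos.get(occ, 0) + 1
    rows = [
        {"phases": "+".join(p for p in PHASES if p in combo) or "none", "n_events": n}
        for combo, n in sorted(combos.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows, columns=["phases", "n_events"])


@dataclass
class FrameComparison:
    statistic: float
    p_value: float
    p_corrected: float
    n_tests: int
    n_preserving: int
    n_disrupting: int

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.01


def compare_psi_by_frame(
    mean_psi: list[float],
    frame_classes: list[str],
    n_tests: int = 1,
) -> FrameComparison:
    """Two-sided Wilcoxon rank-sum test of mean PSI between frame classes.

    Bonferroni correction multiplies the p-value by the number of tests run
    in the batch; significance is declared at corrected p < 0.01.
    """
    if len(mean_psi) != len(frame_classes):
        raise ValueError("mean_psi and frame_classes length mismatch")
    pres = [v for v, c in zip(mean_psi, frame_classes) if c == PRESERVING]
    disr = [v for v, c in zip(mean_psi, frame_classes) if c == DISRUPTING]
    if not pres or not disr:
        raise ValueError("both frame classes need at least one value")
    # exact permutation null for small samples (ties make method="auto" fall
    # back to the approximation even where enumeration is cheap)
    method = "exact" if min(len(pres), len(disr)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(pres, disr, alternative="two-sided", method=method)
    return FrameComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        p_corrected=float(min(1.0, res.pvalue * n_tests)),
        n_tests=n_tests,
        n_preserving=len(pres),
        n_disrupting=len(disr),
    )


def consequences_to_frame(consequences: list[EventConsequence]) -> pd.DataFrame:
    rows = [
        {
            "event_id": c.event_id,
            "event_type": c.event_type,
            "delta_nt": c.delta_nt,
            "frame_class": c.frame_class,
            "inserted_interval": (
                f"{c.inserted_interval[0]}:{c.inserted_interval[1]}-{c.inserted_interval[2]}"
                if c.inserted_interval
                else ""
            ),
            "ptc_all_six": c.ptc_all_six,
        }
        for c in consequences
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "event_type",
            "delta_nt",
            "frame_class",
            "inserted_interval",
            "ptc_all_six",
        ],
    )
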