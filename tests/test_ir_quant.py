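import math

import pysam
import pytest
from helpers_oracle import naive_intron_counts

from splicetime.annotation import Intron
from splicetime.design import Sample, SampleSheet
from splicetime.ir_quant import (
    INSUFFICIENT,
    QUANTIFIED,
    SPLICED_ONLY,
    IntronCounts,
    IntronQuant,
    average_replicates,
    build_pir_matrix,
    compute_pir,
    count_intron_evidence,
    count_sample,
    quantify,
)
from splicetime.simdata import SimDesign, simulate

INTRON = Intron("g:1", "g", "chr1", 100, 200, "+", 1)
INTRON_MINUS = Intron("g:1", "g", "chr1", 100, 200, "-", 1)


def counts_for(bam_factory, reads, intron=INTRON, **kwargs):
    path = bam_factory(reads)
    with pysam.AlignmentFile(str(path)) as af:
        return count_intron_evidence(af, intron, **kwargs)


def test_exact_gap_counts_as_spliced_junction(bam_factory):
    c = counts_for(bam_factory, [("r1", 80, "20M100N20M", 60)])
    assert (c.sj, c.ie5, c.ie3, c.intron_reads) == (1, 0, 0, 0)
    assert c.intron_cov == 0.0


def test_near_miss_gap_is_not_spliced_evidence(bam_factory):
    c = counts_for(bam_factory, [("r1", 80, "20M99N20M", 60)])
    assert c.sj == 0


def test_boundary_anchor_rule_at_donor(bam_factory):
    # (90,120) gives 10 exon + 10 intron positions at boundary 100 -> counted;
    # (92,122) gives only 8 exon positions -> not counted
    ok = counts_for(bam_factory, [("r1", 90, "30M", 60)])
    short = counts_for(bam_factory, [("r1", 92, "30M", 60)])
    assert ok.ie5 == 1 and short.ie5 == 0
    assert ok.intron_reads == 1  # 20 intra-intron positions
    assert ok.intron_cov == pytest.approx(20 / 100)


def test_acceptor_boundary_and_strand_swap(bam_factory):
    reads = [("r1", 190, "20M", 60)]  # covers 190-210, acceptor boundary 200
    plus = counts_for(bam_factory, reads, INTRON)
    minus = counts_for(bam_factory, reads, INTRON_MINUS)
    assert (plus.ie5, plus.ie3) == (0, 1)
    # on the minus strand the 200 boundary is the donor site
    assert (minus.ie5, minus.ie3) == (1, 0)


def test_mapq_secondary_and_supplementary_reads_excluded(bam_factory):
    c = counts_for(
        bam_factory,
        [
            ("low", 90, "30M", 5),
            ("sec", 90, "30M", 60, 256),
            ("sup", 90, "30M", 60, 2048),
            ("ok", 90, "30M", 60),
        ],
    )
    assert c.ie5 == 1 and c.intron_reads == 1


def test_missing_chromosome_raises(bam_factory):
    path = bam_factory([("r1", 80, "20M100N20M", 60)])
    other = Intron("x:1", "x", "chrZ", 100, 200, "+", 1)
    with pysam.AlignmentFile(str(path)) as af:
        with pytest.raises(ValueError, match="chrZ"):
            count_intron_evidence(af, other)


def test_counts_match_bruteforce_oracle_on_simulated_bams(tmp_path):
    design = SimDesign(
        n_genes=3,
        gene_kinds=("ir",),
        timepoints=(2.0, 20.0),
        reads_per_gene=120,
        seed=11,
    )
    genome, bams, _ = simulate(design, tmp_path)
    from splicetime.annotation import all_introns, load_annotation

    introns = all_introns(load_annotation(genome.gff3))
    for path in bams.values():
        got = count_sample(path, introns)
        for intron in introns:
            want = naive_intron_counts(path, intron)
            g = got[intron.intron_id]
            assert (g.sj, g.ie5, g.ie3, g.intron_reads) == (
                want["sj"],
                want["ie5"],
                want["ie3"],
                want["intron_reads"],
            )
            assert g.intron_cov == pytest.approx(want["intron_cov"])


def test_counts_are_additive_over_a_split_bam(tmp_path, bam_factory):
    import numpy as np

    rng = np.random.default_rng(5)
    reads = []
    for i in range(200):
        kind = rng.integers(3)
        if kind == 0:
            reads.append((f"s{i}", int(rng.integers(60, 100)), "40M100N40M", 60))
        elif kind == 1:
            reads.append((f"b{i}", int(rng.integers(70, 230)), "50M", 60))
        else:
            reads.append((f"d{i}", int(rng.integers(60, 240)), "30M", 60))
    half = len(reads) // 2
    whole = bam_factory(reads)
    a = bam_factory(reads[:half])
    b = bam_factory(reads[half:])
    cw = count_sample(whole, [INTRON])["g:1"]
    ca = count_sample(a, [INTRON])["g:1"]
    cb = count_sample(b, [INTRON])["g:1"]
    for f in ("sj", "ie5", "ie3", "intron_reads"):
        assert getattr(cw, f) == getattr(ca, f) + getattr(cb, f)
    assert cw.intron_cov == pytest.approx(ca.intron_cov + cb.intron_cov)


def test_average_replicates_is_arithmetic_mean():
    sheet = SampleSheet(
        [Sample("a", 1.0, "1", "LightG1"), Sample("b", 1.0, "2", "LightG1")]
    )
    counts = {
        "a": {"i": IntronCounts("i", "a", sj=4, ie5=2, ie3=2, intron_reads=3, intron_cov=1.0)},
        "b": {"i": IntronCounts("i", "b", sj=6, ie5=3, ie3=2, intron_reads=5, intron_cov=3.0)},
    }
    avg = average_replicates(counts, sheet)[1.0]["i"]
    assert (avg.sj, avg.ie5, avg.ie3, avg.intron_cov) == (5.0, 2.5, 2.0, 2.0)


def test_average_replicates_single_replicate_unchanged():
    sheet = SampleSheet([Sample("a", 1.0, "1", "LightG1")])
    counts = {"a": {"i": IntronCounts("i", "a", sj=4, ie5=1, ie3=0, intron_reads=2, intron_cov=0.5)}}
    avg = average_replicates(counts, sheet)[1.0]["i"]
    assert (avg.sj, avg.ie5, avg.ie3, avg.intron_reads, avg.intron_cov) == (4, 1, 0, 2, 0.5)


def test_average_replicates_missing_sample_errors():
    sheet = SampleSheet(
        [Sample("a", 1.0, "1", "LightG1"), Sample("b", 1.0, "2", "LightG1")]
    )
    with pytest.raises(ValueError, match="b"):
        average_replicates({"a": {}}, sheet)


class TestComputePir:
    def test_quantified_ratio(self):
        c = IntronCounts("i", "t", sj=5, ie5=2, ie3=2, intron_reads=6, intron_cov=1.5)
        q = compute_pir(c)
        assert q.status == QUANTIFIED
        assert q.pir == pytest.approx(4 / 9)

    def test_spliced_only_yields_exact_zero(self):
        c = IntronCounts("i", "t", sj=7, ie5=0, ie3=0, intron_reads=0, intron_cov=0.0)
        q = compute_pir(c)
        assert q.status == SPLICED_ONLY
        assert q.pir == 0.0

    def test_insufficient_spliced_reads_is_missing_by_default(self):
        c = IntronCounts("i", "t", sj=3, ie5=0, ie3=0, intron_reads=0, intron_cov=0.0)
        q = compute_pir(c)
        assert q.status == INSUFFICIENT and q.pir is None

    def test_insufficient_as_zero_compatibility_mode(self):
        c = IntronCounts("i", "t", sj=3, ie5=0, ie3=0, intron_reads=0, intron_cov=0.0)
        assert compute_pir(c, insufficient_as_zero=True).pir == 0.0

    def test_weak_boundary_evidence_is_not_quantified(self):
        c = IntronCounts("i", "t", sj=9, ie5=1, ie3=0, intron_reads=1, intron_cov=0.1)
        assert compute_pir(c).status == INSUFFICIENT

    def test_negative_counts_rejected(self):
        c = IntronCounts("i", "t", sj=-1)
        with pytest.raises(ValueError):
            compute_pir(c)

    def test_filters_are_monotone_in_thresholds(self):
        import numpy as np

        rng = np.random.default_rng(3)
        counts = [
            IntronCounts(
                f"i{n}",
                "t",
                sj=float(rng.integers(0, 12)),
                ie5=float(rng.integers(0, 5)),
                ie3=float(rng.integers(0, 5)),
                intron_reads=float(rng.integers(0, 12)),
                intron_cov=float(rng.uniform(0, 3)),
            )
            for n in range(200)
        ]

        def n_quantified(**kw):
            return sum(1 for c in counts if compute_pir(c, **kw).status == QUANTIFIED)

        base = n_quantified()
        assert n_quantified(min_sj=7) <= base
        assert n_quantified(min_ie=3) <= base
        assert n_quantified(min_cov=2.0) <= base
        assert n_quantified(min_intron_reads=8) <= base


def _quants(sheet):
    mk = lambda iid, tp, pir, status: IntronQuant(
        iid, tp, IntronCounts(iid, "x"), pir, status
    )
    return [
        mk("hi", 2.0, 0.4, QUANTIFIED),
        mk("hi", 20.0, 0.0, SPLICED_ONLY),
        mk("low", 2.0, 0.01, QUANTIFIED),
        mk("low", 20.0, 0.02, QUANTIFIED),
        mk("na", 2.0, 0.5, QUANTIFIED),
        mk("na", 20.0, None, INSUFFICIENT),
    ]


def test_pir_matrix_row_filter_pseudo_and_missing(sheet22):
    mat = build_pir_matrix(_quants(sheet22), sheet22, min_pir=0.05, pseudo=0.001)
    assert list(mat.values.columns) == ["TP2", "TP20"]
    assert "low" not in mat.values.index  # max PIR < 0.05 at every timepoint
    assert mat.values.loc["hi", "TP2"] == pytest.approx(0.401)
    assert mat.values.loc["hi", "TP20"] == 0.001  # 0.0 + pseudo exactly
    assert math.isnan(mat.values.loc["na", "TP20"])  # insufficient stays NA


def test_pir_matrix_roundtrip_preserves_missing(sheet22, tmp_path):
    mat = build_pir_matrix(_quants(sheet22), sheet22)
    out = tmp_path / "pir.tsv"
    mat.to_tsv(out)
    from splicetime.matrix import SplicingMatrix

    back = SplicingMatrix.from_tsv(out, "PIR", 0.001)
    assert back.values.equals(mat.values) or (
        (back.values.isna() == mat.values.isna()).all().all()
        and (back.values.fillna(0) - mat.values.fillna(0)).abs().max().max() < 1e-12
    )


def test_quantified_pir_always_within_unit_interval(tmp_path):
    design = SimDesign(
        n_genes=2,
        gene_kinds=("ir",),
        timepoints=(2.0, 20.0),
        reads_per_gene=400,
        seed=23,
    )
    genome, bams, _ = simulate(design, tmp_path)
    from splicetime.annotation import all_introns, load_annotation

    introns = all_introns(load_annotation(genome.gff3))
    sheet = SampleSheet.from_tsv(genome.design_tsv)
    counts = {s: count_sample(p, introns) for s, p in bams.items()}
    for q in quantify(average_replicates(counts, sheet)):
        if q.status == QUANTIFIED:
            assert 0 < q.pir <= 1
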